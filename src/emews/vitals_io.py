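"""Flowsheet and alert-log I/O.

The flowsheet is the tabular EMR structure where timestamped vital signs are
recorded.  This module reads and writes a portable CSV stand-in for it
(UTF-8, comma-separated, RFC-4180 quoting, header required), validates every
row at ingest, and keeps streams stably sorted by (patient_id, timestamp).

File formats
------------
Flowsheet CSV columns (exact header)::

    patient_id,timestamp,parameter,value,source

Alert log CSV columns::

    patient_id,fired_at,criteria,acknowledgement

where ``criteria`` is a semicolon-joined list of parameter names and
``acknowledgement`` is one of the five outcome labels (empty for an alert
that has not been closed yet).

Timestamps must be timezone-aware ISO-8601; naive timestamps are rejected so
that calendar-day bucketing in the audit module is unambiguous.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, field_validator

logger = logging.getLogger("emews.vitals_io")

PathLike = Union[str, Path]


class Parameter(str, Enum):
    """Physiological parameters the system monitors."""

    SBP = "SBP"  # systolic blood pressure, mmHg
    DBP = "DBP"  # diastolic blood pressure, mmHg
    HR = "HR"  # heart rate, beats/min
    RR = "RR"  # respiratory rate, breaths/min
    SPO2 = "SPO2"  # oxygen saturation, percent
    TEMP = "TEMP"  # temperature, degrees Celsius
    URINE_OUTPUT = "URINE_OUTPUT"  # urine output rate, mL/hr


class Source(str, Enum):
    """How a value reached the flowsheet.

    BP, HR and SpO2 arrive automatically from the bedside monitor; RR,
    temperature and urine output are entered manually by the nurse.
    """

    MONITOR = "MONITOR"
    MANUAL = "MANUAL"


#: Hard physiologic plausibility bounds applied at ingest.  Values outside
#: these are rejected loudly, never silently dropped.  Parameters not listed
#: are only required to be finite and non-negative.
HARD_BOUNDS: dict[Parameter, tuple[float, float]] = {
    Parameter.SPO2: (0.0, 100.0),
    Parameter.TEMP: (25.0, 45.0),
}

FLOWSHEET_COLUMNS = ["patient_id", "timestamp", "parameter", "value", "source"]
ALERT_LOG_COLUMNS = ["patient_id", "fired_at", "criteria", "acknowledgement"]


class FlowsheetFormatError(ValueError):
    """The file-level format (header, column set) is wrong."""


class RowValidationError(ValueError):
    """One or more data rows failed validation.

    Carries ``(line_number, message)`` pairs for every offending row.
    """

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"line {n}: {msg}" for n, msg in self.errors)
        super().__init__(f"{len(self.errors)} invalid row(s): {lines}")


def _parse_timestamp(raw: str) -> datetime:
    ts = datetime.fromisoformat(raw)
    if ts.tzinfo is None or ts.tzinfo.utcoffset(ts) is None:
        raise ValueError(f"timestamp {raw!r} has no timezone offset")
    return ts


class VitalSample(BaseModel):
    """One timestamped measurement of one physiological parameter.

    Units by parameter: mmHg (SBP, DBP), beats/min (HR), breaths/min (RR),
    percent (SPO2), degrees Celsius (TEMP), mL/hr (URINE_OUTPUT).
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str
    timestamp: datetime
    parameter: Parameter
    value: float
    source: Source

    @field_validator("patient_id")
    @classmethod
    def _nonempty_id(cls, v: str) -> str:
        if not v:
            raise ValueError("patient_id must be non-empty")
        return v

    @field_validator("timestamp")
    @classmethod
    def _aware(cls, v: datetime) -> datetime:
        if v.tzinfo is None or v.tzinfo.utcoffset(v) is None:
            raise ValueError("timestamp must be timezone-aware")
        return v

    @field_validator("value")
    @classmethod
    def _finite_nonnegative(cls, v: float) -> float:
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"value must be finite and non-negative, got {v}")
        return v

    def model_post_init(self, __context) -> None:
        bounds = HARD_BOUNDS.get(self.parameter)
        if bounds is not None and not (bounds[0] <= self.value <= bounds[1]):
            raise ValueError(
                f"{self.parameter.value} value {self.value} outside plausibility "
                f"bounds [{bounds[0]}, {bounds[1]}]"
            )


@dataclass(frozen=True)
class VitalStream:
    """An ordered collection of vital samples.

    Sorted by (patient_id, timestamp); samples sharing both keys keep their
    original insertion order (stable sort), so repeated ingest never
    reorders simultaneous readings.
    """

    samples: tuple[VitalSample, ...] = field(default_factory=tuple)

    @classmethod
    def from_samples(cls, samples: Sequence[VitalSample]) -> "VitalStream":
        ordered = sorted(samples, key=lambda s: (s.patient_id, s.timestamp))
        return cls(tuple(ordered))

    def __iter__(self) -> Iterator[VitalSample]:
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.patient_id, None)
        return list(seen)

    def for_patient(self, patient_id: str) -> "VitalStream":
        return VitalStream(tuple(s for s in self.samples if s.patient_id == patient_id))

    def restrict(self, parameter: Parameter) -> "VitalStream":
        return VitalStream(tuple(s for s in self.samples if s.parameter == parameter))


def _format_value(value: float) -> str:
    # repr gives the shortest string that round-trips through float()
    return repr(float(value))


def read_flowsheet(path: PathLike, skip_invalid: bool = False) -> VitalStream:
    """Read and validate a flowsheet CSV.

    Parameters
    ----------
    path
        CSV file with the exact header ``patient_id,timestamp,parameter,value,source``.
    skip_invalid
        If False (default) any invalid row aborts the read with a
        :class:`RowValidationError` listing offending line numbers.  If True,
        invalid rows are logged and skipped — a deliberate opt-in, since a
        safety system should be loud about bad input.

    Returns
    -------
    VitalStream
        Validated and stably sorted by (patient_id, timestamp).
    """
    path = Path(path)
    samples: list[VitalSample] = []
    errors: list[tuple[int, str]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FlowsheetFormatError(f"{path}: empty file, expected header row")
        if header != FLOWSHEET_COLUMNS:
            raise FlowsheetFormatError(
                f"{path}: header {header!r} does not match required columns "
                f"{FLOWSHEET_COLUMNS!r}"
            )
        for row in reader:
            if not row:
                continue
            lineno = reader.line_num
            if len(row) != len(FLOWSHEET_COLUMNS):
                errors.append((lineno, f"expected {len(FLOWSHEET_COLUMNS)} fields, got {len(row)}"))
                continue
            pid, raw_ts, raw_param, raw_value, raw_source = row
            try:
                ts = _parse_timestamp(raw_ts)
                parameter = Parameter(raw_param)
                value = float(raw_value)
                source = Source(raw_source)
                samples.append(
                    VitalSample(
                        patient_id=pid,
                        timestamp=ts,
                        parameter=parameter,
                        value=value,
                        source=source,
                    )
                )
            except (ValueError, TypeError) as exc:
                errors.append((lineno, _brief(exc)))
    if errors:
        if not skip_invalid:
            raise RowValidationError(errors)
        for lineno, msg in errors:
            logger.warning("%s: skipping line %d: %s", path, lineno, msg)
    return VitalStream.from_samples(samples)


def _brief(exc: Exception) -> str:
    # pydantic ValidationError messages are multi-line; keep the first line
    return str(exc).splitlines()[0]


def write_flowsheet(stream: VitalStream, path: PathLike) -> None:
    """Write a flowsheet CSV such that ``read_flowsheet`` reproduces the stream exactly."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(FLOWSHEET_COLUMNS)
        for s in stream:
            writer.writerow(
                [
                    s.patient_id,
                    s.timestamp.isoformat(),
                    s.parameter.value,
                    _format_value(s.value),
                    s.source.value,
                ]
            )


def read_alert_log(path: PathLike) -> list:
    """Read an alert/acknowledgement log CSV into a list of AlertEvents.

    The ``criteria`` column is a semicolon-joined list of parameter names;
    ``acknowledgement`` is one of the five outcome labels, or empty for an
    alert that has not been closed.  The log format carries no
    acknowledged-at timestamp, so loaded outcomes have ``acknowledged_at``
    of None.  Output is sorted by ``fired_at`` (then patient id).
    """
    # local imports: alert_engine/acknowledgement import this module's types
    from .acknowledgement import AckLabel, AckOutcome
    from .alert_engine import AlertEvent
    from .criteria import CriterionFlag

    path = Path(path)
    alerts: list[AlertEvent] = []
    errors: list[tuple[int, str]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FlowsheetFormatError(f"{path}: empty file, expected header row")
        if header != ALERT_LOG_COLUMNS:
            raise FlowsheetFormatError(
                f"{path}: header {header!r} does not match required columns "
                f"{ALERT_LOG_COLUMNS!r}"
            )
        for row in reader:
            if not row:
                continue
            lineno = reader.line_num
            if len(row) != len(ALERT_LOG_COLUMNS):
                errors.append((lineno, f"expected {len(ALERT_LOG_COLUMNS)} fields, got {len(row)}"))
                continue
            pid, raw_ts, raw_criteria, raw_ack = row
            try:
                fired_at = _parse_timestamp(raw_ts)
                params = [Parameter(p) for p in raw_criteria.split(";") if p]
                if not params:
                    raise ValueError("criteria column is empty")
                outcome: Optional[AckOutcome] = None
                if raw_ack:
                    try:
                        label = AckLabel(raw_ack)
                    except ValueError:
                        raise ValueError(f"unknown acknowledgement label {raw_ack!r}")
                    outcome = AckOutcome(label=label, acknowledged_at=None)
                contributing = tuple(
                    CriterionFlag(
                        patient_id=pid,
                        timestamp=fired_at,
                        parameter=p,
                        value=math.nan,
                        rule="(loaded from log)",
                    )
                    for p in params
                )
                alerts.append(
                    AlertEvent(
                        patient_id=pid,
                        fired_at=fired_at,
                        contributing=contributing,
                        acknowledgement=outcome,
                    )
                )
            except (ValueError, TypeError) as exc:
                errors.append((lineno, _brief(exc)))
    if errors:
        raise RowValidationError(errors)
    alerts.sort(key=lambda a: (a.fired_at, a.patient_id))
    return alerts


def write_alert_log(alerts: Sequence, path: PathLike) -> None:
    """Write an alert log CSV (inverse of :func:`read_alert_log` up to flag detail)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ALERT_LOG_COLUMNS)
        for a in alerts:
            params: dict[str, None] = {}
            for f in a.contributing:
                params.setdefault(f.parameter.value, None)
            ack = a.acknowledgement.label.value if a.acknowledgement is not None else ""
            writer.writerow([a.patient_id, a.fired_at.isoformat(), ";".join(params), ack])
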