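"""Maternal early-warning abnormality criteria.

A maternal early-warning system (MEWS) flags vital signs outside thresholds
tuned to the physiology of pregnancy.  This module evaluates single samples
(and, for oliguria, short histories) against a configurable threshold table.

Boundary semantics are fixed and documented: every low bound is strict
(``value < low`` flags) and every high bound is strict (``value > high``
flags) except the temperature upper bound, which is inclusive (``>= 38``
flags) — abnormal temperature is defined as <36 or >=38 degrees Celsius.

The oliguria criterion is duration-qualified: a urine-output rate below
threshold must be sustained over a window, and at least two in-window
measurements are required so that a single spurious entry cannot flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from enum import Enum
from typing import Iterable, Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .vitals_io import Parameter, VitalSample, VitalStream


class Phase(str, Enum):
    """Development phases of the alert system's trigger policy."""

    P1 = "P1"
    P2 = "P2"
    P3 = "P3"


class CriteriaConfig(BaseModel):
    """Per-parameter abnormality thresholds (the MEWS trigger table).

    Defaults follow the 2014 national-partnership maternal early warning
    criteria; all values are overridable from the ``criteria:`` YAML block.
    Only parameters in ``enabled`` are evaluated.
    """

    model_config = ConfigDict(frozen=True)

    sbp_low: float = 90.0  # mmHg
    sbp_high: float = 160.0  # mmHg
    dbp_high: float = 100.0  # mmHg
    hr_low: float = 50.0  # beats/min
    hr_high: float = 120.0  # beats/min
    rr_low: float = 10.0  # breaths/min
    rr_high: float = 30.0  # breaths/min
    spo2_low: float = 95.0  # percent
    temp_low: float = 36.0  # degrees Celsius
    temp_high: float = 38.0  # degrees Celsius (inclusive bound)
    oliguria_rate: float = 35.0  # mL/hr
    oliguria_duration: float = 120.0  # minutes
    enabled: frozenset[Parameter] = frozenset(
        {
            Parameter.SBP,
            Parameter.DBP,
            Parameter.HR,
            Parameter.RR,
            Parameter.SPO2,
            Parameter.TEMP,
        }
    )

    @model_validator(mode="after")
    def _check(self) -> "CriteriaConfig":
        pairs = [
            ("sbp_low", "sbp_high"),
            ("hr_low", "hr_high"),
            ("rr_low", "rr_high"),
            ("temp_low", "temp_high"),
        ]
        for lo, hi in pairs:
            if getattr(self, lo) >= getattr(self, hi):
                raise ValueError(f"{lo} must be < {hi}")
        for name in (
            "sbp_low", "sbp_high", "dbp_high", "hr_low", "hr_high",
            "rr_low", "rr_high", "spo2_low", "temp_low", "temp_high",
            "oliguria_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.oliguria_duration <= 0:
            raise ValueError("oliguria_duration must be positive")
        return self

    def disable(self, *parameters: Parameter) -> "CriteriaConfig":
        return self.model_copy(update={"enabled": self.enabled - set(parameters)})

    def enable(self, *parameters: Parameter) -> "CriteriaConfig":
        return self.model_copy(update={"enabled": self.enabled | set(parameters)})


@dataclass(frozen=True)
class CriterionFlag:
    """One abnormal-vital finding: which rule fired, on which value, when."""

    patient_id: str
    timestamp: datetime
    parameter: Parameter
    value: float
    rule: str


def evaluate_sample(sample: VitalSample, config: CriteriaConfig) -> Optional[CriterionFlag]:
    """Evaluate one sample against the threshold table.

    Returns a flag iff the value violates the configured threshold(s) for its
    parameter; parameters outside ``config.enabled`` never flag.  Pure
    function of its arguments.

    Raises
    ------
    ValueError
        For URINE_OUTPUT samples — oliguria is duration-qualified and must go
        through :func:`evaluate_oliguria`.
    """
    if sample.parameter is Parameter.URINE_OUTPUT:
        raise ValueError("URINE_OUTPUT is duration-qualified; use evaluate_oliguria")
    if sample.parameter not in config.enabled:
        return None
    rule = _violated_rule(sample.parameter, sample.value, config)
    if rule is None:
        return None
    return CriterionFlag(
        patient_id=sample.patient_id,
        timestamp=sample.timestamp,
        parameter=sample.parameter,
        value=sample.value,
        rule=rule,
    )


def _violated_rule(parameter: Parameter, value: float, config: CriteriaConfig) -> Optional[str]:
    # low bounds strict, high bounds strict — except TEMP upper, inclusive
    if parameter is Parameter.SBP:
        if value < config.sbp_low:
            return "SBP < sbp_low"
        if value > config.sbp_high:
            return "SBP > sbp_high"
    elif parameter is Parameter.DBP:
        if value > config.dbp_high:
            return "DBP > dbp_high"
    elif parameter is Parameter.HR:
        if value < config.hr_low:
            return "HR < hr_low"
        if value > config.hr_high:
            return "HR > hr_high"
    elif parameter is Parameter.RR:
        if value < config.rr_low:
            return "RR < rr_low"
        if value > config.rr_high:
            return "RR > rr_high"
    elif parameter is Parameter.SPO2:
        if value < config.spo2_low:
            return "SPO2 < spo2_low"
    elif parameter is Parameter.TEMP:
        if value < config.temp_low:
            return "TEMP < temp_low"
        if value >= config.temp_high:
            return "TEMP >= temp_high"
    return None


def evaluate_oliguria(
    history: Iterable[VitalSample], at: datetime, config: CriteriaConfig
) -> Optional[CriterionFlag]:
    """Evaluate the sustained-low-urine-output criterion at time ``at``.

    Flags iff *every* URINE_OUTPUT sample in the closed-left/open-right
    window ``[at - oliguria_duration, at)`` is below ``oliguria_rate`` and at
    least two samples exist in that window.  A duration criterion is
    meaningless from a single reading, and the two-sample floor keeps one
    inconsistent manual entry from flagging on its own.

    ``history`` must be one patient's URINE_OUTPUT samples, time-sorted.
    """
    samples = list(history)
    if any(s.parameter is not Parameter.URINE_OUTPUT for s in samples):
        raise ValueError("history must contain only URINE_OUTPUT samples")
    if Parameter.URINE_OUTPUT not in config.enabled:
        return None
    window_start = at - timedelta(minutes=config.oliguria_duration)
    in_window = [s for s in samples if window_start <= s.timestamp < at]
    if len(in_window) < 2:
        return None
    if all(s.value < config.oliguria_rate for s in in_window):
        latest = in_window[-1]
        return CriterionFlag(
            patient_id=latest.patient_id,
            timestamp=at,
            parameter=Parameter.URINE_OUTPUT,
            value=latest.value,
            rule="URINE_OUTPUT < oliguria_rate sustained over oliguria_duration",
        )
    return None


#: Parameter sets active in each development phase.  Phases 1 and 2 used the
#: original criteria including urine output; phase 3 removed urine output
#: (inconsistent manual measurements drove ~30% of alerts) and added
#: temperature as a recommended expert screening criterion.
_PHASE_ENABLED: dict[Phase, frozenset[Parameter]] = {
    Phase.P1: frozenset(
        {Parameter.SBP, Parameter.DBP, Parameter.HR, Parameter.RR,
         Parameter.SPO2, Parameter.URINE_OUTPUT}
    ),
    Phase.P2: frozenset(
        {Parameter.SBP, Parameter.DBP, Parameter.HR, Parameter.RR,
         Parameter.SPO2, Parameter.URINE_OUTPUT}
    ),
    Phase.P3: frozenset(
        {Parameter.SBP, Parameter.DBP, Parameter.HR, Parameter.RR,
         Parameter.SPO2, Parameter.TEMP}
    ),
}


def default_config(phase: Phase = Phase.P3) -> CriteriaConfig:
    """Threshold table with the parameter set active in the given phase."""
    return CriteriaConfig(enabled=_PHASE_ENABLED[Phase(phase)])
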