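"""Synthetic intrapartum labor-ward vital-sign simulator.

Generates seeded, reproducible vital-sign streams that follow the monitoring
cadences of a labor-and-delivery unit:

* a full vitals set within one hour of the start of care, then at minimum
  every four hours;
* with an epidural, blood pressure and heart rate every 15 minutes (monitor
  source);
* temperature hourly after rupture of membranes (manual source);
* after delivery, a full set every 15 minutes for two hours (the immediate
  recovery period).

BP, HR and SpO2 arrive from the bedside monitor; RR, temperature and urine
output are entered manually by the nurse, with an entry-lag jitter uniform
on [0, 10] minutes after the scheduled time to exercise window-boundary
logic downstream.

Values are drawn from truncated normals (per-parameter baseline mean/sd,
truncated at the hard plausibility bounds of the flowsheet data model).
Optional deterioration episodes add a linear drift to affected parameters
from an onset time.  Monitor samples are replaced, with a configured
probability, by artifact draws from extreme bands — a stand-in for patient
movement or pushing spikes — and every such replacement is recorded in a
ground-truth sidecar so detection can be evaluated against labels.

One explicitly seeded generator drives each ``simulate_ward`` call; there is
no hidden global state, and identical (scenarios, seed) give byte-identical
output.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .vitals_io import HARD_BOUNDS, Parameter, Source, VitalSample, VitalStream

PathLike = Union[str, Path]

#: Baseline physiology (mean, sd) per parameter.  Shipped as configuration,
#: not constants, and NOT claimed to match any study population — they are
#: plausible intrapartum values well inside the default alert thresholds.
DEFAULT_BASELINES: dict[Parameter, tuple[float, float]] = {
    Parameter.SBP: (118.0, 9.0),
    Parameter.DBP: (72.0, 7.0),
    Parameter.HR: (85.0, 8.0),
    Parameter.RR: (16.0, 2.0),
    Parameter.SPO2: (98.0, 1.0),
    Parameter.TEMP: (36.9, 0.2),
}

#: Extreme bands for artifact draws: (low band, high band); a side is picked
#: by fair coin where both exist.  Band edges are configuration, not claims.
ARTIFACT_BANDS: dict[Parameter, tuple[Optional[tuple[float, float]], Optional[tuple[float, float]]]] = {
    Parameter.HR: ((25.0, 45.0), (130.0, 180.0)),
    Parameter.SBP: ((50.0, 85.0), (165.0, 220.0)),
    Parameter.DBP: ((20.0, 40.0), (105.0, 130.0)),
    Parameter.SPO2: ((50.0, 90.0), None),
    Parameter.RR: ((2.0, 6.0), (32.0, 50.0)),
    Parameter.TEMP: ((30.0, 34.0), (39.5, 42.0)),
    Parameter.URINE_OUTPUT: ((0.0, 10.0), None),
}

#: Parameters in the "full vitals set" and their flowsheet source.
_FULL_SET: list[tuple[Parameter, Source]] = [
    (Parameter.SBP, Source.MONITOR),
    (Parameter.DBP, Source.MONITOR),
    (Parameter.HR, Source.MONITOR),
    (Parameter.SPO2, Source.MONITOR),
    (Parameter.RR, Source.MANUAL),
    (Parameter.TEMP, Source.MANUAL),
]

_MANUAL_JITTER_MAX_MIN = 10.0
ROUTINE_INTERVAL_MIN = 240.0
EPIDURAL_INTERVAL_MIN = 15.0
ROM_TEMP_INTERVAL_MIN = 60.0
RECOVERY_INTERVAL_MIN = 15.0
RECOVERY_DURATION_MIN = 120.0


class Deterioration(BaseModel):
    """A clinical-deterioration episode: linear drift on affected parameters."""

    model_config = ConfigDict(frozen=True)

    onset: datetime
    #: drift in parameter units per hour, applied from onset onward
    drift_per_hour: dict[Parameter, float]

    @property
    def affected(self) -> frozenset[Parameter]:
        return frozenset(self.drift_per_hour)


class PatientScenario(BaseModel):
    """One patient's labor course and sampling configuration."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    admission: datetime
    labor_duration_min: float = Field(gt=0)
    delivery_at: Optional[datetime] = None
    epidural_at: Optional[datetime] = None
    rom_at: Optional[datetime] = None
    baseline: dict[Parameter, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    artifact_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    deterioration: Optional[Deterioration] = None

    @model_validator(mode="after")
    def _check(self) -> "PatientScenario":
        if self.delivery_at is None:
            object.__setattr__(
                self, "delivery_at", self.admission + timedelta(minutes=self.labor_duration_min)
            )
        if self.delivery_at <= self.admission:
            raise ValueError("delivery_at must be after admission")
        for name in ("epidural_at", "rom_at"):
            t = getattr(self, name)
            if t is not None and not (self.admission <= t <= self.delivery_at):
                raise ValueError(f"{name} must lie within [admission, delivery_at]")
        for p, (mean, sd) in self.baseline.items():
            if sd < 0 or not np.isfinite(mean) or not np.isfinite(sd):
                raise ValueError(f"baseline for {p} must have finite mean and sd >= 0")
        return self


@dataclass(frozen=True)
class SampleLabel:
    """Ground-truth annotation for one emitted sample."""

    patient_id: str
    timestamp: datetime
    parameter: Parameter
    is_artifact: bool
    source: Source = Source.MONITOR


@dataclass(frozen=True)
class GroundTruth:
    """Evaluation sidecar: per-sample artifact labels, per-patient onsets.

    ``labels`` is aligned 1:1 with the returned stream's samples (same
    order).  Manual samples are never artifacts.
    """

    labels: tuple[SampleLabel, ...]
    deterioration_onsets: dict[str, Optional[datetime]] = field(default_factory=dict)

    def artifact_fraction(self) -> float:
        """Observed artifact fraction among monitor-sourced samples."""
        flags = [l.is_artifact for l in self.labels if l.source is Source.MONITOR]
        return float(np.mean(flags)) if flags else 0.0

    def n_monitor(self) -> int:
        return sum(l.source is Source.MONITOR for l in self.labels)

    def n_artifacts(self) -> int:
        return sum(l.is_artifact for l in self.labels)


def _hard_bounds(parameter: Parameter) -> tuple[float, float]:
    return HARD_BOUNDS.get(parameter, (0.0, np.inf))


def _round_value(parameter: Parameter, value: float) -> float:
    # flowsheet granularity: one decimal for temperature, whole units otherwise
    if parameter is Parameter.TEMP:
        return round(value, 1)
    return float(round(value))


def _draw_value(
    rng: np.random.Generator,
    parameter: Parameter,
    mean: float,
    sd: float,
    t: datetime,
    deterioration: Optional[Deterioration],
) -> float:
    lo, hi = _hard_bounds(parameter)
    if sd == 0:
        value = mean
    else:
        a, b = (lo - mean) / sd, (hi - mean) / sd
        value = float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
    if deterioration is not None and t >= deterioration.onset:
        drift = deterioration.drift_per_hour.get(parameter)
        if drift is not None:
            hours = (t - deterioration.onset).total_seconds() / 3600.0
            value += drift * hours
    return float(np.clip(value, lo, hi if np.isfinite(hi) else value))


def _draw_artifact(rng: np.random.Generator, parameter: Parameter) -> float:
    low_band, high_band = ARTIFACT_BANDS[parameter]
    if low_band is not None and high_band is not None:
        band = low_band if rng.random() < 0.5 else high_band
    else:
        band = low_band if low_band is not None else high_band
    assert band is not None
    return float(rng.uniform(band[0], band[1]))


def _schedule(scenario: PatientScenario, rng: np.random.Generator) -> list[tuple[datetime, Parameter, Source]]:
    """Build the (scheduled time, parameter, source) event list for one patient.

    Construction order is fixed (routine, urine, epidural, ROM, recovery) so
    that random-draw order — and hence output under a fixed seed — is
    deterministic.
    """
    adm, dlv = scenario.admission, scenario.delivery_at
    assert dlv is not None
    events: list[tuple[datetime, Parameter, Source]] = []

    # (a) full set within 60 min of admission, then every 4 h until delivery
    first = adm + timedelta(minutes=float(rng.uniform(0.0, 60.0)))
    t = first
    while t < dlv:
        for p, src in _FULL_SET:
            if p in scenario.baseline:
                events.append((t, p, src))
        t += timedelta(minutes=ROUTINE_INTERVAL_MIN)

    # urine output (if simulated): hourly manual entries during labor
    if Parameter.URINE_OUTPUT in scenario.baseline:
        t = adm + timedelta(minutes=60.0)
        while t < dlv:
            events.append((t, Parameter.URINE_OUTPUT, Source.MANUAL))
            t += timedelta(minutes=60.0)

    # (b) post-epidural: BP and HR every 15 min from the monitor
    if scenario.epidural_at is not None:
        t = scenario.epidural_at
        while t <= dlv:
            for p in (Parameter.SBP, Parameter.DBP, Parameter.HR):
                if p in scenario.baseline:
                    events.append((t, p, Source.MONITOR))
            t += timedelta(minutes=EPIDURAL_INTERVAL_MIN)

    # (c) post-ROM: hourly temperature, manual
    if scenario.rom_at is not None and Parameter.TEMP in scenario.baseline:
        t = scenario.rom_at
        while t <= dlv:
            events.append((t, Parameter.TEMP, Source.MANUAL))
            t += timedelta(minutes=ROM_TEMP_INTERVAL_MIN)

    # (d) immediate recovery: full set every 15 min for two hours
    t = dlv
    end = dlv + timedelta(minutes=RECOVERY_DURATION_MIN)
    while t <= end:
        for p, src in _FULL_SET:
            if p in scenario.baseline:
                events.append((t, p, src))
        t += timedelta(minutes=RECOVERY_INTERVAL_MIN)

    return events


def simulate_ward(
    scenarios: Sequence[PatientScenario], seed: int
) -> tuple[VitalStream, GroundTruth]:
    """Simulate a set of labor-ward patients into one flowsheet stream.

    Returns the stream (stably sorted, valid) and a :class:`GroundTruth`
    sidecar whose labels align 1:1 with the stream's samples.
    """
    rng = np.random.default_rng(seed)
    pairs: list[tuple[VitalSample, SampleLabel]] = []
    onsets: dict[str, Optional[datetime]] = {}

    for scenario in scenarios:
        onsets[scenario.patient_id] = (
            scenario.deterioration.onset if scenario.deterioration else None
        )
        for scheduled, parameter, source in _schedule(scenario, rng):
            t = scheduled
            if source is Source.MANUAL:
                t = t + timedelta(minutes=float(rng.uniform(0.0, _MANUAL_JITTER_MAX_MIN)))
            mean, sd = scenario.baseline[parameter]
            value = _draw_value(rng, parameter, mean, sd, t, scenario.deterioration)
            is_artifact = False
            if source is Source.MONITOR and scenario.artifact_rate > 0:
                if rng.random() < scenario.artifact_rate:
                    value = _draw_artifact(rng, parameter)
                    is_artifact = True
            value = _round_value(parameter, value)
            sample = VitalSample(
                patient_id=scenario.patient_id,
                timestamp=t,
                parameter=parameter,
                value=value,
                source=source,
            )
            pairs.append(
                (sample, SampleLabel(scenario.patient_id, t, parameter, is_artifact, source))
            )

    pairs.sort(key=lambda pl: (pl[0].patient_id, pl[0].timestamp))
    stream = VitalStream(tuple(s for s, _ in pairs))
    truth = GroundTruth(labels=tuple(l for _, l in pairs), deterioration_onsets=onsets)
    return stream, truth


class ScenarioMix(BaseModel):
    """Composition of a scenario battery.

    Fractions of deterioration and epidural scenarios; the remainder are
    uncomplicated.  Fractions must sum to at most 1.
    """

    model_config = ConfigDict(frozen=True)

    epidural: float = Field(default=0.5, ge=0.0, le=1.0)
    deterioration: float = Field(default=0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _sum(self) -> "ScenarioMix":
        if self.epidural + self.deterioration > 1.0 + 1e-12:
            raise ValueError("mix fractions must sum to at most 1")
        return self


_BATTERY_EPOCH = datetime(2019, 1, 1, tzinfo=timezone.utc)
#: Deterioration drift defaults: tachycardia with falling systolic pressure,
#: the hemorrhage-like pattern an early-warning system exists to catch.
_DEFAULT_DRIFT: dict[Parameter, float] = {Parameter.HR: 12.0, Parameter.SBP: -10.0}


def scenario_battery(
    n_patients: int,
    mix: Optional[ScenarioMix] = None,
    seed: int = 0,
    artifact_rate: float = 0.03,
    baseline: Optional[dict[Parameter, tuple[float, float]]] = None,
) -> list[PatientScenario]:
    """Reproducible list of patient scenarios with a requested composition.

    Allocation is deterministic: the first ``round(deterioration * n)``
    patients deteriorate, the next ``round(epidural * n)`` have epidurals,
    the rest are uncomplicated.  Admissions are staggered so a battery spans
    several calendar days.
    """
    if n_patients < 0:
        raise ValueError("n_patients must be non-negative")
    mix = mix or ScenarioMix()
    rng = np.random.default_rng(seed)
    n_det = int(round(mix.deterioration * n_patients))
    n_epi = int(round(mix.epidural * n_patients))
    if n_det + n_epi > n_patients:
        n_epi = n_patients - n_det
    base = dict(baseline or DEFAULT_BASELINES)

    scenarios: list[PatientScenario] = []
    for i in range(n_patients):
        admission = _BATTERY_EPOCH + timedelta(minutes=137.0 * i)
        duration = float(np.clip(rng.normal(480.0, 120.0), 180.0, 960.0))
        epidural_at = None
        rom_at = None
        deterioration = None
        if i < n_det:
            onset = admission + timedelta(minutes=float(rng.uniform(0.5, 0.8)) * duration)
            deterioration = Deterioration(onset=onset, drift_per_hour=dict(_DEFAULT_DRIFT))
        elif i < n_det + n_epi:
            epidural_at = admission + timedelta(minutes=float(rng.uniform(0.1, 0.3)) * duration)
        if rng.random() < 0.7:
            rom_at = admission + timedelta(minutes=float(rng.uniform(0.3, 0.7)) * duration)
        scenarios.append(
            PatientScenario(
                patient_id=f"p{i:04d}",
                admission=admission,
                labor_duration_min=duration,
                epidural_at=epidural_at,
                rom_at=rom_at,
                baseline=base,
                artifact_rate=artifact_rate,
                deterioration=deterioration,
            )
        )
    return scenarios


def write_truth(truth: GroundTruth, path: PathLike) -> None:
    """Write the ground-truth sidecar CSV: patient_id,timestamp,parameter,is_artifact."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "timestamp", "parameter", "is_artifact"])
        for l in truth.labels:
            writer.writerow(
                [l.patient_id, l.timestamp.isoformat(), l.parameter.value, int(l.is_artifact)]
            )
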