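"""Phased alert engine: flags in, alert events out.

The engine converts a vital-sign stream into alert events under a phase
policy.  A policy is defined by

* ``min_distinct_criteria`` — how many *distinct* abnormal parameters must
  be present (repeated readings of one channel never count twice; single
  channel artifacts from patient movement or pushing are exactly what the
  distinct-parameter rule suppresses),
* ``lookback_min`` — the sliding window, in minutes, over which distinct
  abnormal parameters are pooled (0 means only simultaneous flags count),
* ``refractory_min`` — the minimum gap, in minutes, after an alert before
  another alert may fire for the same patient.

The three development phases map to: P1 = any single abnormal vital fires
immediately; P2 = single abnormal vital, but at most one alert per 15
minutes; P3 = at least two distinct abnormal parameters within the preceding
30 minutes, with a 30-minute timeframe before a subsequent alert.

Window semantics are half-open, ``(t - lookback, t]``, anchored at flag
timestamps only: an alert can only be caused by an arriving abnormal value,
and half-open windows avoid double-anchoring a flag exactly at the window
edge.  Simultaneous flags (equal timestamps) are evaluated together, so at
most one alert fires per (patient, timestamp) — one pop-up per event.

``detect_bruteforce`` is an independently written quadratic reference used
only for equivalence testing of ``detect``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import TYPE_CHECKING, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field

from .criteria import (
    CriteriaConfig,
    CriterionFlag,
    Phase,
    default_config,
    evaluate_oliguria,
    evaluate_sample,
)
from .vitals_io import Parameter, VitalStream

if TYPE_CHECKING:  # pragma: no cover
    from .acknowledgement import AckOutcome


class PhaseConfig(BaseModel):
    """Trigger policy: distinct-criteria count, lookback window, refractory delay.

    ``delay_mode`` selects how the inter-event delay is interpreted:
    ``"refractory"`` (default) suppresses *alerts* within ``refractory_min``
    of the previous alert; ``"flag_gap"`` instead requires the triggering
    abnormal reading to arrive at least ``refractory_min`` after the previous
    abnormal reading.  Both readings of the phase-2 wording are defensible;
    the alert-refractory reading matches the phase-3 wording and is the
    default.
    """

    model_config = ConfigDict(frozen=True)

    min_distinct_criteria: int = Field(default=1, ge=1)
    lookback_min: float = Field(default=0.0, ge=0.0)
    refractory_min: float = Field(default=0.0, ge=0.0)
    delay_mode: Literal["refractory", "flag_gap"] = "refractory"
    criteria: CriteriaConfig = Field(default_factory=default_config)


#: (min_distinct_criteria, lookback_min, refractory_min) per phase.
_PHASE_POLICY: dict[Phase, tuple[int, float, float]] = {
    Phase.P1: (1, 0.0, 0.0),
    Phase.P2: (1, 0.0, 15.0),
    Phase.P3: (2, 30.0, 30.0),
}


def default_policy(phase: Phase = Phase.P3) -> PhaseConfig:
    """The trigger policy of a development phase, with that phase's criteria set."""
    phase = Phase(phase)
    mdc, lb, rf = _PHASE_POLICY[phase]
    return PhaseConfig(
        min_distinct_criteria=mdc,
        lookback_min=lb,
        refractory_min=rf,
        criteria=default_config(phase),
    )


@dataclass(frozen=True)
class AlertEvent:
    """A fired alert: when, for whom, on which contributing criteria."""

    patient_id: str
    fired_at: datetime
    contributing: tuple[CriterionFlag, ...]
    acknowledgement: Optional["AckOutcome"] = None

    def parameters(self) -> frozenset[Parameter]:
        return frozenset(f.parameter for f in self.contributing)


def compute_flags(stream: VitalStream, config: CriteriaConfig) -> list[CriterionFlag]:
    """All criterion flags raised by a stream, sorted by (patient_id, timestamp).

    Point criteria are evaluated per sample.  The oliguria criterion is
    evaluated at each URINE_OUTPUT sample's timestamp over the preceding
    window, so a flag can only appear when a measurement arrives.
    """
    flags: list[CriterionFlag] = []
    for pid in stream.patient_ids():
        patient = stream.for_patient(pid)
        urine = [s for s in patient if s.parameter is Parameter.URINE_OUTPUT]
        for s in patient:
            if s.parameter is Parameter.URINE_OUTPUT:
                if Parameter.URINE_OUTPUT in config.enabled:
                    flag = evaluate_oliguria(urine, at=s.timestamp, config=config)
                    if flag is not None:
                        flags.append(flag)
            else:
                flag = evaluate_sample(s, config)
                if flag is not None:
                    flags.append(flag)
    flags.sort(key=lambda f: (f.patient_id, f.timestamp))
    return flags


def detect(stream: VitalStream, policy: PhaseConfig) -> list[AlertEvent]:
    """Run the alert engine over a validated, sorted stream.

    Each patient is processed independently in timestamp order.  At each
    flagged sample time ``t`` the engine counts distinct parameters with
    flags in ``(t - lookback, t]`` and fires iff the count reaches
    ``min_distinct_criteria`` and the delay rule allows it.  Contributing
    flags are the most recent flag per distinct in-window parameter.  Output
    is sorted by (patient_id, fired_at).  Pure function of (stream, policy).
    """
    flags = compute_flags(stream, policy.criteria)
    lookback = timedelta(minutes=policy.lookback_min)
    delay = timedelta(minutes=policy.refractory_min)
    alerts: list[AlertEvent] = []

    by_patient: dict[str, list[CriterionFlag]] = {}
    for f in flags:
        by_patient.setdefault(f.patient_id, []).append(f)

    for pid in sorted(by_patient):
        pflags = by_patient[pid]  # already time-sorted
        times = sorted({f.timestamp for f in pflags})
        last_alert: Optional[datetime] = None
        prev_flag_time: Optional[datetime] = None
        for t in times:
            if policy.lookback_min == 0:
                # instantaneous policy: only flags at exactly t count
                in_window = [f for f in pflags if f.timestamp == t]
            else:
                in_window = [f for f in pflags if t - lookback < f.timestamp <= t]
            latest: dict[Parameter, CriterionFlag] = {}
            for f in in_window:  # time-sorted, so later flags overwrite
                latest[f.parameter] = f
            allowed = True
            if policy.delay_mode == "refractory":
                if last_alert is not None and t - last_alert < delay:
                    allowed = False
            else:  # flag_gap: gap measured between abnormal readings
                if prev_flag_time is not None and t - prev_flag_time < delay:
                    allowed = False
            if len(latest) >= policy.min_distinct_criteria and allowed:
                contributing = tuple(
                    sorted(latest.values(), key=lambda f: (f.timestamp, f.parameter.value))
                )
                alerts.append(AlertEvent(patient_id=pid, fired_at=t, contributing=contributing))
                last_alert = t
            prev_flag_time = t
    alerts.sort(key=lambda a: (a.patient_id, a.fired_at))
    return alerts


def detect_bruteforce(stream: VitalStream, policy: PhaseConfig) -> list[AlertEvent]:
    """Quadratic reference implementation of :func:`detect`.

    Re-derives flags and alerts with straight-line scans over all sample and
    flag pairs; exists solely as an independent oracle for equivalence
    testing on small streams.
    """
    if len(stream) > 10_000:
        raise ValueError("brute-force oracle is restricted to small streams")
    cfg = policy.criteria

    # flags, the slow way: every sample checked against every rule in turn
    flags: list[CriterionFlag] = []
    for s in stream:
        if s.parameter is Parameter.URINE_OUTPUT:
            if Parameter.URINE_OUTPUT not in cfg.enabled:
                continue
            window_start = s.timestamp - timedelta(minutes=cfg.oliguria_duration)
            in_win = [
                o
                for o in stream
                if o.patient_id == s.patient_id
                and o.parameter is Parameter.URINE_OUTPUT
                and window_start <= o.timestamp < s.timestamp
            ]
            in_win.sort(key=lambda o: o.timestamp)
            if len(in_win) >= 2 and all(o.value < cfg.oliguria_rate for o in in_win):
                flags.append(
                    CriterionFlag(
                        patient_id=s.patient_id,
                        timestamp=s.timestamp,
                        parameter=Parameter.URINE_OUTPUT,
                        value=in_win[-1].value,
                        rule="URINE_OUTPUT < oliguria_rate sustained over oliguria_duration",
                    )
                )
            continue
        if s.parameter not in cfg.enabled:
            continue
        rule = None
        if s.parameter is Parameter.SBP and s.value < cfg.sbp_low:
            rule = "SBP < sbp_low"
        if s.parameter is Parameter.SBP and s.value > cfg.sbp_high:
            rule = "SBP > sbp_high"
        if s.parameter is Parameter.DBP and s.value > cfg.dbp_high:
            rule = "DBP > dbp_high"
        if s.parameter is Parameter.HR and s.value < cfg.hr_low:
            rule = "HR < hr_low"
        if s.parameter is Parameter.HR and s.value > cfg.hr_high:
            rule = "HR > hr_high"
        if s.parameter is Parameter.RR and s.value < cfg.rr_low:
            rule = "RR < rr_low"
        if s.parameter is Parameter.RR and s.value > cfg.rr_high:
            rule = "RR > rr_high"
        if s.parameter is Parameter.SPO2 and s.value < cfg.spo2_low:
            rule = "SPO2 < spo2_low"
        if s.parameter is Parameter.TEMP and s.value < cfg.temp_low:
            rule = "TEMP < temp_low"
        if s.parameter is Parameter.TEMP and s.value >= cfg.temp_high:
            rule = "TEMP >= temp_high"
        if rule is not None:
            flags.append(
                CriterionFlag(
                    patient_id=s.patient_id,
                    timestamp=s.timestamp,
                    parameter=s.parameter,
                    value=s.value,
                    rule=rule,
                )
            )

    flags.sort(key=lambda f: (f.patient_id, f.timestamp))
    lookback = timedelta(minutes=policy.lookback_min)
    delay = timedelta(minutes=policy.refractory_min)
    alerts: list[AlertEvent] = []
    for pid in sorted({f.patient_id for f in flags}):
        pflags = [f for f in flags if f.patient_id == pid]
        times = sorted({f.timestamp for f in pflags})
        last_alert: Optional[datetime] = None
        prev_flag_time: Optional[datetime] = None
        for t in times:
            if policy.lookback_min == 0:
                in_window = [f for f in pflags if f.timestamp == t]
            else:
                in_window = [f for f in pflags if t - lookback < f.timestamp <= t]
            latest: dict[Parameter, CriterionFlag] = {}
            for f in in_window:
                if f.parameter not in latest or f.timestamp >= latest[f.parameter].timestamp:
                    latest[f.parameter] = f
            if policy.delay_mode == "refractory":
                allowed = last_alert is None or t - last_alert >= delay
            else:
                allowed = prev_flag_time is None or t - prev_flag_time >= delay
            if len(latest) >= policy.min_distinct_criteria and allowed:
                contributing = tuple(
                    sorted(latest.values(), key=lambda f: (f.timestamp, f.parameter.value))
                )
                alerts.append(AlertEvent(patient_id=pid, fired_at=t, contributing=contributing))
                last_alert = t
            prev_flag_time = t
    alerts.sort(key=lambda a: (a.patient_id, a.fired_at))
    return alerts
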