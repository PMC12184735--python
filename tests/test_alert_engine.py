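"""Alert engine: window/refractory semantics, oracle equivalence, invariants."""

from __future__ import annotations

from datetime import timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emews import (
    Parameter,
    Phase,
    PhaseConfig,
    VitalStream,
    default_policy,
    detect,
    detect_bruteforce,
)

from conftest import make_sample, random_stream, ts

P1 = default_policy(Phase.P1)
P2 = default_policy(Phase.P2)
P3 = default_policy(Phase.P3)


def _hr(minutes, pid="p1", value=130.0):
    return make_sample(pid=pid, minutes=minutes, parameter=Parameter.HR, value=value)


def _sbp(minutes, pid="p1", value=170.0):
    return make_sample(pid=pid, minutes=minutes, parameter=Parameter.SBP, value=value)


def test_phase1_single_flag_fires_immediately():
    stream = VitalStream.from_samples([_hr(0)])
    alerts = detect(stream, P1)
    assert len(alerts) == 1
    assert alerts[0].fired_at == ts(0)
    assert len(alerts[0].contributing) == 1


def test_phase3_isolated_criterion_no_longer_fires():
    """A single abnormal parameter with nothing else within 30 min stays silent."""
    stream = VitalStream.from_samples([_hr(0)])
    assert detect(stream, P3) == []


def test_phase3_two_distinct_parameters_within_window_fire_once():
    stream = VitalStream.from_samples([_hr(0), _sbp(20)])
    alerts = detect(stream, P3)
    assert len(alerts) == 1
    assert alerts[0].fired_at == ts(20)
    assert alerts[0].parameters() == {Parameter.HR, Parameter.SBP}


def test_phase3_repeated_flags_on_one_channel_do_not_count_twice():
    stream = VitalStream.from_samples([_hr(0), _hr(10)])
    assert detect(stream, P3) == []


def test_phase2_refractory_walk():
    # frozen from a by-hand walk of the 15-min refractory rule:
    # flags at 0, 5, 10, 20 -> alerts at 0 (first) and 20 (20-0 >= 15)
    stream = VitalStream.from_samples([_hr(0), _hr(5), _hr(10), _hr(20)])
    alerts = detect(stream, P2)
    assert [a.fired_at for a in alerts] == [ts(0), ts(20)]


def test_lookback_window_is_half_open():
    # a flag exactly lookback minutes before t falls outside (t - lookback, t]
    assert detect(VitalStream.from_samples([_hr(0), _sbp(30)]), P3) == []
    alerts = detect(VitalStream.from_samples([_hr(1), _sbp(30)]), P3)
    assert [a.fired_at for a in alerts] == [ts(30)]


def test_simultaneous_flags_yield_one_alert():
    stream = VitalStream.from_samples([_hr(0), _sbp(0)])
    alerts = detect(stream, P3)
    assert len(alerts) == 1
    assert alerts[0].parameters() == {Parameter.HR, Parameter.SBP}


def test_contributing_is_most_recent_flag_per_parameter():
    stream = VitalStream.from_samples([_hr(0, value=130), _hr(15, value=140), _sbp(20)])
    (alert,) = detect(stream, P3)
    hr_flag = next(f for f in alert.contributing if f.parameter is Parameter.HR)
    assert hr_flag.value == 140


def test_flag_gap_delay_mode_measures_between_abnormal_readings():
    policy = P2.model_copy(update={"delay_mode": "flag_gap"})
    stream = VitalStream.from_samples([_hr(0), _hr(10), _hr(30)])
    alerts = detect(stream, policy)
    # 10 is only 10 min after the previous abnormal reading; 30 is 20 min after 10
    assert [a.fired_at for a in alerts] == [ts(0), ts(30)]


def test_per_patient_independence():
    a = [_hr(0, pid="a"), _sbp(10, pid="a")]
    b = [_hr(5, pid="b"), _sbp(40, pid="b")]
    merged = detect(VitalStream.from_samples(a + b), P3)
    separate = detect(VitalStream.from_samples(a), P3) + detect(VitalStream.from_samples(b), P3)
    assert merged == sorted(separate, key=lambda x: (x.patient_id, x.fired_at))


def test_oliguria_feeds_the_engine():
    policy = default_policy(Phase.P1)
    samples = [
        make_sample(minutes=m, parameter=Parameter.URINE_OUTPUT, value=10.0,
                    source="MANUAL")
        for m in (0, 60, 120)
    ]
    alerts = detect(VitalStream.from_samples(samples), policy)
    # evaluation anchors at each sample; at t=120 the [0, 120) window holds two low values
    assert [a.fired_at for a in alerts] == [ts(120)]
    assert alerts[0].parameters() == {Parameter.URINE_OUTPUT}


def test_empty_stream():
    assert detect(VitalStream(), P3) == []
    assert detect_bruteforce(VitalStream(), P3) == []


CUSTOM = PhaseConfig(
    min_distinct_criteria=2,
    lookback_min=45,
    refractory_min=10,
    criteria=P1.criteria,
)
GAP = PhaseConfig(
    min_distinct_criteria=1,
    lookback_min=20,
    refractory_min=25,
    delay_mode="flag_gap",
    criteria=P3.criteria,
)
POLICIES = [P1, P2, P3, CUSTOM, GAP]


@given(seed=st.integers(min_value=0, max_value=10_000))
@settings(derandomize=True, max_examples=150, deadline=None)
def test_oracle_equivalence_on_random_streams(seed):
    """The production engine and the quadratic reference agree everywhere."""
    stream = random_stream(np.random.default_rng(seed))
    for policy in POLICIES:
        assert detect(stream, policy) == detect_bruteforce(stream, policy)


@given(seed=st.integers(min_value=0, max_value=10_000))
@settings(derandomize=True, max_examples=100, deadline=None)
def test_refractory_and_window_invariants(seed):
    stream = random_stream(np.random.default_rng(seed))
    for policy in POLICIES:
        if policy.delay_mode != "refractory":
            continue
        alerts = detect(stream, policy)
        by_patient: dict[str, list] = {}
        for a in alerts:
            by_patient.setdefault(a.patient_id, []).append(a)
            # contributing flags lie in (fired_at - lookback, fired_at];
            # an instantaneous policy only pools flags at exactly fired_at
            for f in a.contributing:
                if policy.lookback_min == 0:
                    assert f.timestamp == a.fired_at
                else:
                    assert (
                        a.fired_at - timedelta(minutes=policy.lookback_min)
                        < f.timestamp
                        <= a.fired_at
                    )
            assert len(a.parameters()) >= policy.min_distinct_criteria
        for seq in by_patient.values():
            for earlier, later in zip(seq, seq[1:]):
                assert (later.fired_at - earlier.fired_at) >= timedelta(minutes=policy.refractory_min)


@given(
    seed=st.integers(min_value=0, max_value=10_000),
    extra_min=st.integers(min_value=1, max_value=3),
    extra_refractory=st.floats(min_value=1, max_value=60),
)
@settings(derandomize=True, max_examples=100, deadline=None)
def test_tightening_policy_never_increases_alert_count(seed, extra_min, extra_refractory):
    stream = random_stream(np.random.default_rng(seed))
    base = P3
    n_base = len(detect(stream, base))
    stricter_count = base.model_copy(
        update={"min_distinct_criteria": base.min_distinct_criteria + extra_min}
    )
    longer_refractory = base.model_copy(
        update={"refractory_min": base.refractory_min + extra_refractory}
    )
    assert len(detect(stream, stricter_count)) <= n_base
    assert len(detect(stream, longer_refractory)) <= n_base


def test_determinism():
    stream = random_stream(np.random.default_rng(7))
    assert detect(stream, P3) == detect(stream, P3)


def test_bruteforce_rejects_large_streams():
    big = VitalStream.from_samples([_hr(i % 240, pid=f"p{i % 7}") for i in range(10_001)])
    with pytest.raises(ValueError):
        detect_bruteforce(big, P1)
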