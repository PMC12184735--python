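"""Shared fixtures and stream factories for the test suite."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from emews import Parameter, Source, VitalSample, VitalStream

BASE = datetime(2019, 1, 1, tzinfo=timezone.utc)


def ts(minutes: float) -> datetime:
    return BASE + timedelta(minutes=minutes)


def make_sample(
    pid: str = "p1",
    minutes: float = 0.0,
    parameter: Parameter = Parameter.HR,
    value: float = 80.0,
    source: Source = Source.MONITOR,
) -> VitalSample:
    return VitalSample(
        patient_id=pid,
        timestamp=ts(minutes),
        parameter=parameter,
        value=value,
        source=source,
    )


# value ranges that straddle the default thresholds, so random streams carry
# a healthy mix of normal and abnormal readings
_VALUE_RANGES = {
    Parameter.SBP: (70.0, 180.0),
    Parameter.DBP: (50.0, 120.0),
    Parameter.HR: (40.0, 140.0),
    Parameter.RR: (5.0, 35.0),
    Parameter.SPO2: (85.0, 100.0),
    Parameter.TEMP: (35.0, 39.0),
    Parameter.URINE_OUTPUT: (5.0, 80.0),
}


def random_stream(rng: np.random.Generator, max_patients: int = 3, max_samples: int = 40) -> VitalStream:
    """A small random stream mixing parameters, patients and near-threshold values."""
    n = int(rng.integers(0, max_samples + 1))
    params = list(Parameter)
    samples = []
    for _ in range(n):
        p = params[int(rng.integers(len(params)))]
        lo, hi = _VALUE_RANGES[p]
        samples.append(
            VitalSample(
                patient_id=f"p{int(rng.integers(1, max_patients + 1))}",
                timestamp=ts(float(rng.integers(0, 241))),
                parameter=p,
                value=round(float(rng.uniform(lo, hi)), 1),
                source=Source.MONITOR if rng.random() < 0.6 else Source.MANUAL,
            )
        )
    return VitalStream.from_samples(samples)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20190101)
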