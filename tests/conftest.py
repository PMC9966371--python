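import numpy as np
import pytest

from oxiflight import (SyntheticParams, SubjectRecord, TimeSeries,
                       generate_flight, generate_subject)


NOISELESS = SyntheticParams(noise_sd_spo2=0.0, noise_sd_hr=0.0,
                            dropout_prob=0.0)


@pytest.fixture
def noiseless_params():
    return NOISELESS


@pytest.fixture
def clean_subject(noiseless_params):
    """One noiseless synthetic subject plus its analytic ground truth."""
    return generate_subject(noiseless_params, subject_id="S01",
                            age=31.0, sex="M", station=1)


@pytest.fixture
def small_flight():
    """Four-subject noisy flight plus ground-truth phase table."""
    return generate_flight(4, base_params=SyntheticParams(), seed=42,
                           flight_id="FLT042")


def make_subject(times, spo2, mask=None, hr=None, subject_id="T01", **kw):
    """Hand-build a SubjectRecord from plain arrays (mask defaults to
    all-connected, HR to a constant 70 bpm)."""
    times = np.asarray(times, dtype=float)
    if mask is None:
        mask = np.ones_like(times)
    if hr is None:
        hr = np.full_like(times, 70.0)
    return SubjectRecord(
        subject_id=subject_id,
        spo2=TimeSeries(times, np.asarray(spo2, dtype=float), "spo2"),
        hr=TimeSeries(times, np.asarray(hr, dtype=float), "hr"),
        mask=TimeSeries(times, np.asarray(mask, dtype=float), "mask"),
        **kw,
    )


def random_piecewise_linear_trace(rng, n_knots=6, duration=300.0,
                                  dt=1.0, lo=55.0, hi=100.0):
    """Random piecewise-linear SpO2-like trace sampled on a uniform grid."""
    knot_t = np.sort(rng.uniform(0, duration, n_knots))
    knot_t[0], knot_t[-1] = 0.0, duration
    knot_v = rng.uniform(lo, hi, n_knots)
    t = np.arange(0, duration + dt / 2, dt)
    return t, np.interp(t, knot_t, knot_v)
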