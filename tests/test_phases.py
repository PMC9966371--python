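"""Unit and property tests for mask events, threshold crossings, the six
phase parameters, segment slopes, trace stats and validity checks."""

import numpy as np
import pytest

from oxiflight import (
    AnalysisConfig,
    TimeSeries,
    auto_segment,
    compute_phase_parameters,
    detect_mask_intervals,
    fit_segment_slope,
    summarize_trace,
    threshold_crossing_time,
    validate_record,
)
from oxiflight.errors import ContractError, InsufficientDataError

from conftest import make_subject, random_piecewise_linear_trace
from oracles import brute_dwell_time, brute_first_crossing, brute_mask_intervals


def series(values, dt=1.0, name="spo2"):
    v = np.asarray(values, dtype=float)
    return TimeSeries(np.arange(len(v)) * dt, v, name)


# ---------------------------------------------------------------------------
# mask events

class TestDetectMaskIntervals:
    def test_always_connected_yields_no_intervals(self):
        assert len(detect_mask_intervals(series([1, 1, 1, 1], name="mask"))) == 0

    def test_single_disconnection_run(self):
        ev = detect_mask_intervals(series([1, 1, 0, 0, 0, 1], name="mask"))
        assert ev.intervals == ((2.0, 5.0),)

    def test_record_ending_disconnected_is_censored(self):
        ev = detect_mask_intervals(series([1, 0, 0], name="mask"))
        assert ev.intervals == ((1.0, None),)

    def test_empty_series_rejected(self):
        with pytest.raises(ContractError):
            detect_mask_intervals(series([], name="mask"))

    def test_matches_run_length_oracle_on_random_masks(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            m = (rng.random(rng.integers(2, 40)) > 0.4).astype(float)
            ts = series(m, name="mask")
            got = [tuple(iv) for iv in detect_mask_intervals(ts).intervals]
            assert got == brute_mask_intervals(ts.times, ts.values)


# ---------------------------------------------------------------------------
# threshold crossings

class TestThresholdCrossing:
    def test_never_crossing_returns_none(self):
        assert threshold_crossing_time(series([98] * 5), 97, "below") is None

    def test_linear_decline_crosses_strictly_below(self):
        # s(t) = 98 - 0.5 t: s(2) = 97.0 is not < 97; s(3) = 96.5 is
        t = np.arange(0, 11.0)
        ts = TimeSeries(t, 98 - 0.5 * t, "spo2")
        assert threshold_crossing_time(ts, 97, "below") == 3.0

    def test_debounce_requires_consecutive_run(self):
        ts = series([98, 96, 98, 96, 96, 96])
        assert threshold_crossing_time(ts, 97, "below", debounce=3) == 3.0
        assert threshold_crossing_time(ts, 97, "below", debounce=1) == 1.0

    def test_anchor_skips_earlier_crossings(self):
        ts = series([96, 98, 98, 96, 96])
        assert threshold_crossing_time(ts, 97, "below", anchor=1.0) == 3.0

    def test_missing_samples_break_runs(self):
        ts = series([98, 96, np.nan, 96, 96])
        assert threshold_crossing_time(ts, 97, "below", debounce=2) == 3.0

    def test_at_or_above_is_inclusive(self):
        ts = series([90, 93, 97, 99])
        assert threshold_crossing_time(ts, 97, "at_or_above") == 2.0

    def test_anchor_outside_span_rejected(self):
        with pytest.raises(ContractError):
            threshold_crossing_time(series([98, 98]), 97, "below", anchor=10.0)

    def test_matches_scan_oracle_on_random_traces(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            t, v = random_piecewise_linear_trace(rng)
            thr = rng.uniform(60, 99)
            direction = "below" if rng.random() < 0.5 else "at_or_above"
            deb = int(rng.integers(1, 4))
            anchor = float(rng.uniform(0, t[-1] / 2))
            ts = TimeSeries(t, v, "spo2")
            got = threshold_crossing_time(ts, thr, direction, anchor, deb)
            want = brute_first_crossing(t, v, thr, direction, anchor, deb)
            assert got == want


# ---------------------------------------------------------------------------
# phase parameters

def piecewise_subject():
    """Hand-built trace matching known phase geometry: DM=60, RM=360,
    first <97 at 75 s, first <90 at 120 s, recovers to >=97 at 450 s."""
    t = np.arange(0.0, 601.0)
    knots_t = [0, 74, 75, 119, 120, 360, 449, 450, 600]
    knots_v = [98, 98, 96.5, 90.5, 89.5, 62, 96.5, 97.5, 98]
    spo2 = np.interp(t, knots_t, knots_v)
    mask = np.where((t >= 60) & (t < 360), 0.0, 1.0)
    return make_subject(t, spo2, mask=mask)


class TestComputePhaseParameters:
    def test_known_geometry_recovered(self):
        subj = piecewise_subject()
        ph = compute_phase_parameters(subj)
        assert ph.DT.value == 300.0          # RM - DM = 360 - 60
        assert ph.DeD.value == 15.0          # 75 - 60
        assert ph.HD.value == 60.0           # 120 - 60
        assert ph.RT.value == 90.0           # 450 - 360
        # dwell sums against the brute-force oracle
        t, v = subj.spo2.times, subj.spo2.values
        assert ph.DeT.value == brute_dwell_time(t, v, 97, 1.0)
        assert ph.HT.value == brute_dwell_time(t, v, 90, 1.0)

    def test_never_desaturating_trace(self):
        t = np.arange(0.0, 100.0)
        mask = np.where((t >= 20) & (t < 60), 0.0, 1.0)
        subj = make_subject(t, np.full_like(t, 98.0), mask=mask)
        ph = compute_phase_parameters(subj)
        assert ph.DeT.value == 0.0 and ph.HT.value == 0.0
        assert not ph.DeD.defined and not ph.HD.defined
        assert ph.RT.value == 0.0            # already >= 97 at reconnection

    def test_no_disconnection_leaves_phases_undefined(self):
        subj = make_subject(np.arange(10.0), np.full(10, 98.0))
        ph = compute_phase_parameters(subj)
        assert not ph.DT.defined and not ph.DT.censored
        assert ph.DeT.value == 0.0

    def test_censored_reconnection_censors_DT_and_RT(self):
        t = np.arange(0.0, 100.0)
        subj = make_subject(t, np.full_like(t, 98.0),
                            mask=np.where(t >= 40, 0.0, 1.0))
        ph = compute_phase_parameters(subj)
        assert ph.DT.censored and ph.DT.censoring_time == 99.0 - 40.0
        assert ph.RT.censored

    def test_dt_equals_rm_minus_dm(self, clean_subject):
        rec, _ = clean_subject
        ev = detect_mask_intervals(rec.mask)
        ph = compute_phase_parameters(rec)
        dm, rm = ev.first
        assert ph.DT.value == rm - dm

    def test_ordering_invariants_on_random_traces(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            t, v = random_piecewise_linear_trace(rng)
            mask = np.where((t >= 30) & (t < 200), 0.0, 1.0)
            ph = compute_phase_parameters(make_subject(t, v, mask=mask))
            if ph.DeD.defined and ph.HD.defined:
                assert ph.DeD.value <= ph.HD.value
            assert ph.HT.value <= ph.DeT.value

    def test_oracle_equivalence_on_random_traces(self):
        rng = np.random.default_rng(13)
        cfg = AnalysisConfig()
        for _ in range(100):
            t, v = random_piecewise_linear_trace(rng)
            mask = np.where((t >= 30) & (t < 200), 0.0, 1.0)
            subj = make_subject(t, v, mask=mask)
            ph = compute_phase_parameters(subj)
            for thr, delay_name, dwell_name in (
                    (cfg.desat_threshold, "DeD", "DeT"),
                    (cfg.hypoxia_threshold, "HD", "HT")):
                want = brute_first_crossing(t, v, thr, "below", anchor=30.0)
                got = ph[delay_name]
                assert (got.value == want - 30.0 if want is not None
                        else not got.defined)
                assert ph[dwell_name].value == pytest.approx(
                    brute_dwell_time(t, v, thr, 1.0))
            want_rt = brute_first_crossing(t, v, cfg.recovery_threshold,
                                           "at_or_above", anchor=200.0)
            if want_rt is None:
                assert ph.RT.censored
            else:
                assert ph.RT.value == want_rt - 200.0

    def test_raising_threshold_cannot_shrink_dwell(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            t, v = random_piecewise_linear_trace(rng)
            mask = np.where((t >= 30) & (t < 200), 0.0, 1.0)
            subj = make_subject(t, v, mask=mask)
            dets = [
                compute_phase_parameters(
                    subj, AnalysisConfig(desat_threshold=thr)).DeT.value
                for thr in (85.0, 92.0, 97.0)]
            assert dets == sorted(dets)


# ---------------------------------------------------------------------------
# slopes and trace stats

class TestFitSegmentSlope:
    def test_constant_trace_slope_zero_r2_one(self):
        seg = fit_segment_slope(series([98.0] * 61), 0, 60)
        assert seg.slope == 0.0 and seg.r_squared == 1.0

    def test_exact_line_recovered_in_per_minute_units(self):
        t = np.arange(0.0, 11.0)
        seg = fit_segment_slope(TimeSeries(t, 98 - 0.5 * t, "spo2"), 0, 10)
        assert seg.slope == pytest.approx(-30.0, rel=1e-9)   # -0.5 %/s
        assert seg.r_squared == pytest.approx(1.0)
        assert seg.intercept == pytest.approx(98.0, rel=1e-9)

    def test_two_point_line_is_exact(self):
        ts = TimeSeries(np.array([0.0, 60.0]), np.array([98.0, 92.0]), "spo2")
        seg = fit_segment_slope(ts, 0, 60)
        assert seg.slope == pytest.approx(-6.0, rel=1e-12)

    def test_slope_invariant_under_constant_shift(self):
        rng = np.random.default_rng(2)
        t = np.arange(0.0, 50.0)
        v = 95 + rng.normal(0, 1, t.size)
        a = fit_segment_slope(TimeSeries(t, v, "spo2"), 0, 49)
        b = fit_segment_slope(TimeSeries(t, v + 7.5, "spo2"), 0, 49)
        assert a.slope == pytest.approx(b.slope, abs=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_segment_slope(series([98, 98, 98]), 0, 0.5)

    def test_missing_samples_excluded_from_fit(self):
        v = np.array([98.0, np.nan, 96.0, np.nan, 94.0])
        seg = fit_segment_slope(series(v), 0, 4)
        assert seg.n == 3
        assert seg.slope == pytest.approx(-60.0, rel=1e-9)   # -1 %/s


class TestSummarizeTrace:
    def test_basic_arithmetic(self):
        st = summarize_trace(series([96, 97, 98]))
        assert (st.minimum, st.maximum, st.mean) == (96.0, 98.0, 97.0)

    def test_singleton_window(self):
        st = summarize_trace(series([96, 97, 98]), window=(1.0, 1.0))
        assert st.minimum == st.maximum == st.mean == 97.0
        assert st.slope is None

    def test_whole_record_equals_spanning_window(self):
        ts = series([98, 97, 95, 93])
        assert summarize_trace(ts) == summarize_trace(ts, window=ts.span)

    def test_min_le_mean_le_max(self):
        rng = np.random.default_rng(8)
        t, v = random_piecewise_linear_trace(rng)
        st = summarize_trace(TimeSeries(t, v, "spo2"))
        assert st.minimum <= st.mean <= st.maximum


class TestAutoSegment:
    def test_no_disconnection_gives_only_baseline(self):
        subj = make_subject(np.arange(100.0), np.full(100, 98.0))
        segs = auto_segment(subj, compute_phase_parameters(subj))
        assert {s.label for s in segs} == {"baseline"}

    def test_desaturation_slope_matches_generated_decline(self):
        # linear decline 98 -> 68 over [60, 360]: -0.1 %/s = -6 %/min
        t = np.arange(0.0, 601.0)
        knots_t = [0, 60, 360, 420, 600]
        knots_v = [98, 98, 68, 98, 98]
        mask = np.where((t >= 60) & (t < 360), 0.0, 1.0)
        subj = make_subject(t, np.interp(t, knots_t, knots_v), mask=mask)
        segs = auto_segment(subj, compute_phase_parameters(subj))
        desat = [s for s in segs if s.label == "desaturation"
                 and s.channel == "spo2"]
        assert len(desat) == 1
        assert desat[0].slope == pytest.approx(-6.0, rel=1e-9)
        assert desat[0].source == "automatic"

    def test_manual_fit_shares_window_semantics(self):
        subj = piecewise_subject()
        segs = auto_segment(subj, compute_phase_parameters(subj))
        ref = [s for s in segs if s.label == "desaturation"
               and s.channel == "spo2"][0]
        man = fit_segment_slope(subj.spo2, ref.t0, ref.t1, source="manual")
        assert man.slope == ref.slope and man.source == "manual"


# ---------------------------------------------------------------------------
# validity

class TestValidateRecord:
    def test_clean_synthetic_record_is_valid(self, clean_subject):
        rec, _ = clean_subject
        rep = validate_record(rec)
        assert rep.valid and rep.reasons == ()

    def test_long_gap_flagged(self):
        t = np.array([0, 1, 2, 3, 13, 14, 15], dtype=float)
        v = np.array([98, 96, 95, 94, 80, 79, 78], dtype=float)
        mask = np.array([1, 0, 0, 0, 0, 0, 1], dtype=float)
        rep = validate_record(make_subject(t, v, mask=mask),
                              AnalysisConfig(max_gap=5.0))
        assert not rep.valid and "gap_too_long" in rep.reasons

    def test_flat_trace_with_disconnection_flagged_unresponsive(self):
        t = np.arange(0.0, 300.0)
        mask = np.where((t >= 60) & (t < 200), 0.0, 1.0)
        rep = validate_record(make_subject(t, np.full_like(t, 98.0), mask=mask))
        assert rep.reasons == ("no_desaturation_response",)

    def test_missing_mask_events_flagged(self):
        subj = make_subject(np.arange(50.0), np.full(50, 98.0))
        rep = validate_record(subj)
        assert "mask_events_missing" in rep.reasons

    def test_out_of_range_spo2_flagged(self):
        t = np.arange(0.0, 300.0)
        v = np.full_like(t, 98.0)
        v[10] = 104.0
        mask = np.where((t >= 60) & (t < 200), 0.0, 1.0)
        v[(t >= 60) & (t < 200)] = 80.0
        rep = validate_record(make_subject(t, v, mask=mask))
        assert rep.reasons == ("out_of_range_values",)
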