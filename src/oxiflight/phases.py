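"""Decomposition of the SpO2 desaturation curve into its six phases.

The acute hypoxia test has a single canonical structure: the subject
breathes supplemental oxygen at a simulated altitude, disconnects the
mask at time DM, desaturates toward a nadir, reconnects at RM and
recovers.  Six durations characterise the SpO2 curve:

======  ==========================================================
DT      disconnection time, RM - DM (the hypoxia exposure)
DeD     desaturation delay: DM until SpO2 first falls below the
        desaturation threshold (default 97 %)
HD      hypoxia delay: DM until SpO2 first falls below the hypoxia
        threshold (default 90 %)
DeT     total dwell time with SpO2 below the desaturation threshold
        over the whole record
HT      total dwell time with SpO2 below the hypoxia threshold
RT      recovery time: RM until SpO2 first reaches the recovery
        threshold (default 97 %) again
======  ==========================================================

DT and RT are *censored* when the record ends before the event (mask
never reconnected, saturation never recovered); DeD and HD are
*undefined* when the threshold is never crossed.  All phase delays
reduce to one primitive, :func:`threshold_crossing_time`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .errors import ContractError, InsufficientDataError
from .records import SubjectRecord, TimeSeries

__all__ = [
    "PhaseValue",
    "MaskEvents",
    "PhaseParameters",
    "SegmentSlope",
    "TraceStats",
    "ValidityReport",
    "detect_mask_intervals",
    "threshold_crossing_time",
    "compute_phase_parameters",
    "fit_segment_slope",
    "auto_segment",
    "summarize_trace",
    "validate_record",
]


# ---------------------------------------------------------------------------
# result containers

@dataclass(frozen=True)
class PhaseValue:
    """One phase duration in seconds, which may be undefined or censored.

    ``value is None and not censored``  -> undefined (never crossed)
    ``censored``                        -> event not observed before the
    record (or exposure) ended; ``censoring_time`` is the duration
    observed up to that point.
    """

    value: float | None = None
    censored: bool = False
    censoring_time: float | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None and not self.censored

    def __float__(self) -> float:
        if not self.defined:
            raise ValueError("phase value is undefined or censored")
        return float(self.value)

    def to_dict(self) -> dict:
        return {"value": self.value, "censored": self.censored,
                "censoring_time": self.censoring_time}

    @classmethod
    def from_dict(cls, d: dict) -> "PhaseValue":
        return cls(d.get("value"), bool(d.get("censored", False)),
                   d.get("censoring_time"))


@dataclass(frozen=True)
class MaskEvents:
    """Disconnection/reconnection intervals of the oxygen mask.

    ``intervals`` holds ordered, non-overlapping pairs (DM, RM) in
    seconds; RM is None (censored) only for the last interval, when the
    record ends with the mask still off.
    """

    intervals: tuple[tuple[float, float | None], ...] = ()

    def __post_init__(self):
        prev_end = -math.inf
        for i, (dm, rm) in enumerate(self.intervals):
            if rm is None and i != len(self.intervals) - 1:
                raise ContractError("only the last interval may lack RM")
            if rm is not None and not dm < rm:
                raise ContractError(f"DM must precede RM (interval {i})")
            if dm <= prev_end:
                raise ContractError("intervals must be ordered, non-overlapping")
            prev_end = rm if rm is not None else math.inf

    @property
    def first(self) -> tuple[float, float | None] | None:
        return self.intervals[0] if self.intervals else None

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class PhaseParameters:
    """The six phase durations for one subject, with the thresholds used."""

    DT: PhaseValue = field(default_factory=PhaseValue)
    DeD: PhaseValue = field(default_factory=PhaseValue)
    HD: PhaseValue = field(default_factory=PhaseValue)
    DeT: PhaseValue = field(default_factory=PhaseValue)
    HT: PhaseValue = field(default_factory=PhaseValue)
    RT: PhaseValue = field(default_factory=PhaseValue)
    desat_threshold: float = 97.0
    hypoxia_threshold: float = 90.0
    recovery_threshold: float = 97.0

    NAMES = ("DT", "DeD", "HD", "DeT", "HT", "RT")

    def __post_init__(self):
        for name in self.NAMES:
            pv: PhaseValue = getattr(self, name)
            if pv.defined and pv.value < 0:
                raise ContractError(f"{name} must be >= 0, got {pv.value}")
        # ordering invariants hold only for canonically-ordered thresholds
        # (hypoxia below desaturation); nonstandard configs skip them
        if self.desat_threshold >= self.hypoxia_threshold:
            if (self.DeD.defined and self.HD.defined
                    and self.DeD.value > self.HD.value):
                raise ContractError("DeD cannot exceed HD")
            if (self.HT.defined and self.DeT.defined
                    and self.HT.value > self.DeT.value):
                raise ContractError("HT cannot exceed DeT")

    def __getitem__(self, name: str) -> PhaseValue:
        if name not in self.NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def to_dict(self) -> dict:
        d = {name: self[name].to_dict() for name in self.NAMES}
        d["thresholds"] = {
            "desat_threshold": self.desat_threshold,
            "hypoxia_threshold": self.hypoxia_threshold,
            "recovery_threshold": self.recovery_threshold,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhaseParameters":
        thr = d.get("thresholds", {})
        return cls(
            **{name: PhaseValue.from_dict(d[name]) for name in cls.NAMES},
            desat_threshold=thr.get("desat_threshold", 97.0),
            hypoxia_threshold=thr.get("hypoxia_threshold", 90.0),
            recovery_threshold=thr.get("recovery_threshold", 97.0),
        )


@dataclass(frozen=True)
class SegmentSlope:
    """OLS linear trend of one channel over a time window.

    Slope is reported per minute (%/min for SpO2, bpm/min for HR), the
    physiological convention for desaturation rates.  ``intercept`` is
    the fitted value at ``t0`` in channel units.
    """

    t0: float
    t1: float
    channel: str
    slope: float
    intercept: float
    r_squared: float
    n: int
    source: str = "automatic"       # "automatic" | "manual"
    label: str = ""

    def __post_init__(self):
        if not self.t0 < self.t1:
            raise ContractError("t0 must precede t1")
        if self.source not in ("automatic", "manual"):
            raise ContractError("source must be 'automatic' or 'manual'")


@dataclass(frozen=True)
class TraceStats:
    """Min / max / mean / slope of a channel over a window."""

    minimum: float
    maximum: float
    mean: float
    slope: float | None             # channel units per minute; None if <2 samples
    window: tuple[float, float]
    n: int


@dataclass(frozen=True)
class ValidityReport:
    """Outcome of the automatic record-quality check.

    Reasons are drawn from {gap_too_long, no_desaturation_response,
    mask_events_missing, out_of_range_values}; a record is valid iff the
    reason list is empty.
    """

    valid: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self):
        if self.valid != (len(self.reasons) == 0):
            raise ContractError("valid must equal (reasons empty)")


# ---------------------------------------------------------------------------
# operations

def detect_mask_intervals(mask: TimeSeries) -> MaskEvents:
    """Find maximal runs of mask == 0 (disconnected).

    DM is the time of the first 0 sample of a run; RM the time of the
    first 1 sample after it, or None (censored) if the record ends with
    the mask off.
    """
    if len(mask) == 0:
        raise ContractError("mask series is empty")
    vals = mask.values
    if np.any(np.isnan(vals)) or not np.isin(vals, (0.0, 1.0)).all():
        raise ContractError("mask values must be in {0, 1} with no missing")
    intervals: list[tuple[float, float | None]] = []
    dm: float | None = None
    for t, v in zip(mask.times, vals):
        if v == 0.0 and dm is None:
            dm = float(t)
        elif v == 1.0 and dm is not None:
            intervals.append((dm, float(t)))
            dm = None
    if dm is not None:
        intervals.append((dm, None))
    return MaskEvents(tuple(intervals))


def threshold_crossing_time(
    trace: TimeSeries,
    threshold: float,
    direction: str,
    anchor: float = 0.0,
    debounce: int = 1,
) -> float | None:
    """Time of the first debounced threshold crossing at or after ``anchor``.

    Scans samples with time >= anchor for the first run of at least
    ``debounce`` consecutive samples satisfying the condition — strictly
    ``< threshold`` for ``direction="below"``, ``>= threshold`` for
    ``direction="at_or_above"`` — and returns the time of the run's
    first sample, or None if no such run exists.  Missing samples never
    satisfy the condition and break runs.
    """
    if direction not in ("below", "at_or_above"):
        raise ValueError(f"direction must be 'below' or 'at_or_above', got {direction!r}")
    if debounce < 1:
        raise ValueError("debounce must be >= 1")
    if len(trace) == 0:
        raise ContractError("empty trace")
    t0, t1 = trace.span
    if not t0 <= anchor <= t1:
        raise ContractError(f"anchor {anchor} outside trace span [{t0}, {t1}]")

    m = trace.times >= anchor
    times = trace.times[m]
    vals = trace.values[m]
    with np.errstate(invalid="ignore"):
        ok = (vals < threshold) if direction == "below" else (vals >= threshold)
    ok &= ~np.isnan(vals)

    run = 0
    for i, good in enumerate(ok):
        run = run + 1 if good else 0
        if run >= debounce:
            return float(times[i - debounce + 1])
    return None


def _dwell_time(spo2: TimeSeries, threshold: float) -> float:
    """Total time with SpO2 strictly below ``threshold``.

    Each sub-threshold sample contributes its local inter-sample interval
    (time to the next sample); the last sample contributes the nominal dt.
    Missing samples contribute nothing.
    """
    if len(spo2) < 2:
        v = spo2.values
        return 0.0
    gaps = np.empty(len(spo2))
    gaps[:-1] = np.diff(spo2.times)
    gaps[-1] = spo2.dt
    with np.errstate(invalid="ignore"):
        below = (spo2.values < threshold) & ~np.isnan(spo2.values)
    return float(np.sum(gaps[below]))


def compute_phase_parameters(
    subject: SubjectRecord,
    config: AnalysisConfig = DEFAULT_CONFIG,
    mask_events: MaskEvents | None = None,
) -> PhaseParameters:
    """Compute the six phase parameters from the *first* disconnection.

    With no disconnection interval, every phase except the dwell times
    DeT/HT is undefined.  Protocols with several disconnection cycles
    have their later intervals reported by :func:`detect_mask_intervals`
    but are not phased here.
    """
    subject.check_alignment()
    if mask_events is None:
        mask_events = detect_mask_intervals(subject.mask)
    spo2 = subject.spo2
    thr = dict(
        desat_threshold=config.desat_threshold,
        hypoxia_threshold=config.hypoxia_threshold,
        recovery_threshold=config.recovery_threshold,
    )

    # dwell times over the whole record, independent of mask events
    det = PhaseValue(_dwell_time(spo2, config.desat_threshold))
    ht = PhaseValue(_dwell_time(spo2, config.hypoxia_threshold))

    first = mask_events.first
    if first is None:
        return PhaseParameters(DeT=det, HT=ht, **thr)

    dm, rm = first
    record_end = float(spo2.times[-1])

    if rm is None:
        dt_phase = PhaseValue(censored=True, censoring_time=record_end - dm)
    else:
        dt_phase = PhaseValue(rm - dm)

    def delay(threshold: float) -> PhaseValue:
        t = threshold_crossing_time(spo2, threshold, "below",
                                    anchor=dm, debounce=config.debounce)
        return PhaseValue(t - dm) if t is not None else PhaseValue()

    ded = delay(config.desat_threshold)
    hd = delay(config.hypoxia_threshold)

    if rm is None:
        rt = PhaseValue(censored=True, censoring_time=None)
    else:
        t = threshold_crossing_time(spo2, config.recovery_threshold,
                                    "at_or_above", anchor=rm,
                                    debounce=config.debounce)
        rt = (PhaseValue(t - rm) if t is not None
              else PhaseValue(censored=True, censoring_time=record_end - rm))

    return PhaseParameters(DT=dt_phase, DeD=ded, HD=hd, DeT=det, HT=ht,
                           RT=rt, **thr)


def fit_segment_slope(
    trace: TimeSeries,
    t0: float,
    t1: float,
    source: str = "automatic",
    label: str = "",
) -> SegmentSlope:
    """Ordinary-least-squares line over samples in the closed window [t0, t1].

    Slope is converted to channel units per minute.  The coefficient of
    determination is 1 whenever residuals are all zero — including the
    constant-trace case where total variance is zero.
    """
    if not t0 < t1:
        raise ContractError("t0 must precede t1")
    win = trace.window(t0, t1).dropna()
    if len(win) < 2:
        raise InsufficientDataError(
            f"need >= 2 non-missing samples in [{t0}, {t1}], found {len(win)}")

    t = win.times - t0
    y = win.values
    if np.ptp(y) == 0.0:
        # degenerate constant trace: OLS is exact with zero slope
        return SegmentSlope(t0=t0, t1=t1, channel=trace.channel_name,
                            slope=0.0, intercept=float(y[0]), r_squared=1.0,
                            n=len(win), source=source, label=label)
    slope_per_s, intercept = np.polyfit(t, y, 1)
    resid = y - (slope_per_s * t + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_res <= 1e-12 * max(ss_tot, 1.0):
        r2 = 1.0
    elif ss_tot == 0.0:
        r2 = 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return SegmentSlope(
        t0=t0, t1=t1, channel=trace.channel_name,
        slope=float(slope_per_s * 60.0), intercept=float(intercept),
        r_squared=float(r2), n=len(win), source=source, label=label,
    )


def auto_segment(
    subject: SubjectRecord,
    phases: PhaseParameters,
    mask_events: MaskEvents | None = None,
    channels: tuple[str, ...] = ("spo2", "hr"),
) -> list[SegmentSlope]:
    """Phase-anchored automatic segmentation: baseline, desaturation, recovery.

    Windows: baseline [record start, DM]; desaturation [DM, time of the
    SpO2 minimum within the disconnection interval]; recovery
    [RM, RM + RT].  Windows whose endpoints are undefined or censored,
    or which hold fewer than two samples, are skipped.
    """
    if mask_events is None:
        mask_events = detect_mask_intervals(subject.mask)
    start = float(subject.times[0])
    end = float(subject.times[-1])

    windows: list[tuple[str, float, float]] = []
    first = mask_events.first
    if first is None:
        windows.append(("baseline", start, end))
    else:
        dm, rm = first
        if dm > start:
            windows.append(("baseline", start, dm))
        # SpO2 minimum within the disconnection interval marks the nadir
        hi = rm if rm is not None else end
        desat = subject.spo2.window(dm, hi).dropna()
        if len(desat):
            t_nadir = float(desat.times[int(np.argmin(desat.values))])
            if t_nadir > dm:
                windows.append(("desaturation", dm, t_nadir))
        if rm is not None and phases.RT.defined and phases.RT.value > 0:
            windows.append(("recovery", rm, min(rm + phases.RT.value, end)))

    out: list[SegmentSlope] = []
    for label, a, b in windows:
        for ch in channels:
            try:
                out.append(fit_segment_slope(subject.channel(ch), a, b,
                                             source="automatic", label=label))
            except InsufficientDataError:
                continue
    return out


def summarize_trace(
    trace: TimeSeries,
    window: tuple[float, float] | None = None,
) -> TraceStats:
    """Min/max/mean and OLS slope over a window (whole record if None)."""
    if window is None:
        if len(trace) == 0:
            raise InsufficientDataError("empty trace")
        window = trace.span
    t0, t1 = window
    win = trace.window(t0, t1).dropna()
    if len(win) == 0:
        raise InsufficientDataError(f"no non-missing samples in [{t0}, {t1}]")
    slope = None
    if len(win) >= 2 and t0 < t1:
        slope = fit_segment_slope(trace, t0, t1).slope
    return TraceStats(
        minimum=float(win.values.min()),
        maximum=float(win.values.max()),
        mean=float(win.values.mean()),
        slope=slope,
        window=(float(t0), float(t1)),
        n=len(win),
    )


def validate_record(
    subject: SubjectRecord,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> ValidityReport:
    """Automatic proxy for the visual record-validity inspection.

    Checks recording continuity (no inter-sample gap above ``max_gap``),
    presence of a mask disconnection, a physiological desaturation
    response after disconnection (SpO2 falls by at least
    ``response_drop`` % within ``response_window`` s of DM), and SpO2
    staying within [0, 100].
    """
    reasons: list[str] = []
    t = subject.times
    if len(t) >= 2 and float(np.max(np.diff(t))) > config.max_gap:
        reasons.append("gap_too_long")

    spo2 = subject.spo2.values
    finite = spo2[~np.isnan(spo2)]
    if finite.size and (finite.min() < 0 or finite.max() > 100):
        reasons.append("out_of_range_values")

    events = detect_mask_intervals(subject.mask)
    if len(events) == 0:
        reasons.append("mask_events_missing")
    else:
        dm, _ = events.first
        # baseline: last non-missing sample strictly before disconnection
        pre_m = (subject.spo2.times < dm) & ~np.isnan(subject.spo2.values)
        post = subject.spo2.window(dm, dm + config.response_window).dropna()
        baseline = float(subject.spo2.values[pre_m][-1]) if pre_m.any() else (
            float(post.values[0]) if len(post) else math.nan)
        if not len(post) or math.isnan(baseline) or (
                baseline - float(post.values.min()) < config.response_drop):
            reasons.append("no_desaturation_response")

    return ValidityReport(valid=not reasons, reasons=tuple(reasons))
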