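"""Synthetic hypoxia-test flight records with analytic ground truth.

The generator emulates what a chamber pulse-oximetry chain records during
an acute hypoxia test: SpO2 sits at a 97–99 % baseline while the subject
breathes supplemental oxygen, falls after mask disconnection (DM) with a
short circulatory lag and exponential kinetics toward a nadir near 60 %
(the typical saturation floor at a simulated 25,000 ft), then recovers
exponentially after reconnection (RM); heart rate mirrors the
desaturation with a sympathetically-driven rise.  Gaussian sensor noise,
integer quantization (oximeters report whole percent / whole bpm) and
Bernoulli sample dropouts are layered on top.

Ground-truth phase durations are obtained by inverting the exponential
threshold crossings in closed form and snapping to the sample grid —
*before* noise and dropouts are applied — so recovery of the phases by
the analysis pipeline can be checked against an independent analytic
route.  When quantization is on, the emitted integer signal crosses an
integer threshold c where the continuous signal crosses ceil(c) - 0.5,
and the inversion uses that effective threshold: the ground truth
describes the record actually emitted.

Exponential approach kinetics are used for both desaturation and
recovery because they are smooth, monotone and analytically invertible;
real desaturation curves are more nearly sigmoid near onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .errors import ContractError
from .phases import PhaseParameters, PhaseValue
from .records import FlightRecord, SubjectRecord, TimeSeries

__all__ = [
    "SyntheticParams",
    "ParamSpread",
    "generate_subject",
    "generate_flight",
]


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of one synthetic subject's recording.

    Times are seconds from record start; DM/RM are mask disconnection
    and reconnection (RM None = never reconnected, censored exposure).
    ``desat_delay`` is the circulatory lag between disconnection and the
    onset of the SpO2 decline; ``desat_tau`` / ``recovery_tau`` are the
    exponential time constants of the decline toward ``nadir_spo2`` and
    the recovery back toward ``baseline_spo2``.
    """

    duration: float = 600.0
    dt: float = 1.0
    DM: float = 60.0
    RM: float | None = 360.0
    baseline_spo2: float = 98.0
    nadir_spo2: float = 60.0
    desat_delay: float = 10.0
    desat_tau: float = 60.0
    recovery_tau: float = 15.0
    baseline_hr: float = 70.0
    hr_rise: float = 40.0
    noise_sd_spo2: float = 1.0
    noise_sd_hr: float = 2.0
    dropout_prob: float = 0.005
    quantize: bool = True
    include_altitude: bool = True
    altitude_ft: float = 25000.0
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ContractError("dt must be positive")
        if self.duration < 2 * self.dt:
            raise ContractError("duration too short")
        if not 0 < self.nadir_spo2 < self.baseline_spo2 <= 100:
            raise ContractError(
                "need 0 < nadir_spo2 < baseline_spo2 <= 100")
        if not 0 <= self.DM < self.duration:
            raise ContractError("DM must lie within the record")
        if self.RM is not None and not self.DM < self.RM:
            raise ContractError("DM must precede RM")
        if self.desat_tau <= 0 or self.recovery_tau <= 0:
            raise ContractError("time constants must be positive")
        if self.desat_delay < 0:
            raise ContractError("desat_delay must be >= 0")
        for name in ("noise_sd_spo2", "noise_sd_hr"):
            if getattr(self, name) < 0:
                raise ContractError(f"{name} must be >= 0")
        if not 0 <= self.dropout_prob < 1:
            raise ContractError("dropout_prob must be in [0, 1)")


# ---------------------------------------------------------------------------
# noiseless signal model

def _spo2_noiseless(p: SyntheticParams, t: np.ndarray) -> np.ndarray:
    s = np.full(t.shape, p.baseline_spo2)
    t0 = p.DM + p.desat_delay                   # decline onset
    rm = p.RM if p.RM is not None else math.inf
    amp = p.baseline_spo2 - p.nadir_spo2
    if t0 < rm:
        decl = (t >= t0) & (t < rm)
        s[decl] = p.nadir_spo2 + amp * np.exp(-(t[decl] - t0) / p.desat_tau)
    if p.RM is not None:
        s_rm = _spo2_at_rm(p)
        rec = t >= p.RM
        s[rec] = p.baseline_spo2 + (s_rm - p.baseline_spo2) * np.exp(
            -(t[rec] - p.RM) / p.recovery_tau)
    return s


def _spo2_at_rm(p: SyntheticParams) -> float:
    t0 = p.DM + p.desat_delay
    if p.RM is None or p.RM <= t0:
        return p.baseline_spo2
    amp = p.baseline_spo2 - p.nadir_spo2
    return p.nadir_spo2 + amp * math.exp(-(p.RM - t0) / p.desat_tau)


def _below_interval(p: SyntheticParams, c: float) -> tuple[float, float] | None:
    """Open interval (t_lo, t_hi) on which the noiseless SpO2 is strictly
    below ``c``, or None if it never is.  t_hi = inf when saturation
    never climbs back above c before the model's asymptote."""
    t0 = p.DM + p.desat_delay
    rm = p.RM
    if p.baseline_spo2 < c:
        return (-math.inf, math.inf)
    if p.baseline_spo2 == c:
        # strictly below only once the decline starts; recovery approaches
        # the baseline asymptotically and never reaches it
        return (t0, math.inf) if (rm is None or t0 < rm) else None
    if c <= p.nadir_spo2:
        return None                                 # decline never gets there
    amp = p.baseline_spo2 - p.nadir_spo2
    t_lo = t0 + p.desat_tau * math.log(amp / (c - p.nadir_spo2))
    if rm is not None and t_lo >= rm:
        return None                                 # reconnected first
    if rm is None:
        return (t_lo, math.inf)
    s_rm = _spo2_at_rm(p)
    t_hi = rm + p.recovery_tau * math.log(
        (p.baseline_spo2 - s_rm) / (p.baseline_spo2 - c))
    return (t_lo, t_hi)


def _eff(threshold: float, quantize: bool) -> float:
    """Effective continuous threshold for the emitted signal: an integer
    reading is < c (resp. >= c) exactly where the continuous signal is
    below (resp. at or above) ceil(c) - 0.5."""
    return math.ceil(threshold) - 0.5 if quantize else threshold


_EPS = 1e-9


def _ground_truth(p: SyntheticParams, t: np.ndarray,
                  config: AnalysisConfig) -> PhaseParameters:
    """Analytic phase parameters of the emitted noiseless record."""
    end = float(t[-1])
    thr = dict(desat_threshold=config.desat_threshold,
               hypoxia_threshold=config.hypoxia_threshold,
               recovery_threshold=config.recovery_threshold)

    # grid-snapped mask events, as ingestion will see them
    dm_g = float(t[t >= p.DM - _EPS][0])
    rm_g = None
    if p.RM is not None:
        after = t[t >= p.RM - _EPS]
        if len(after):
            rm_g = float(after[0])

    def first_sample_after(x: float, strict: bool) -> float | None:
        cand = t[t > x + _EPS] if strict else t[t >= x - _EPS]
        return float(cand[0]) if len(cand) else None

    def delay(c: float) -> PhaseValue:
        iv = _below_interval(p, _eff(c, p.quantize))
        if iv is None:
            return PhaseValue()
        # first grid sample at/after DM lying strictly inside the interval
        cand = t[(t >= dm_g - _EPS) & (t > iv[0] + _EPS) & (t < iv[1] - _EPS)]
        if not len(cand):
            return PhaseValue()
        return PhaseValue(float(cand[0]) - dm_g)

    def dwell(c: float) -> PhaseValue:
        iv = _below_interval(p, _eff(c, p.quantize))
        if iv is None:
            return PhaseValue(0.0)
        count = int(np.sum((t > iv[0] + _EPS) & (t < iv[1] - _EPS)))
        return PhaseValue(count * p.dt)

    det, ht = dwell(config.desat_threshold), dwell(config.hypoxia_threshold)
    ded, hd = delay(config.desat_threshold), delay(config.hypoxia_threshold)

    if rm_g is None:
        dt_phase = PhaseValue(censored=True,
                              censoring_time=end - dm_g if dm_g <= end else None)
        rt = PhaseValue(censored=True)
    else:
        dt_phase = PhaseValue(rm_g - dm_g)
        c_eff = _eff(config.recovery_threshold, p.quantize)
        s_rm = _spo2_at_rm(p)
        if p.baseline_spo2 < c_eff:
            rt = PhaseValue(censored=True, censoring_time=end - rm_g)
        else:
            if s_rm >= c_eff:
                t_up = p.RM
            else:
                t_up = p.RM + p.recovery_tau * math.log(
                    (p.baseline_spo2 - s_rm) / (p.baseline_spo2 - c_eff))
            g = first_sample_after(max(t_up, rm_g), strict=False)
            rt = (PhaseValue(g - rm_g) if g is not None
                  else PhaseValue(censored=True, censoring_time=end - rm_g))
    return PhaseParameters(DT=dt_phase, DeD=ded, HD=hd, DeT=det, HT=ht,
                           RT=rt, **thr)


# ---------------------------------------------------------------------------
# generation

def generate_subject(
    params: SyntheticParams,
    subject_id: str = "S01",
    config: AnalysisConfig = DEFAULT_CONFIG,
    age: float | None = None,
    sex: str | None = None,
    station: int | None = None,
) -> tuple[SubjectRecord, PhaseParameters]:
    """Generate one subject's record plus its analytic ground-truth phases.

    The same seed yields bit-identical output.  Ground truth is computed
    on the noiseless signal (post-quantization semantics, pre-noise);
    with noise or dropouts enabled the pipeline's estimates will scatter
    around it.
    """
    p = params
    n = int(math.floor(p.duration / p.dt)) + 1
    t = np.arange(n) * p.dt

    s = _spo2_noiseless(p, t)
    amp = p.baseline_spo2 - p.nadir_spo2
    hr = p.baseline_hr + p.hr_rise * (p.baseline_spo2 - s) / amp

    truth = _ground_truth(p, t, config)

    rng = np.random.default_rng(np.random.SeedSequence(p.seed))
    if p.noise_sd_spo2 > 0:
        s = s + rng.normal(0.0, p.noise_sd_spo2, n)
    if p.noise_sd_hr > 0:
        hr = hr + rng.normal(0.0, p.noise_sd_hr, n)
    if p.quantize:
        s, hr = np.rint(s), np.rint(hr)
    s = np.clip(s, 0.0, 100.0)
    hr = np.clip(hr, 0.0, None)
    if p.dropout_prob > 0:
        drop = rng.random(n) < p.dropout_prob
        s[drop] = np.nan
        hr[drop] = np.nan

    rm = p.RM if p.RM is not None else math.inf
    mask = np.where((t >= p.DM - _EPS) & (t < rm - _EPS), 0.0, 1.0)

    altitude = None
    if p.include_altitude:
        ramp = min(120.0, p.duration / 4)
        alt = np.minimum.reduce([
            np.full(n, p.altitude_ft),
            t * (p.altitude_ft / ramp),
            (p.duration - t) * (p.altitude_ft / ramp),
        ])
        altitude = TimeSeries(t, np.maximum(alt, 0.0), "altitude")

    record = SubjectRecord(
        subject_id=subject_id,
        spo2=TimeSeries(t, s, "spo2"),
        hr=TimeSeries(t, hr, "hr"),
        mask=TimeSeries(t, mask, "mask"),
        altitude=altitude,
        age=age, sex=sex, station=station,
    )
    return record, truth


@dataclass(frozen=True)
class ParamSpread:
    """Between-subject SDs for the jittered physiological parameters.

    Defaults reflect typical inter-individual variability in hypoxia
    tests: about half a percent of baseline spread, several percent of
    nadir spread, and broad variation in decline/recovery kinetics.
    Mask events (DM, RM) are shared by the whole crew — the protocol
    disconnects everyone together — so they are not jittered.
    """

    baseline_spo2: float = 0.5
    nadir_spo2: float = 3.0
    desat_delay: float = 3.0
    desat_tau: float = 10.0
    recovery_tau: float = 4.0
    baseline_hr: float = 8.0
    hr_rise: float = 10.0


def _jitter(base: SyntheticParams, spread: ParamSpread,
            rng: np.random.Generator, seed: int) -> SyntheticParams:
    def draw(value, sd, lo=None, hi=None):
        v = value + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        if lo is not None:
            v = max(v, lo)
        if hi is not None:
            v = min(v, hi)
        return v

    baseline = draw(base.baseline_spo2, spread.baseline_spo2, 95.0, 100.0)
    nadir = draw(base.nadir_spo2, spread.nadir_spo2, 40.0, baseline - 10.0)
    return replace(
        base,
        baseline_spo2=baseline,
        nadir_spo2=nadir,
        desat_delay=draw(base.desat_delay, spread.desat_delay, 0.0),
        desat_tau=draw(base.desat_tau, spread.desat_tau, 5.0),
        recovery_tau=draw(base.recovery_tau, spread.recovery_tau, 2.0),
        baseline_hr=draw(base.baseline_hr, spread.baseline_hr, 40.0),
        hr_rise=draw(base.hr_rise, spread.hr_rise, 0.0),
        seed=seed,
    )


def generate_flight(
    n_subjects: int,
    base_params: SyntheticParams = SyntheticParams(),
    spread: ParamSpread = ParamSpread(),
    seed: int = 0,
    flight_id: str = "FLT001",
    datetime: str = "2023-01-10T09:00:00",
    protocol: str = "acute hypoxia test 25000 ft",
    flight_type: str = "day_only",
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[FlightRecord, dict[tuple[str, str], PhaseParameters]]:
    """Generate a whole flight of jittered subjects.

    Per-subject parameters and noise streams are derived from spawned
    child seeds, so increasing ``n_subjects`` never perturbs earlier
    subjects.  Returns the FlightRecord and the ground-truth phases
    keyed by (flight_id, subject_id).
    """
    if n_subjects < 1:
        raise ContractError("n_subjects must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    subjects, truths = [], {}
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sid = f"S{i + 1:02d}"
        p = _jitter(base_params, spread, rng,
                    seed=int(rng.integers(0, 2**31 - 1)))
        age = float(np.round(rng.uniform(22, 45), 1))
        sex = "F" if rng.random() < 0.3 else "M"
        rec, truth = generate_subject(p, subject_id=sid, config=config,
                                      age=age, sex=sex, station=i + 1)
        subjects.append(rec)
        truths[(flight_id, sid)] = truth
    flight = FlightRecord(flight_id=flight_id, datetime=datetime,
                          protocol=protocol, flight_type=flight_type,
                          subjects=subjects)
    return flight, truths
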