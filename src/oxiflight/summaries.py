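"""Group-level analysis: aligned matrices, group curves, heat maps and
descriptive statistics.

Subjects are aligned on a common grid — by default anchored at mask
disconnection (DM = 0), since the phenomenon of interest is the
post-disconnection desaturation response — and summarised per timepoint
with pairwise-available data: every timepoint uses all subjects that
cover it, and ``n_per_timepoint`` makes the coverage auditable.
Quantiles (Q1/Q3 and the median) use the linear-interpolation
convention.  Rendering is a thin optional layer: every plot is backed by
a numeric matrix that tests (and CSV exports) target directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, InsufficientDataError
from .phases import (PhaseParameters, TraceStats, detect_mask_intervals)
from .records import SubjectRecord

__all__ = [
    "AlignedMatrix",
    "GroupCurve",
    "align_and_resample",
    "group_curve",
    "heatmap_matrix",
    "HeatmapData",
    "descriptive_summary",
    "phase_table",
]


@dataclass(frozen=True)
class AlignedMatrix:
    """Subjects x timepoints matrix of one channel on a common grid.

    ``grid`` is in seconds relative to the chosen anchor (DM = 0 for
    disconnection anchoring); cells outside a subject's coverage are NaN.
    """

    grid: np.ndarray
    values: np.ndarray
    subject_ids: tuple[str, ...]
    channel: str
    anchor: str

    def __post_init__(self):
        if self.values.shape != (len(self.subject_ids), len(self.grid)):
            raise ContractError("values shape must be (n_subjects, n_timepoints)")
        if len(self.grid) > 1 and np.any(np.diff(self.grid) <= 0):
            raise ContractError("grid must be increasing")

    @property
    def n_per_timepoint(self) -> np.ndarray:
        return (~np.isnan(self.values)).sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.subject_ids),
                            columns=self.grid)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = self.to_dataframe()
        df.index.name = "subject_id"
        df.to_csv(path, float_format="%.10g")
        return path


@dataclass(frozen=True)
class GroupCurve:
    """Per-timepoint central tendency and dispersion of an aligned cohort."""

    grid: np.ndarray
    center: np.ndarray
    dispersion_low: np.ndarray
    dispersion_high: np.ndarray
    method: str                      # "mean_sd" | "median_iqr"
    n_per_timepoint: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.grid,
            "center": self.center,
            "dispersion_low": self.dispersion_low,
            "dispersion_high": self.dispersion_high,
            "n": self.n_per_timepoint,
        })

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")
        return path


def _anchor_time(subject: SubjectRecord, anchor: str) -> float:
    if anchor == "record_start":
        return float(subject.times[0])
    if anchor == "disconnection":
        events = detect_mask_intervals(subject.mask)
        if events.first is None:
            raise ContractError(
                f"subject {subject.subject_id!r} has no mask disconnection; "
                "cannot anchor at disconnection")
        return events.first[0]
    raise ValueError(f"anchor must be 'disconnection' or 'record_start', "
                     f"got {anchor!r}")


def align_and_resample(
    subjects: Sequence[SubjectRecord],
    channel: str = "spo2",
    anchor: str = "disconnection",
    dt_out: float = 1.0,
    subject_ids: Sequence[str] | None = None,
) -> AlignedMatrix:
    """Shift each subject so the anchor maps to t = 0 and linearly
    interpolate onto a common uniform grid of step ``dt_out``.

    The grid spans the union of subject coverage; timepoints outside a
    subject's span are NaN.  Missing samples are bridged by the
    interpolation (they are dropped before interpolating).
    ``subject_ids`` overrides row labels, e.g. to disambiguate the same
    crew member across flights.
    """
    if not len(subjects):
        raise ContractError("empty subject list")
    if dt_out <= 0:
        raise ContractError("dt_out must be positive")

    shifted = []
    for subj in subjects:
        a = _anchor_time(subj, anchor)
        ts = subj.channel(channel).dropna()
        if len(ts) == 0:
            raise InsufficientDataError(
                f"subject {subj.subject_id!r}: channel {channel!r} all missing")
        shifted.append((ts.times - a, ts.values))

    lo = min(t[0] for t, _ in shifted)
    hi = max(t[-1] for t, _ in shifted)
    # grid on multiples of dt_out so identical subjects land on identical cells
    k0 = int(np.ceil(lo / dt_out - 1e-9))
    k1 = int(np.floor(hi / dt_out + 1e-9))
    grid = np.arange(k0, k1 + 1) * dt_out

    values = np.full((len(subjects), len(grid)), np.nan)
    for i, (t, v) in enumerate(shifted):
        inside = (grid >= t[0] - 1e-9) & (grid <= t[-1] + 1e-9)
        values[i, inside] = np.interp(grid[inside], t, v)

    ids = tuple(subject_ids) if subject_ids is not None else tuple(
        s.subject_id for s in subjects)
    if len(ids) != len(subjects):
        raise ContractError("subject_ids length mismatch")
    return AlignedMatrix(grid=grid, values=values, subject_ids=ids,
                         channel=channel, anchor=anchor)


def group_curve(matrix: AlignedMatrix, method: str = "mean_sd") -> GroupCurve:
    """Per-timepoint mean±SD or median±IQR over non-missing entries.

    SD is the sample standard deviation (ddof = 1), defined as 0 when a
    timepoint has a single contributing subject.  Q1/Q3 use linear
    interpolation.
    """
    if matrix.values.shape[0] < 1:
        raise ContractError("need >= 1 subject row")
    v = matrix.values
    n = matrix.n_per_timepoint.astype(float)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN timepoints
        if method == "mean_sd":
            center = np.where(n >= 1, np.nansum(v, axis=0) / np.where(n, n, 1),
                              np.nan)
            sd = np.full(v.shape[1], np.nan)
            multi = n >= 2
            if multi.any():
                sd[multi] = np.nanstd(v[:, multi], axis=0, ddof=1)
            sd[n == 1] = 0.0
            low, high = center - sd, center + sd
        elif method == "median_iqr":
            center = np.nanmedian(v, axis=0)
            low = np.nanpercentile(v, 25, axis=0, method="linear")
            high = np.nanpercentile(v, 75, axis=0, method="linear")
        else:
            raise ValueError(f"method must be 'mean_sd' or 'median_iqr', "
                             f"got {method!r}")
    return GroupCurve(grid=matrix.grid, center=center, dispersion_low=low,
                      dispersion_high=high, method=method,
                      n_per_timepoint=matrix.n_per_timepoint)


@dataclass(frozen=True)
class HeatmapData:
    """Heat-map payload: the aligned matrix plus colour-scale bounds."""

    matrix: AlignedMatrix
    vmin: float
    vmax: float

    def render(self, path: str | Path, cmap: str = "viridis") -> Path:
        """Write a PNG/SVG image; rendering never mutates the data."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        m = self.matrix
        fig, ax = plt.subplots(figsize=(8, max(2.0, 0.3 * len(m.subject_ids))))
        extent = (float(m.grid[0]), float(m.grid[-1]),
                  len(m.subject_ids) - 0.5, -0.5)
        im = ax.imshow(m.values, aspect="auto", interpolation="nearest",
                       vmin=self.vmin, vmax=self.vmax, cmap=cmap,
                       extent=extent)
        ax.set_yticks(range(len(m.subject_ids)))
        ax.set_yticklabels(m.subject_ids)
        ax.set_xlabel(f"time from {m.anchor} (s)")
        fig.colorbar(im, ax=ax, label=m.channel)
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)
        return Path(path)


#: default colour-scale bounds per channel; HR is data-driven
SPO2_SCALE = (60.0, 100.0)


def heatmap_matrix(
    matrix: AlignedMatrix,
    value_range: tuple[float, float] | None = None,
) -> HeatmapData:
    """Package an aligned matrix for heat-map display.

    SpO2 defaults to the [60, 100] % scale spanning baseline to the
    deepest expected nadir; other channels default to data-driven bounds.
    """
    if matrix.values.shape[0] < 1:
        raise ContractError("need >= 1 subject row")
    if value_range is None:
        if matrix.channel == "spo2":
            value_range = SPO2_SCALE
        else:
            finite = matrix.values[~np.isnan(matrix.values)]
            if finite.size == 0:
                raise InsufficientDataError("matrix entirely missing")
            value_range = (float(finite.min()), float(finite.max()))
    return HeatmapData(matrix=matrix, vmin=float(value_range[0]),
                       vmax=float(value_range[1]))


# ---------------------------------------------------------------------------
# descriptive summary table

def phase_table(
    phases_by_subject: Mapping[tuple[str, str], PhaseParameters],
    stats_by_subject: Mapping[tuple[str, str], Mapping[str, TraceStats]] | None = None,
) -> pd.DataFrame:
    """One row per subject; phase durations (NaN if undefined/censored),
    per-phase censored flags, and optional per-channel trace stats."""
    rows = []
    for (fid, sid), ph in phases_by_subject.items():
        row: dict = {"flight_id": fid, "subject_id": sid}
        for name in PhaseParameters.NAMES:
            pv = ph[name]
            row[name] = pv.value if pv.defined else np.nan
            row[f"{name}_censored"] = pv.censored
        if stats_by_subject is not None:
            for ch, st in stats_by_subject.get((fid, sid), {}).items():
                row[f"{ch}_min"] = st.minimum
                row[f"{ch}_max"] = st.maximum
                row[f"{ch}_mean"] = st.mean
                row[f"{ch}_slope_per_min"] = st.slope
        rows.append(row)
    return pd.DataFrame(rows)


def descriptive_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics per variable over defined, non-censored values.

    Returns one row per numeric variable with n, mean, SD (ddof = 1, NaN
    for n = 1), median, Q1, Q3 (linear interpolation), min, max, and the
    count of censored values for phase parameters.
    """
    if not len(table):
        raise ContractError("empty phase table")
    out = []
    skip = {"flight_id", "subject_id"}
    for col in table.columns:
        if col in skip or col.endswith("_censored"):
            continue
        vals = pd.to_numeric(table[col], errors="coerce").dropna().to_numpy()
        cens_col = f"{col}_censored"
        censored = int(table[cens_col].sum()) if cens_col in table.columns else 0
        if len(vals):
            row = {
                "variable": col,
                "n": len(vals),
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                "median": float(np.median(vals)),
                "q1": float(np.percentile(vals, 25, method="linear")),
                "q3": float(np.percentile(vals, 75, method="linear")),
                "min": float(np.min(vals)),
                "max": float(np.max(vals)),
                "censored_count": censored,
            }
        else:
            row = {"variable": col, "n": 0, "mean": np.nan, "sd": np.nan,
                   "median": np.nan, "q1": np.nan, "q3": np.nan,
                   "min": np.nan, "max": np.nan, "censored_count": censored}
        out.append(row)
    return pd.DataFrame(out).set_index("variable")
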