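"""Core in-memory containers for hypoxia-test flight recordings.

A recording is organised as ``Sample`` -> ``FlightRecord`` ->
``SubjectRecord`` -> ``TimeSeries``.  Each subject carries three mandatory
channels on a shared time grid — SpO2 (%), heart rate (bpm) and the oxygen
mask connection state (1 = connected, 0 = disconnected) — plus an optional
chamber altitude profile in feet.  Missing measurements are NaN; the mask
channel is a step signal and never missing after ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import ContractError

__all__ = [
    "TimeSeries",
    "SubjectRecord",
    "FlightRecord",
    "Sample",
    "CHANNELS",
]

#: canonical channel labels, in file-column order
CHANNELS = ("spo2", "hr", "mask", "altitude")


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly-intended timestamped samples of one physiological channel.

    Parameters
    ----------
    times
        Seconds from record start; non-negative, strictly increasing.
    values
        Channel measurements: SpO2 in percent, HR in bpm, altitude in
        feet, or mask state in {0, 1}.  NaN marks a missing sample.
    channel_name
        Label, usually one of :data:`CHANNELS`.
    """

    times: np.ndarray
    values: np.ndarray
    channel_name: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1:
            raise ContractError("times and values must be 1-D")
        if len(t) != len(v):
            raise ContractError(
                f"times ({len(t)}) and values ({len(v)}) differ in length")
        if len(t) and np.any(np.diff(t) <= 0):
            i = int(np.argmax(np.diff(t) <= 0))
            raise ContractError(
                f"times must be strictly increasing (violated at index {i + 1})")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        """Nominal sampling interval: median of successive time differences."""
        if len(self.times) < 2:
            raise ContractError("dt undefined for series with < 2 samples")
        return float(np.median(np.diff(self.times)))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def window(self, t0: float, t1: float) -> "TimeSeries":
        """Samples with t0 <= time <= t1 (closed window)."""
        m = (self.times >= t0) & (self.times <= t1)
        return TimeSeries(self.times[m], self.values[m], self.channel_name)

    def dropna(self) -> "TimeSeries":
        m = ~np.isnan(self.values)
        return TimeSeries(self.times[m], self.values[m], self.channel_name)

    def equals(self, other: "TimeSeries") -> bool:
        return (
            len(self) == len(other)
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.values, other.values, equal_nan=True)
            and self.channel_name == other.channel_name
        )


@dataclass
class SubjectRecord:
    """One crew member's channels and metadata for a single flight."""

    subject_id: str
    spo2: TimeSeries
    hr: TimeSeries
    mask: TimeSeries
    altitude: TimeSeries | None = None
    age: float | None = None
    sex: str | None = None          # "F", "M" or None (unspecified)
    station: int | None = None
    valid_override: bool | None = None  # manual validity flag from metadata

    def __post_init__(self):
        if not self.subject_id:
            raise ContractError("subject_id must be non-empty")
        if self.sex is not None and self.sex not in ("F", "M"):
            raise ContractError(f"sex must be 'F', 'M' or None, got {self.sex!r}")
        self.check_alignment()

    def check_alignment(self) -> None:
        """All mandatory channels must share the same time grid."""
        for ch in (self.hr, self.mask):
            if not np.array_equal(self.spo2.times, ch.times):
                raise ContractError(
                    f"channel '{ch.channel_name}' is not aligned with spo2")
        bad = ~np.isin(self.mask.values[~np.isnan(self.mask.values)], (0.0, 1.0))
        if bad.any():
            raise ContractError("mask values must be in {0, 1}")

    @property
    def times(self) -> np.ndarray:
        return self.spo2.times

    def channel(self, name: str) -> TimeSeries:
        if name not in ("spo2", "hr", "mask", "altitude"):
            raise KeyError(name)
        ts = getattr(self, name)
        if ts is None:
            raise KeyError(f"subject {self.subject_id} has no '{name}' channel")
        return ts

    def equals(self, other: "SubjectRecord") -> bool:
        same_alt = (
            (self.altitude is None and other.altitude is None)
            or (self.altitude is not None and other.altitude is not None
                and self.altitude.equals(other.altitude))
        )
        return (
            self.subject_id == other.subject_id
            and self.age == other.age
            and self.sex == other.sex
            and self.station == other.station
            and self.spo2.equals(other.spo2)
            and self.hr.equals(other.hr)
            and self.mask.equals(other.mask)
            and same_alt
        )


@dataclass
class FlightRecord:
    """One chamber flight: identifying metadata plus the subjects on board."""

    flight_id: str
    datetime: str               # ISO-8601 wall-clock of the activity
    protocol: str
    flight_type: str
    subjects: list[SubjectRecord] = field(default_factory=list)

    def __post_init__(self):
        if not self.flight_id:
            raise ContractError("flight_id must be non-empty")
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise ContractError("subject_ids must be distinct within a flight")

    def equals(self, other: "FlightRecord") -> bool:
        return (
            self.flight_id == other.flight_id
            and self.datetime == other.datetime
            and self.protocol == other.protocol
            and self.flight_type == other.flight_type
            and len(self.subjects) == len(other.subjects)
            and all(a.equals(b) for a, b in zip(self.subjects, other.subjects))
        )


@dataclass
class Sample:
    """An ordered collection of flights selected for joint analysis."""

    flights: list[FlightRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [f.flight_id for f in self.flights]
        if len(ids) != len(set(ids)):
            raise ContractError("flight_ids must be pairwise distinct")

    @property
    def flight_ids(self) -> list[str]:
        return [f.flight_id for f in self.flights]

    def subjects(self) -> Iterable[tuple[FlightRecord, SubjectRecord]]:
        for fl in self.flights:
            for subj in fl.subjects:
                yield fl, subj

    def __len__(self) -> int:
        return len(self.flights)
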