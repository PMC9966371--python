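"""Declarative cohort selection over multi-flight samples.

A :class:`FilterSpec` combines subject-attribute constraints (identity,
age, sex), a mask-connection constraint, per-phase-parameter numeric
ranges and a flight-type selection.  All specified criteria are combined
by conjunction (AND): a subject is kept only if it satisfies every one,
which is the natural semantics for progressively delimiting a study
sample.  Omitted criteria impose no constraint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

from .errors import FilterSpecError
from .phases import PhaseParameters, ValidityReport
from .records import FlightRecord, Sample, SubjectRecord

__all__ = [
    "FLIGHT_TYPES",
    "FilterSpec",
    "apply_filters",
    "save_filters",
    "load_filters",
    "combine_specs",
]

FILTER_FORMAT_VERSION = "1.0"

#: recognised flight-type selections; all but "total"/"valid" are matched
#: case-insensitively against the flight's free-text flight_type label
FLIGHT_TYPES = ("total", "valid", "day_and_night", "day_only",
                "decompression", "medical")

PHASE_NAMES = PhaseParameters.NAMES


@dataclass(frozen=True)
class FilterSpec:
    """Cohort-selection criteria; every field is optional except flight_type.

    ``phase_ranges`` maps a phase name in {DT, DeD, HD, DeT, HT, RT} to an
    inclusive (min, max) range in seconds; either bound may be None for
    half-open ranges.  Censored phase values fail a range check unless
    ``include_censored`` is set.  ``mask_state`` restricts to subjects
    that were ("disconnected") or never were ("connected") disconnected
    from the oxygen mask during the record.
    """

    identity: str | None = None
    age_min: float | None = None
    age_max: float | None = None
    sex: str | None = None
    mask_state: str | None = None           # "disconnected" | "connected"
    phase_ranges: Mapping[str, tuple[float | None, float | None]] = field(
        default_factory=dict)
    flight_type: str = "total"
    include_censored: bool = False

    def __post_init__(self):
        if self.flight_type not in FLIGHT_TYPES:
            raise FilterSpecError(
                f"unknown flight_type {self.flight_type!r}; "
                f"expected one of {FLIGHT_TYPES}")
        if self.sex is not None and self.sex not in ("F", "M"):
            raise FilterSpecError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.mask_state is not None and self.mask_state not in (
                "disconnected", "connected"):
            raise FilterSpecError(
                f"mask_state must be 'disconnected' or 'connected', "
                f"got {self.mask_state!r}")
        if (self.age_min is not None and self.age_max is not None
                and self.age_min > self.age_max):
            raise FilterSpecError(
                f"age range min {self.age_min} > max {self.age_max}")
        ranges = dict(self.phase_ranges)
        for name, (lo, hi) in ranges.items():
            if name not in PHASE_NAMES:
                raise FilterSpecError(
                    f"unknown phase parameter {name!r}; expected one of "
                    f"{PHASE_NAMES}")
            if lo is not None and hi is not None and lo > hi:
                raise FilterSpecError(f"{name} range min {lo} > max {hi}")
        object.__setattr__(self, "phase_ranges", ranges)

    def to_dict(self) -> dict:
        return {
            "format_version": FILTER_FORMAT_VERSION,
            "identity": self.identity,
            "age_min": self.age_min,
            "age_max": self.age_max,
            "sex": self.sex,
            "mask_state": self.mask_state,
            "phase_ranges": {k: list(v) for k, v in self.phase_ranges.items()},
            "flight_type": self.flight_type,
            "include_censored": self.include_censored,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterSpec":
        d = dict(d)
        d.pop("format_version", None)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise FilterSpecError(
                f"unknown filter field(s): {sorted(unknown)}")
        ranges = {k: tuple(v) for k, v in (d.pop("phase_ranges", {}) or {}).items()}
        return cls(phase_ranges=ranges, **d)


def _subject_passes(
    flight: FlightRecord,
    subject: SubjectRecord,
    phases: PhaseParameters | None,
    validity: ValidityReport | None,
    spec: FilterSpec,
) -> bool:
    if spec.identity is not None and subject.subject_id != spec.identity:
        return False
    if spec.sex is not None and subject.sex != spec.sex:
        return False
    if spec.age_min is not None or spec.age_max is not None:
        if subject.age is None:
            return False
        if spec.age_min is not None and subject.age < spec.age_min:
            return False
        if spec.age_max is not None and subject.age > spec.age_max:
            return False

    needs_phases = spec.mask_state is not None or spec.phase_ranges
    if needs_phases and phases is None:
        raise FilterSpecError(
            f"phase parameters required to filter subject "
            f"{subject.subject_id!r} but none were provided")

    if spec.mask_state is not None:
        disconnected = phases.DT.defined or phases.DT.censored
        if spec.mask_state == "disconnected" and not disconnected:
            return False
        if spec.mask_state == "connected" and disconnected:
            return False

    for name, (lo, hi) in spec.phase_ranges.items():
        pv = phases[name]
        if pv.censored and not spec.include_censored:
            return False
        val = pv.value if pv.defined else (
            pv.censoring_time if (pv.censored and spec.include_censored) else None)
        if val is None:
            return False
        if lo is not None and val < lo:
            return False
        if hi is not None and val > hi:
            return False

    if spec.flight_type == "valid":
        if subject.valid_override is not None:
            return bool(subject.valid_override)
        if validity is None:
            raise FilterSpecError(
                f"validity report required for flight_type='valid' "
                f"(subject {subject.subject_id!r})")
        return validity.valid
    if spec.flight_type != "total":
        return flight.flight_type.strip().lower().replace(" ", "_") == \
            spec.flight_type
    return True


def apply_filters(
    sample: Sample,
    phases_by_subject: Mapping[tuple[str, str], PhaseParameters] | None,
    spec: FilterSpec,
    validity_by_subject: Mapping[tuple[str, str], ValidityReport] | None = None,
) -> tuple[Sample, list[tuple[str, str]]]:
    """Keep the subjects satisfying every criterion of ``spec``.

    ``phases_by_subject`` and ``validity_by_subject`` are keyed by
    (flight_id, subject_id).  Returns a new Sample (flights stripped to
    their surviving subjects; emptied flights dropped) plus the kept
    (flight_id, subject_id) keys.  The result does not depend on subject
    order, and applying two specs in sequence equals applying their
    conjunction.
    """
    kept_flights: list[FlightRecord] = []
    kept_keys: list[tuple[str, str]] = []
    for fl in sample.flights:
        survivors = []
        for subj in fl.subjects:
            key = (fl.flight_id, subj.subject_id)
            ph = (phases_by_subject or {}).get(key)
            va = (validity_by_subject or {}).get(key)
            if _subject_passes(fl, subj, ph, va, spec):
                survivors.append(subj)
                kept_keys.append(key)
        if survivors:
            kept_flights.append(replace(fl, subjects=survivors))
    return Sample(kept_flights), kept_keys


def combine_specs(a: FilterSpec, b: FilterSpec) -> FilterSpec:
    """Conjunction of two specs (intersection of their selections).

    Flight type: "total" is neutral; combining two different non-total
    types (or "valid" with a concrete type) is rejected as contradictory.
    """
    def pick(x, y, name):
        if x is None:
            return y
        if y is None or x == y:
            return x
        if name in ("identity", "sex", "mask_state"):
            raise FilterSpecError(f"contradictory {name}: {x!r} vs {y!r}")
        return x

    if a.flight_type == "total":
        ftype = b.flight_type
    elif b.flight_type == "total" or b.flight_type == a.flight_type:
        ftype = a.flight_type
    else:
        raise FilterSpecError(
            f"cannot combine flight types {a.flight_type!r} and "
            f"{b.flight_type!r}")

    impossible = False
    ranges: dict[str, tuple[float | None, float | None]] = dict(a.phase_ranges)
    for name, (lo, hi) in b.phase_ranges.items():
        if name in ranges:
            plo, phi = ranges[name]
            lo = plo if lo is None else (lo if plo is None else max(lo, plo))
            hi = phi if hi is None else (hi if phi is None else min(hi, phi))
            if lo is not None and hi is not None and lo > hi:
                # empty intersection: clamp to a point range nothing real
                # will hit, and flag via the impossible identity below
                lo = hi = plo
                impossible = True
        ranges[name] = (lo, hi)

    age_min = max(filter(lambda v: v is not None, [a.age_min, b.age_min]),
                  default=None)
    age_max = min(filter(lambda v: v is not None, [a.age_max, b.age_max]),
                  default=None)
    if age_min is not None and age_max is not None and age_min > age_max:
        impossible = True
        age_min = age_max = None

    if impossible:
        # selects nobody: subject_ids are non-empty, never the NUL sentinel
        return FilterSpec(identity="\x00", flight_type=ftype)

    return FilterSpec(
        identity=pick(a.identity, b.identity, "identity"),
        age_min=age_min,
        age_max=age_max,
        sex=pick(a.sex, b.sex, "sex"),
        mask_state=pick(a.mask_state, b.mask_state, "mask_state"),
        phase_ranges=ranges,
        flight_type=ftype,
        include_censored=a.include_censored and b.include_censored,
    )


def save_filters(spec: FilterSpec, path: str | Path) -> Path:
    """Serialize a FilterSpec to JSON; load_filters(save_filters(s)) == s."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(spec.to_dict(), indent=2) + "\n")
    return path


def load_filters(path: str | Path) -> FilterSpec:
    """Load a FilterSpec from JSON, rejecting malformed or inconsistent files."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FilterSpecError(f"{path}: empty filter file")
    try:
        data = json.loads(text)
    except json.JSONDecodeError as e:
        raise FilterSpecError(f"{path}: invalid JSON: {e}") from e
    if not isinstance(data, dict):
        raise FilterSpecError(f"{path}: expected a JSON object")
    return FilterSpec.from_dict(data)
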