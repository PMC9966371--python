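"""Flight-record file dialect: per-subject CSVs with a JSON sidecar.

The original chamber acquisition chain stores its recordings in a
proprietary binary format, so this package defines an open, diff-able
dialect instead:

* one CSV per subject with columns ``time_s, spo2_pct, hr_bpm, mask_on``
  and optionally ``altitude_ft``; missing measurements are empty cells;
* one JSON sidecar per flight holding flight metadata (id, ISO-8601
  datetime, protocol, flight type), per-subject metadata (id, age, sex,
  seat station) and the relative paths of the subject CSVs, under a
  versioned ``format_version`` key.

Timestamps are seconds from record start; absolute wall-clock time lives
only in the sidecar.  Within a subject CSV all channels share the time
column; missing mask cells are filled by previous-value hold (the mask
is a step signal), so every ingested record has aligned channels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError
from .phases import PhaseParameters, TraceStats
from .records import FlightRecord, Sample, SubjectRecord, TimeSeries

__all__ = [
    "FORMAT_VERSION",
    "FlightDescriptor",
    "read_flight_record",
    "write_flight_record",
    "search_flights",
    "edit_sample",
    "export_report",
]

FORMAT_VERSION = "1.0"
SIDECAR_SUFFIX = ".flight.json"

_REQUIRED_COLUMNS = ("time_s", "spo2_pct", "hr_bpm", "mask_on")
_OPTIONAL_COLUMNS = ("altitude_ft",)


# ---------------------------------------------------------------------------
# subject CSVs

def _parse_numeric(raw: pd.Series, field: str) -> np.ndarray:
    """Convert a string column to float, NaN for empty cells; report the
    first non-numeric cell by 1-based data row."""
    stripped = raw.fillna("").str.strip()
    try:
        # Series.astype(float) round-trips repr-formatted floats exactly,
        # unlike pd.to_numeric's fast parser
        return stripped.replace("", "nan").astype(float).to_numpy()
    except ValueError:
        for i, cell in enumerate(stripped):
            if cell == "":
                continue
            try:
                float(cell)
            except ValueError:
                raise FormatError(f"non-numeric value {cell!r}",
                                  row=i + 1, field=field) from None
        raise                                               # pragma: no cover


def _read_subject_csv(path: Path) -> dict[str, np.ndarray]:
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except Exception as e:                                  # pragma: no cover
        raise FormatError(f"cannot parse CSV {path}: {e}") from e
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required columns {missing}")

    cols = {c: _parse_numeric(df[c], c)
            for c in df.columns if c in _REQUIRED_COLUMNS + _OPTIONAL_COLUMNS}

    t = cols["time_s"]
    if np.any(np.isnan(t)):
        row = int(np.argmax(np.isnan(t))) + 1
        raise FormatError("missing timestamp", row=row, field="time_s")
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        row = int(np.argmax(np.diff(t) <= 0)) + 2
        raise FormatError("timestamps not strictly increasing",
                          row=row, field="time_s")

    s = cols["spo2_pct"]
    bad = ~np.isnan(s) & ((s < 0) | (s > 100))
    if bad.any():
        row = int(np.argmax(bad)) + 1
        raise FormatError(f"SpO2 value {s[row - 1]} outside [0, 100]",
                          row=row, field="spo2_pct")

    # mask: previous-value hold over missing cells, backfill a missing head
    m = pd.Series(cols["mask_on"]).ffill().bfill().to_numpy()
    if np.any(np.isnan(m)):
        raise FormatError("mask_on column entirely empty", field="mask_on")
    if not np.isin(m, (0.0, 1.0)).all():
        row = int(np.argmax(~np.isin(m, (0.0, 1.0)))) + 1
        raise FormatError("mask_on must be 0 or 1", row=row, field="mask_on")
    cols["mask_on"] = m
    return cols


def _subject_from_csv(path: Path, meta: Mapping) -> SubjectRecord:
    cols = _read_subject_csv(path)
    t = cols["time_s"]
    alt = None
    if "altitude_ft" in cols:
        alt = TimeSeries(t, cols["altitude_ft"], "altitude")

    def _opt(key, conv):
        v = meta.get(key)
        if v is None or v == "":
            return None
        try:
            return conv(v)
        except (TypeError, ValueError):
            return None                 # unparseable optional field -> missing

    sex = meta.get("sex")
    if sex not in ("F", "M"):
        sex = None
    return SubjectRecord(
        subject_id=str(meta["subject_id"]),
        spo2=TimeSeries(t, cols["spo2_pct"], "spo2"),
        hr=TimeSeries(t, cols["hr_bpm"], "hr"),
        mask=TimeSeries(t, cols["mask_on"], "mask"),
        altitude=alt,
        age=_opt("age", float),
        sex=sex,
        station=_opt("station", int),
        valid_override=meta.get("valid_override"),
    )


# ---------------------------------------------------------------------------
# flight records

def _resolve_sidecar(path: Path) -> Path:
    if path.is_dir():
        hits = sorted(path.glob(f"*{SIDECAR_SUFFIX}"))
        if len(hits) != 1:
            raise FormatError(
                f"{path}: expected exactly one *{SIDECAR_SUFFIX} sidecar, "
                f"found {len(hits)}")
        return hits[0]
    return path


def read_flight_record(path: str | Path) -> FlightRecord:
    """Load one flight from its JSON sidecar (or the directory holding it).

    Required fields that are malformed raise :class:`FormatError` naming
    the row and field; unparseable *optional* metadata becomes missing.
    """
    sidecar = _resolve_sidecar(Path(path))
    if not sidecar.exists():
        raise FileNotFoundError(sidecar)
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{sidecar}: invalid JSON sidecar: {e}") from e
    for key in ("flight_id", "datetime", "subjects"):
        if key not in meta:
            raise FormatError(f"{sidecar.name}: sidecar missing '{key}'")
    subjects = []
    for sm in meta["subjects"]:
        if "subject_id" not in sm or "data_file" not in sm:
            raise FormatError(
                f"{sidecar.name}: subject entry needs 'subject_id' and 'data_file'")
        subjects.append(_subject_from_csv(sidecar.parent / sm["data_file"], sm))
    return FlightRecord(
        flight_id=str(meta["flight_id"]),
        datetime=str(meta["datetime"]),
        protocol=str(meta.get("protocol", "")),
        flight_type=str(meta.get("flight_type", "")),
        subjects=subjects,
    )


def _fmt(x: float) -> str:
    if np.isnan(x):
        return ""
    # repr is the shortest string that round-trips the float exactly
    return repr(float(x))


def write_flight_record(record: FlightRecord, path: str | Path) -> Path:
    """Write a flight as a JSON sidecar plus one CSV per subject.

    ``path`` may be a directory (sidecar named ``<flight_id>.flight.json``
    inside it) or the sidecar path itself; CSVs are placed alongside.
    Returns the sidecar path.  The emitted files round-trip through
    :func:`read_flight_record` exactly on all required fields.
    """
    path = Path(path)
    if path.suffix == ".json":
        sidecar, outdir = path, path.parent
    else:
        outdir = path
        sidecar = outdir / f"{record.flight_id}{SIDECAR_SUFFIX}"
    outdir.mkdir(parents=True, exist_ok=True)

    subj_meta = []
    for subj in record.subjects:
        csv_name = f"{record.flight_id}_{subj.subject_id}.csv"
        cols = {
            "time_s": subj.times,
            "spo2_pct": subj.spo2.values,
            "hr_bpm": subj.hr.values,
            "mask_on": subj.mask.values,
        }
        if subj.altitude is not None:
            cols["altitude_ft"] = subj.altitude.values
        lines = [",".join(cols)]
        for i in range(len(subj.times)):
            lines.append(",".join(_fmt(c[i]) for c in cols.values()))
        (outdir / csv_name).write_text("\n".join(lines) + "\n")
        sm = {"subject_id": subj.subject_id, "data_file": csv_name}
        for key in ("age", "sex", "station", "valid_override"):
            v = getattr(subj, key)
            if v is not None:
                sm[key] = v
        subj_meta.append(sm)

    meta = {
        "format_version": FORMAT_VERSION,
        "flight_id": record.flight_id,
        "datetime": record.datetime,
        "protocol": record.protocol,
        "flight_type": record.flight_type,
        "subjects": subj_meta,
    }
    sidecar.write_text(json.dumps(meta, indent=2) + "\n")
    return sidecar


# ---------------------------------------------------------------------------
# search / edit

@dataclass(frozen=True)
class FlightDescriptor:
    """Lightweight metadata of one stored flight, for search results."""

    flight_id: str
    datetime: str
    protocol: str
    flight_type: str
    n_subjects: int
    path: Path


def search_flights(
    directory: str | Path,
    query: Callable[[FlightDescriptor], bool] | None = None,
) -> list[FlightDescriptor]:
    """Scan a directory tree for stored flights matching ``query``.

    Returns descriptors sorted by datetime; an empty result is valid.
    Sidecars that fail to parse are skipped with a warning.
    """
    directory = Path(directory)
    out = []
    for sidecar in sorted(directory.rglob(f"*{SIDECAR_SUFFIX}")):
        try:
            meta = json.loads(sidecar.read_text())
            desc = FlightDescriptor(
                flight_id=str(meta["flight_id"]),
                datetime=str(meta["datetime"]),
                protocol=str(meta.get("protocol", "")),
                flight_type=str(meta.get("flight_type", "")),
                n_subjects=len(meta.get("subjects", [])),
                path=sidecar,
            )
        except (json.JSONDecodeError, KeyError) as e:
            warnings.warn(f"skipping unreadable sidecar {sidecar}: {e}")
            continue
        if query is None or query(desc):
            out.append(desc)
    return sorted(out, key=lambda d: (d.datetime, d.flight_id))


def edit_sample(sample: Sample, remove_ids: list[str]) -> Sample:
    """Return a new Sample without the flights in ``remove_ids``.

    The input is left unmodified; ids not present trigger a warning, not
    an error.  Idempotent for a fixed ``remove_ids``.
    """
    present = set(sample.flight_ids)
    for fid in remove_ids:
        if fid not in present:
            warnings.warn(f"flight_id {fid!r} not in sample")
    drop = set(remove_ids)
    return Sample([f for f in sample.flights if f.flight_id not in drop])


# ---------------------------------------------------------------------------
# per-subject report

def _report_dict(subject: SubjectRecord, phases: PhaseParameters,
                 stats: Mapping[str, TraceStats]) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "subject": {
            "subject_id": subject.subject_id,
            "age": subject.age,
            "sex": subject.sex,
            "station": subject.station,
        },
        "phases": phases.to_dict(),
        "trace_stats": {
            ch: {
                "minimum": st.minimum, "maximum": st.maximum,
                "mean": st.mean, "slope_per_min": st.slope,
                "window": list(st.window), "n": st.n,
            }
            for ch, st in stats.items()
        },
    }


def _phase_line(name: str, pv) -> str:
    if pv.defined:
        return f"  {name:>4s}: {pv.value:.1f} s"
    if pv.censored:
        extra = (f" (observed >= {pv.censoring_time:.1f} s)"
                 if pv.censoring_time is not None else "")
        return f"  {name:>4s}: not reached before record end{extra}"
    return f"  {name:>4s}: undefined (threshold never crossed)"


def export_report(
    subject: SubjectRecord,
    phases: PhaseParameters,
    stats: Mapping[str, TraceStats],
    path: str | Path,
) -> Path:
    """Write a per-subject report: JSON if ``path`` ends in .json, else text.

    The JSON form re-parses to exactly the input values; the text form
    lists metadata, the six phase durations (censored ones marked "not
    reached") and min/max/mean/slope per channel.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = _report_dict(subject, phases, stats)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
        return path

    lines = [f"Subject report: {subject.subject_id}"]
    if subject.age is not None:
        lines.append(f"  age: {subject.age:g} y")
    if subject.sex is not None:
        lines.append(f"  sex: {subject.sex}")
    if subject.station is not None:
        lines.append(f"  station: {subject.station}")
    lines.append("Phase parameters "
                 f"(desat {phases.desat_threshold:g}%, "
                 f"hypoxia {phases.hypoxia_threshold:g}%, "
                 f"recovery {phases.recovery_threshold:g}%):")
    for name in PhaseParameters.NAMES:
        lines.append(_phase_line(name, phases[name]))
    for ch, st in stats.items():
        slope = f"{st.slope:.2f}" if st.slope is not None else "n/a"
        lines.append(
            f"{ch}: min {st.minimum:.1f}  max {st.maximum:.1f}  "
            f"mean {st.mean:.2f}  slope {slope} /min  "
            f"(window {st.window[0]:g}-{st.window[1]:g} s, n={st.n})")
    path.write_text("\n".join(lines) + "\n")
    return path
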