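"""Analysis configuration: thresholds, debounce and validity criteria.

Defaults follow the standard acute-hypoxia-test conventions: the
desaturation and recovery thresholds are 97 % SpO2, the hypoxia threshold
is 90 % SpO2.  Phase delays use strict ``< threshold`` comparison;
recovery uses ``>= threshold`` (saturation is *reached* again).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "DEFAULT_CONFIG"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the phase and validity analysis.

    Attributes
    ----------
    desat_threshold
        SpO2 (%) below which a subject counts as desaturated; anchors
        DeD and DeT.  Default 97.
    hypoxia_threshold
        SpO2 (%) below which a subject counts as hypoxic; anchors HD and
        HT.  Default 90.
    recovery_threshold
        SpO2 (%) that must be reached again after mask reconnection to
        end the recovery phase (RT).  Default 97.
    debounce
        Minimum run length, in samples, of the threshold condition before
        a crossing is declared.  Default 1 (no debounce); raise for noisy
        oximeters.
    max_gap
        Longest tolerated interval between consecutive samples, seconds.
    response_drop
        Minimum SpO2 fall (%) expected within ``response_window`` seconds
        of mask disconnection for the record to count as physiologically
        responsive.
    response_window
        Window (s) after disconnection in which ``response_drop`` must
        occur.
    """

    desat_threshold: float = 97.0
    hypoxia_threshold: float = 90.0
    recovery_threshold: float = 97.0
    debounce: int = 1
    max_gap: float = 5.0
    response_drop: float = 2.0
    response_window: float = 120.0

    def __post_init__(self):
        if self.debounce < 1:
            raise ValueError("debounce must be >= 1 sample")
        for name in ("desat_threshold", "hypoxia_threshold", "recovery_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValueError(f"{name} must be in (0, 100], got {v}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from a YAML or JSON file (by extension; YAML reads JSON too)."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        return cls.from_dict(data)


DEFAULT_CONFIG = AnalysisConfig()
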