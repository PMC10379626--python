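"""Pipeline configuration: the tunable analysis parameters in one place.

Defaults reproduce the published analysis settings where they are stated
(0.5 Hz segmentation cutoff, 6 Hz feature cutoff, 2nd-order zero-lag
filters, symmetric 1-s peak window, 15-s analysis segment, five-turn trial
minimum); the remaining knobs (peak-detection thresholds, refinement window,
contact threshold, region band fractions) are this package's documented
choices.  Configurations load from YAML and validate on construction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    segmentation_cutoff_hz: float = 0.5
    feature_cutoff_hz: float = 6.0
    filter_order: int = 2
    peak_window_half_s: float = 0.5     # symmetric 1-s window around each apex
    refine_half_s: float = 0.25
    min_separation_s: float = 1.0
    prominence_factor: float = 0.25     # x filtered-signal SD
    analysis_window_s: float = 15.0
    min_turns_per_trial: int = 5
    subject_drop_fraction: float = 0.5
    contact_threshold_kpa: float = 5.0
    region_band_edges: tuple = (0.30, 0.60, 0.85)
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.segmentation_cutoff_hz < self.feature_cutoff_hz):
            raise ValueError("need 0 < segmentation cutoff < feature cutoff")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        for name in ("peak_window_half_s", "refine_half_s", "analysis_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_turns_per_trial < 1:
            raise ValueError("min_turns_per_trial must be >= 1")
        edges = tuple(self.region_band_edges)
        if len(edges) != 3 or not all(0 < a < b for a, b in zip(edges, edges[1:])) or edges[-1] >= 1:
            raise ValueError("region_band_edges must be three increasing fractions in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        object.__setattr__(self, "region_band_edges", edges)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "region_band_edges" in data:
            data["region_band_edges"] = tuple(data["region_band_edges"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["region_band_edges"] = list(d["region_band_edges"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
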