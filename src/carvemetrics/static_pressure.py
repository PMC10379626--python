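"""Static dorsal and plantar boot-pressure metrics.

In-lab trials record pressure between the foot and the boot on two surfaces:
an 18 x 10 sensel pad over the dorsum (instep) and a 235-sensel plantar
insole.  Trials are time-averaged over the recording window and reduced to
scalar metrics: whole-surface mean / SD / total / peak pressure and contact
area for the dorsum, and per-region peak pressure and contact area for the
plantar surface (medial/lateral x heel, midfoot, metatarsals, toes).

Grid conventions
----------------
``values[r, c]`` is the pressure (kPa) at row ``r``, column ``c``.  Row 0 is
the heel end of the plantar insole and rows increase toward the toes.  For a
*right* foot, column 0 lies on the medial side; left-foot grids are mirrored
(column 0 lateral).  The plantar sensor's 235 active sensels sit inside a
31 x 10 bounding grid; inactive sensels are masked out and never contribute
to any statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "PressureGrid",
    "RegionScheme",
    "DorsalMetrics",
    "DORSAL_SHAPE",
    "PLANTAR_SHAPE",
    "PLANTAR_ACTIVE_SENSELS",
    "dorsal_sensel_area_cm2",
    "plantar_sensel_area_cm2",
    "time_average_grid",
    "dorsal_metrics",
    "plantar_region_metrics",
    "build_region_scheme",
    "REGION_NAMES",
]

DORSAL_SHAPE = (18, 10)          # 150 mm x 105 mm pad
PLANTAR_SHAPE = (31, 10)         # bounding grid of the 310 mm x 105 mm insole
PLANTAR_ACTIVE_SENSELS = 235

# Longitudinal band edges as fractions of insole length from the heel.
DEFAULT_BAND_EDGES = (0.30, 0.60, 0.85)
_BANDS = ("heel", "midfoot", "metatarsals", "toes")
REGION_NAMES = tuple(f"{side}_{band}" for band in _BANDS for side in ("medial", "lateral"))


def dorsal_sensel_area_cm2() -> float:
    """Area of one dorsal sensel: 150 x 105 mm over 18 x 10 sensels."""
    return (15.0 * 10.5) / (DORSAL_SHAPE[0] * DORSAL_SHAPE[1])


def plantar_sensel_area_cm2() -> float:
    """Area of one plantar sensel: 310 x 105 mm over the 31 x 10 bounding grid."""
    return (31.0 * 10.5) / (PLANTAR_SHAPE[0] * PLANTAR_SHAPE[1])


@dataclass(frozen=True)
class PressureGrid:
    """A static pressure matrix with sensel geometry.

    ``active_mask`` marks physically present sensels; the dorsal pad is fully
    populated while the plantar insole has 235 active cells in its bounding
    grid.  Values at inactive sensels are stored as 0 and ignored.
    """

    values: np.ndarray
    sensel_area_cm2: float
    surface: str                     # "dorsal" | "plantar"
    foot_side: str = "right"         # "left" | "right"
    active_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("pressure grid must be 2-D")
        if self.surface not in ("dorsal", "plantar"):
            raise ValueError(f"unknown surface {self.surface!r}")
        if self.foot_side not in ("left", "right"):
            raise ValueError(f"unknown foot_side {self.foot_side!r}")
        mask = self.active_mask
        mask = np.ones(v.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
        if mask.shape != v.shape:
            raise ValueError("active_mask shape must match values")
        if np.any(v[mask] < 0):
            raise ValueError("pressures must be non-negative")
        if self.surface == "dorsal" and v.shape != DORSAL_SHAPE:
            raise ValueError(f"dorsal grid must be {DORSAL_SHAPE}, got {v.shape}")
        v = np.where(mask, v, 0.0)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "active_mask", mask)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_active(self) -> int:
        return int(self.active_mask.sum())

    # -- I/O: CSV matrix + JSON sidecar ------------------------------------

    def to_files(self, csv_path, meta_path=None) -> None:
        csv_path = Path(csv_path)
        np.savetxt(csv_path, self.values, delimiter=",", fmt="%.6g")
        meta = {
            "surface": self.surface,
            "foot_side": self.foot_side,
            "sensel_area_cm2": self.sensel_area_cm2,
            "active_mask": self.active_mask.astype(int).tolist(),
        }
        meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
        meta_path.write_text(json.dumps(meta))

    @classmethod
    def from_files(cls, csv_path, meta_path=None) -> "PressureGrid":
        csv_path = Path(csv_path)
        meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
        meta = json.loads(meta_path.read_text())
        values = np.loadtxt(csv_path, delimiter=",", ndmin=2)
        return cls(
            values=values,
            sensel_area_cm2=float(meta["sensel_area_cm2"]),
            surface=meta["surface"],
            foot_side=meta["foot_side"],
            active_mask=np.asarray(meta["active_mask"], dtype=bool),
        )


@dataclass(frozen=True)
class RegionScheme:
    """Assignment of every active plantar sensel to one of eight regions."""

    masks: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.masks) != set(REGION_NAMES):
            raise ValueError("scheme must define exactly the eight standard regions")

    def validate_partition(self, grid: PressureGrid) -> None:
        total = np.zeros(grid.values.shape, dtype=int)
        for m in self.masks.values():
            total += m.astype(int)
        if np.any(total[grid.active_mask] != 1):
            raise ValueError("regions must partition the active sensels")
        if np.any(total[~grid.active_mask] != 0):
            raise ValueError("regions must not cover inactive sensels")


@dataclass(frozen=True)
class DorsalMetrics:
    mean_pressure: float
    sd_pressure: float
    total_pressure: float
    peak_pressure: float
    contact_area: float


def time_average_grid(frames: Iterable[PressureGrid]) -> PressureGrid:
    """Sensel-wise mean of a sequence of frames with identical geometry."""
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    first = frames[0]
    for f in frames[1:]:
        if (
            f.values.shape != first.values.shape
            or f.surface != first.surface
            or f.foot_side != first.foot_side
            or not np.array_equal(f.active_mask, first.active_mask)
        ):
            raise ValueError("all frames must share geometry, surface and side")
    mean = np.mean([f.values for f in frames], axis=0)
    return replace(first, values=mean)


def dorsal_metrics(grid: PressureGrid, contact_threshold: float = 5.0) -> DorsalMetrics:
    """Whole-pad statistics over all 180 dorsal sensels.

    The SD is the population SD across the entire surface (zeros included);
    contact area counts sensels strictly above ``contact_threshold`` (kPa).
    """
    if grid.surface != "dorsal":
        raise ValueError("dorsal_metrics requires a dorsal grid")
    v = grid.values
    return DorsalMetrics(
        mean_pressure=float(v.mean()),
        sd_pressure=float(v.std(ddof=0)),
        total_pressure=float(v.sum()),
        peak_pressure=float(v.max()),
        contact_area=float((v > contact_threshold).sum() * grid.sensel_area_cm2),
    )


def build_region_scheme(grid: PressureGrid) -> RegionScheme:
    """Eight-region plantar masking scheme.

    Longitudinal bands by fraction of insole length from the heel —
    heel 0–30%, midfoot 30–60%, metatarsals 60–85%, toes 85–100% — crossed
    with a medial/lateral split at the column midline, mirrored by foot side.
    Band membership is decided by the sensel's row-center fraction.
    """
    if grid.surface != "plantar":
        raise ValueError("region schemes apply to plantar grids")
    n_rows, n_cols = grid.values.shape
    row_frac = (np.arange(n_rows) + 0.5) / n_rows
    edges = DEFAULT_BAND_EDGES
    band_of_row = np.digitize(row_frac, edges)  # 0..3 -> heel..toes
    col_frac = (np.arange(n_cols) + 0.5) / n_cols
    medial_cols = col_frac < 0.5 if grid.foot_side == "right" else col_frac >= 0.5
    masks = {}
    for b, band in enumerate(_BANDS):
        in_band = (band_of_row == b)[:, None]
        for side, side_cols in (("medial", medial_cols), ("lateral", ~medial_cols)):
            masks[f"{side}_{band}"] = in_band & side_cols[None, :] & grid.active_mask
    scheme = RegionScheme(masks=masks)
    scheme.validate_partition(grid)
    return scheme


def plantar_region_metrics(
    grid: PressureGrid,
    scheme: RegionScheme | None = None,
    contact_threshold: float = 5.0,
) -> dict[str, dict[str, float]]:
    """Per-region peak pressure (kPa) and contact area (cm^2).

    Empty regions report peak 0 and area 0.  Raises if the scheme leaves an
    active sensel unassigned.
    """
    if grid.surface != "plantar":
        raise ValueError("plantar_region_metrics requires a plantar grid")
    scheme = scheme or build_region_scheme(grid)
    scheme.validate_partition(grid)
    out: dict[str, dict[str, float]] = {}
    for name, mask in scheme.masks.items():
        vals = grid.values[mask]
        out[name] = {
            "peak_pressure": float(vals.max()) if vals.size else 0.0,
            "contact_area": float((vals > contact_threshold).sum() * grid.sensel_area_cm2),
        }
    return out
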