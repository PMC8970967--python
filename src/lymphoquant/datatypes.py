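"""Shared domain containers used across the quantification pipeline.

Conventions
-----------
* Image coordinates: origin at the top-left pixel center, ``x`` rightward
  (columns), ``y`` downward (rows).  Centroids are reported in micrometres.
* Areas are um^2 unless a field name says mm^2; the stromal denominator of
  lymphatic vessel density (LVD) is always mm^2.
* Percentages are on the 0-100 scale, fractions on 0-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "ImageField",
    "GroundTruth",
    "StainBasis",
    "VesselRecord",
    "LVDResult",
    "FieldQuantification",
    "ReplicateRollup",
    "SproutResult",
    "BurdenResult",
    "GateReport",
    "GroupComparison",
    "GroupSummary",
]


@dataclass
class ImageField:
    """A calibrated raster: RGB brightfield and/or named fluorescence channels.

    Parameters
    ----------
    pixel_size : float
        Physical pixel size in micrometres per pixel; must be positive.
    rgb : ndarray, optional
        ``(H, W, 3)`` float array in ``[0, 1]`` for brightfield images.
    channels : dict of str -> ndarray
        Named single-channel float rasters (fluorescence), all the same shape.
    provenance : str
        File path or a ``generator:seed`` tag describing where the image came
        from.
    """

    pixel_size: float
    rgb: np.ndarray | None = None
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be strictly positive (um/px)")
        if self.rgb is not None:
            if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
                raise ValueError("rgb must be an (H, W, 3) array")
        shapes = {ch.shape for ch in self.channels.values()}
        if self.rgb is not None:
            shapes.add(self.rgb.shape[:2])
        if len(shapes) > 1:
            raise ValueError("all channels must share one raster shape")

    @property
    def shape(self) -> tuple[int, int]:
        if self.rgb is not None:
            return self.rgb.shape[:2]
        for ch in self.channels.values():
            return ch.shape
        raise ValueError("empty ImageField")


@dataclass
class GroundTruth:
    """Per-object true values recorded by a synthetic generator.

    ``truth_table`` holds per-object rows (vessel areas, per-event population
    labels, ...); scalar truths (realized gap fraction, planted outlier set)
    live in ``scalars``; pixel-level truth (label masks) in ``masks``.
    Regenerating with the same ``seed`` and ``params`` yields byte-identical
    artifacts.
    """

    kind: str
    seed: int
    params: dict[str, Any]
    truth_table: pd.DataFrame
    scalars: dict[str, Any] = field(default_factory=dict)
    masks: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass(frozen=True)
class StainBasis:
    """Optical-density color basis for brightfield stain separation.

    ``rgb_from_stains`` is a 3x3 matrix whose rows are the unit OD color
    vectors of (nuclear counterstain, eosin-like residual, chromogen).  The
    default basis (see :mod:`lymphoquant.vessels`) is the standard
    hematoxylin / eosin / DAB set.
    """

    rgb_from_stains: np.ndarray
    names: tuple[str, str, str] = ("hematoxylin", "residual", "dab")
    chromogen_index: int = 2
    counterstain_index: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.rgb_from_stains, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("stain basis must be a 3x3 matrix")
        if np.any(np.linalg.norm(m, axis=1) == 0):
            raise ValueError("stain vectors must be nonzero")
        if np.linalg.cond(m) > 1e6:
            raise ValueError("stain basis is (numerically) singular")
        object.__setattr__(self, "rgb_from_stains", m)

    @property
    def stains_from_rgb(self) -> np.ndarray:
        return np.linalg.inv(self.rgb_from_stains)


@dataclass
class VesselRecord:
    """Morphometry of one lymphatic vessel cross-section."""

    id: int
    centroid_um: tuple[float, float]  # (x, y)
    area_um2: float
    perimeter_um: float
    provenance: str = "auto"  # auto | manual

    def __post_init__(self) -> None:
        if not (self.area_um2 > 0):
            raise ValueError("vessel area must be positive")
        if not (self.perimeter_um > 0):
            raise ValueError("vessel perimeter must be positive")
        # isoperimetric inequality, with slack for pixel discretization
        if 4.0 * math.pi * self.area_um2 > self.perimeter_um**2 * 1.10:
            raise ValueError(
                "area/perimeter violate the isoperimetric inequality beyond "
                "discretization tolerance"
            )
        if self.provenance not in ("auto", "manual"):
            raise ValueError("provenance must be 'auto' or 'manual'")


@dataclass
class LVDResult:
    """Lymphatic vessel density normalized to stromal area (vessels / mm^2)."""

    n_vessels: int
    stromal_area_mm2: float
    lvd: float
    vessel_records: list[VesselRecord] = field(default_factory=list)
    excluded_outside_stroma: int = 0

    def __post_init__(self) -> None:
        if not (self.stromal_area_mm2 > 0):
            raise ValueError("stromal area must be positive")
        expected = self.n_vessels / self.stromal_area_mm2
        if not math.isclose(self.lvd, expected, rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError("lvd must equal n_vessels / stromal_area exactly")


@dataclass
class FieldQuantification:
    """A per-field count/percentage metric (positivity, gaps, area fraction)."""

    field_id: str
    metric_name: str
    n_cells: int
    n_positive: int
    percent: float
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.n_positive <= max(self.n_cells, 0)):
            raise ValueError("0 <= n_positive <= n_cells required")
        if self.n_cells > 0:
            expected = 100.0 * self.n_positive / self.n_cells
            if not math.isclose(self.percent, expected, rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError("percent must equal 100*n_positive/n_cells")


@dataclass
class ReplicateRollup:
    """Technical-replicate rollup: fields -> well mean -> biological mean."""

    per_field: dict[str, list[float]]
    per_well: dict[str, float]
    biological: float
    n_fields: dict[str, int] = field(default_factory=dict)
    n_wells: int = 0


@dataclass
class SproutResult:
    """Sprout count on an explanted vessel, normalized to vessel area."""

    n_sprouts: int
    vessel_area_mm2: float
    density_per_mm2: float
    sprout_lengths_um: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = self.n_sprouts / self.vessel_area_mm2
        if not math.isclose(self.density_per_mm2, expected, rel_tol=1e-12):
            raise ValueError("density must equal n_sprouts / vessel_area")


@dataclass
class BurdenResult:
    """Metastatic burden: tumor area as percent of tissue, plus lesion list."""

    tissue_area_mm2: float
    tumor_area_mm2: float
    percent_area: float
    lesions: pd.DataFrame | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tumor_area_mm2 > self.tissue_area_mm2 * (1 + 1e-9):
            raise ValueError("tumor area cannot exceed tissue area")
        expected = 100.0 * self.tumor_area_mm2 / self.tissue_area_mm2
        if not math.isclose(self.percent_area, expected, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("percent_area must equal 100*tumor/tissue")


@dataclass
class GateReport:
    """Counts/percentages from the sequential gating tree.

    Tree: all events -> live -> CD45- -> quadrants on CD31 x gp38:
    LEC (CD31+gp38+), BEC (CD31+gp38-), FRC (CD31-gp38+), DN (CD31-gp38-).
    Percents are relative to the stated parent gate.
    """

    counts: dict[str, int]
    percents: dict[str, float]
    thresholds: dict[str, float]
    lec_per_mg: float | None = None

    def __post_init__(self) -> None:
        quad = sum(self.counts[k] for k in ("LEC", "BEC", "FRC", "DN"))
        if quad != self.counts["live_cd45neg"]:
            raise ValueError("quadrants must exactly partition the live CD45- gate")


@dataclass
class GroupComparison:
    """A two-group test result with the dispatch trace that justified it."""

    group_a: str
    group_b: str
    test: str  # student_t | welch_t | mann_whitney
    statistic: float
    p_value: float
    alpha: float
    trace: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value out of [0, 1]")
        if self.test not in ("student_t", "welch_t", "mann_whitney"):
            raise ValueError(f"unknown test {self.test!r}")


@dataclass
class GroupSummary:
    """mean +/- SEM summary of one group, with fold change vs a control."""

    group: str
    n: int
    mean: float
    sem: float
    fold_change: float | None = None
    fold_change_defined: bool = True
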