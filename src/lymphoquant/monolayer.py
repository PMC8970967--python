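"""Fluorescence field quantifications for endothelial monolayers.

Percent marker-positive cells (Ki67, live/dead, ROS with a nuclear +
perinuclear colocalization rule), junctional gap fraction and non-cohesive
cell percentage, hotspot-restricted positivity, and transwell percent
invasion with technical-replicate rollup.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import closing, convex_hull_image, disk
from skimage.segmentation import expand_labels, watershed

from .datatypes import FieldQuantification, ImageField, ReplicateRollup

__all__ = [
    "segment_nuclei",
    "percent_positive_cells",
    "quantify_junction_gaps",
    "hotspot_positive_fraction",
    "percent_invasion",
]


def segment_nuclei(
    nuclei_channel: np.ndarray,
    pixel_size: float,
    threshold: float | None = None,
    min_separation_um: float = 5.0,
) -> np.ndarray:
    """Label nuclei: threshold then distance-transform watershed split.

    Touching nuclei are split at watershed lines seeded from distance-map
    peaks at least ``min_separation_um`` apart.  Returns a label image.
    """
    ch = np.asarray(nuclei_channel, dtype=float)
    if threshold is None:
        if np.ptp(ch) < 1e-6:
            raise ValueError("no cells detected: empty nuclei channel")
        threshold = float(threshold_otsu(ch))
    mask = ch > threshold
    if not mask.any():
        raise ValueError("no cells detected")
    dist = ndimage.distance_transform_edt(mask)
    min_dist = max(int(round(min_separation_um / pixel_size)), 1)
    peaks = peak_local_max(dist, min_distance=min_dist, labels=mask,
                           exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    return watershed(-dist, markers, mask=mask)


def percent_positive_cells(
    nuclei_channel: np.ndarray,
    marker_channel: np.ndarray,
    pixel_size: float,
    rule: str = "overlap_nucleus",
    marker_threshold: float = 0.5,
    nuclei_threshold: float | None = None,
    ring_um: float = 3.0,
    min_coverage: float = 0.5,
    field_id: str = "field",
) -> FieldQuantification:
    """Percent of nuclei whose marker signal satisfies the positivity rule.

    ``overlap_nucleus``: a cell is positive when at least ``min_coverage`` of
    its nuclear pixels carry marker signal above ``marker_threshold``.
    ``nucleus_plus_perinuclear``: the same coverage is additionally required
    over a perinuclear annulus ``ring_um`` wide (a stand-in for the
    mitochondrial compartment), so off-target signal that touches neither
    compartment never scores.
    """
    if rule not in ("overlap_nucleus", "nucleus_plus_perinuclear"):
        raise ValueError(f"unknown positivity rule {rule!r}")
    labels = segment_nuclei(nuclei_channel, pixel_size, threshold=nuclei_threshold)
    n_cells = int(labels.max())
    if n_cells == 0:
        raise ValueError("no cells detected")
    marker = np.asarray(marker_channel, dtype=float) > marker_threshold

    idx = np.arange(1, n_cells + 1)
    nuc_area = ndimage.sum_labels(np.ones_like(labels), labels, idx)
    nuc_hit = ndimage.sum_labels(marker.astype(float), labels, idx)
    positive = nuc_hit / np.maximum(nuc_area, 1) >= min_coverage

    if rule == "nucleus_plus_perinuclear":
        ring_px = max(int(round(ring_um / pixel_size)), 1)
        ring_labels = expand_labels(labels, distance=ring_px)
        ring_labels = np.where(labels > 0, 0, ring_labels)
        ring_area = ndimage.sum_labels(np.ones_like(ring_labels), ring_labels, idx)
        ring_hit = ndimage.sum_labels(marker.astype(float), ring_labels, idx)
        positive &= ring_hit / np.maximum(ring_area, 1) >= min_coverage

    n_pos = int(positive.sum())
    return FieldQuantification(
        field_id=field_id,
        metric_name=f"percent_positive[{rule}]",
        n_cells=n_cells,
        n_positive=n_pos,
        percent=100.0 * n_pos / n_cells,
        extras=dict(rule=rule, marker_threshold=marker_threshold),
    )


def quantify_junction_gaps(
    junction_channel: np.ndarray,
    nuclei_channel: np.ndarray,
    pixel_size: float,
    min_gap_area_um2: float = 2000.0,
    junction_threshold: float = 0.5,
    field_id: str = "field",
) -> FieldQuantification:
    """Gap fraction of the field and percent of non-cohesive cells.

    The monolayer extent is the closed hull of junction signal; gaps are
    enclosed junction-free components with area >= ``min_gap_area_um2``
    (chosen to exceed a single cell interior).  ``gap_fraction`` is gap
    pixels over field pixels.  A cell is non-cohesive when its territory
    (nearest-nucleus partition of the extent) borders a detected gap.
    """
    jmask = np.asarray(junction_channel, dtype=float) > junction_threshold
    if not jmask.any():
        raise ValueError("no junction signal")
    extent = convex_hull_image(closing(jmask, disk(2)))
    if extent.mean() < 0.5:
        warnings.warn("junction signal occupies <50% of the field; monolayer "
                      "may not be confluent", stacklevel=2)
    holes = extent & ~jmask
    hole_labels = sk_label(holes, connectivity=1)
    min_px = min_gap_area_um2 / pixel_size**2
    gap_ids = [rp.label for rp in regionprops(hole_labels) if rp.area >= min_px]
    gap_mask = np.isin(hole_labels, gap_ids)
    gap_fraction = float(gap_mask.sum()) / gap_mask.size

    nuclei = segment_nuclei(nuclei_channel, pixel_size)
    n_cells = int(nuclei.max())
    territories = expand_labels(nuclei, distance=max(gap_mask.shape))
    near_gap = ndimage.binary_dilation(gap_mask, structure=np.ones((3, 3)))
    non_cohesive_ids = np.setdiff1d(np.unique(territories[near_gap]), [0])
    n_nc = int(len(non_cohesive_ids))
    return FieldQuantification(
        field_id=field_id,
        metric_name="junction_gaps",
        n_cells=n_cells,
        n_positive=min(n_nc, n_cells),
        percent=100.0 * min(n_nc, n_cells) / n_cells if n_cells else 0.0,
        extras=dict(
            gap_fraction=gap_fraction,
            n_gaps=len(gap_ids),
            min_gap_area_um2=min_gap_area_um2,
        ),
    )


def hotspot_positive_fraction(
    centroids_um: np.ndarray,
    positive: np.ndarray,
    field_size_um: tuple[float, float],
    window_um: float = 200.0,
    top_quantile: float = 0.1,
    stride_um: float | None = None,
    field_id: str = "field",
) -> FieldQuantification:
    """Percent positive among cells inside the densest (hotspot) windows.

    Square windows of side ``window_um`` slide over the field at
    ``stride_um`` (default: a quarter window); windows are ranked by
    positive-cell density and the top ``top_quantile`` form the hotspot.
    The returned percent is positives over all cells inside the hotspot
    union.
    """
    pts = np.asarray(centroids_um, dtype=float)
    flags = np.asarray(positive, dtype=bool)
    if len(pts) < 10:
        raise ValueError("need at least 10 cells for hotspot analysis")
    fy, fx = field_size_um
    if window_um > min(fy, fx):
        raise ValueError("window larger than field")
    if stride_um is None:
        stride_um = window_um / 4.0
    y0s = np.arange(0.0, fy - window_um + 1e-9, stride_um)
    x0s = np.arange(0.0, fx - window_um + 1e-9, stride_um)
    n_pos_tot = int(flags.sum())
    if n_pos_tot == 0:
        return FieldQuantification(
            field_id=field_id, metric_name="hotspot_positive",
            n_cells=len(pts), n_positive=0, percent=0.0,
            extras=dict(n_windows=len(y0s) * len(x0s), n_hotspot_windows=0),
        )
    # pts columns are (x, y) um
    in_win = []
    dens = []
    for y0 in y0s:
        for x0 in x0s:
            sel = (
                (pts[:, 0] >= x0) & (pts[:, 0] < x0 + window_um)
                & (pts[:, 1] >= y0) & (pts[:, 1] < y0 + window_um)
            )
            in_win.append(sel)
            dens.append(flags[sel].sum() / window_um**2)
    dens = np.asarray(dens)
    k = max(int(np.ceil(top_quantile * len(dens))), 1)
    k = min(k, int((dens > 0).sum()))  # a hotspot window must hold positives
    hot = np.argsort(dens, kind="stable")[::-1][:k]
    union = np.zeros(len(pts), dtype=bool)
    for i in hot:
        union |= in_win[i]
    n_cells_hot = int(union.sum())
    n_pos_hot = int(flags[union].sum())
    return FieldQuantification(
        field_id=field_id,
        metric_name="hotspot_positive",
        n_cells=n_cells_hot,
        n_positive=n_pos_hot,
        percent=100.0 * n_pos_hot / n_cells_hot if n_cells_hot else 0.0,
        extras=dict(n_windows=len(dens), n_hotspot_windows=k),
    )


def percent_invasion(
    field_counts_by_well: Mapping[str, Sequence[float]],
    field_area_fraction: float,
    seeded: int,
) -> ReplicateRollup:
    """Transwell percent invasion: total cells counted / total cells seeded.

    Counted fields cover only ``field_area_fraction`` of the membrane, so the
    summed field count is extrapolated by that fraction before dividing by
    the number of cells seeded.  Wells (technical replicates) are averaged
    into one biological value.
    """
    if seeded <= 0:
        raise ValueError("seeded must be positive")
    if not (0.0 < field_area_fraction <= 1.0):
        raise ValueError("field_area_fraction must be in (0, 1]")
    if not field_counts_by_well:
        raise ValueError("no wells provided")
    per_field: dict[str, list[float]] = {}
    per_well: dict[str, float] = {}
    n_fields: dict[str, int] = {}
    for well, counts in field_counts_by_well.items():
        counts = [c for c in counts if c is not None and np.isfinite(c)]
        if not counts:
            raise ValueError(f"well {well!r} has no fields")
        total = sum(counts) / field_area_fraction
        per_field[well] = list(counts)
        per_well[well] = 100.0 * total / seeded
        n_fields[well] = len(counts)
    biological = float(np.mean(sorted(per_well.values())))
    return ReplicateRollup(
        per_field=per_field,
        per_well=per_well,
        biological=biological,
        n_fields=n_fields,
        n_wells=len(per_well),
    )
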