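"""Metastatic burden quantification in nodes and lungs.

Percent metastatic area of the total node by thresholding a tumor-signal
channel inside the tissue mask, and a connected-component lesion counter
(an automated stand-in for by-eye macroscopic lesion counting, flagged as
such in output metadata).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .datatypes import BurdenResult

__all__ = ["area_fraction", "lesion_metrics"]


def area_fraction(
    tumor_channel: np.ndarray,
    tissue_mask: np.ndarray,
    pixel_size: float,
    policy: str = "otsu",
    fixed_threshold: float | None = None,
    threshold_floor: float = 0.25,
) -> BurdenResult:
    """Percent of tissue area covered by thresholded tumor signal.

    The threshold is Otsu computed over tumor-channel values inside the
    tissue mask (clamped to at least ``threshold_floor`` so a signal-free
    node yields 0%), or a fixed override.  The applied threshold is logged
    in ``metadata``.
    """
    tissue = np.asarray(tissue_mask, dtype=bool)
    if not tissue.any():
        raise ValueError("empty tissue mask")
    ch = np.asarray(tumor_channel, dtype=float)
    vals = ch[tissue]
    if policy == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed policy requires fixed_threshold")
        t = float(fixed_threshold)
    elif policy == "otsu":
        t = threshold_floor if np.ptp(vals) < 1e-6 else max(
            float(threshold_otsu(vals)), threshold_floor
        )
    else:
        raise ValueError(f"unknown threshold policy {policy!r}")
    tumor = (ch >= t) & tissue
    tissue_mm2 = float(tissue.sum()) * pixel_size**2 / 1e6
    tumor_mm2 = float(tumor.sum()) * pixel_size**2 / 1e6
    return BurdenResult(
        tissue_area_mm2=tissue_mm2,
        tumor_area_mm2=tumor_mm2,
        percent_area=100.0 * tumor_mm2 / tissue_mm2,
        metadata=dict(threshold=t, policy=policy),
    )


def lesion_metrics(
    tumor_mask: np.ndarray,
    tissue_mask: np.ndarray,
    pixel_size: float,
    min_lesion_area_um2: float = 10_000.0,
) -> BurdenResult:
    """List tumor lesions as connected components above a minimum area.

    Touching components count as one lesion.  This automated counter stands
    in for manual macroscopic lesion counting; ``metadata['automated']``
    flags the substitution.
    """
    tissue = np.asarray(tissue_mask, dtype=bool)
    if not tissue.any():
        raise ValueError("empty tissue mask")
    tumor = np.asarray(tumor_mask, dtype=bool) & tissue
    lab = sk_label(tumor, connectivity=2)
    rows = []
    for rp in regionprops(lab):
        area_um2 = rp.area * pixel_size**2
        if area_um2 < min_lesion_area_um2:
            continue
        cy, cx = rp.centroid
        rows.append(dict(
            lesion_id=len(rows) + 1,
            area_mm2=area_um2 / 1e6,
            centroid_x_um=cx * pixel_size,
            centroid_y_um=cy * pixel_size,
        ))
    lesions = pd.DataFrame(
        rows, columns=["lesion_id", "area_mm2", "centroid_x_um", "centroid_y_um"]
    )
    tissue_mm2 = float(tissue.sum()) * pixel_size**2 / 1e6
    tumor_mm2 = float(tumor.sum()) * pixel_size**2 / 1e6
    return BurdenResult(
        tissue_area_mm2=tissue_mm2,
        tumor_area_mm2=tumor_mm2,
        percent_area=100.0 * tumor_mm2 / tissue_mm2,
        lesions=lesions,
        metadata=dict(automated=True, min_lesion_area_um2=min_lesion_area_um2),
    )
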