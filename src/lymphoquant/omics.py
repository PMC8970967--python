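"""Omics screens: RPPA ratio-outlier detection and fold-change list filters.

The RPPA screen computes treated/control brightness ratios per protein,
assesses the ratio distribution once (mean and SD over all ratios, no
iterative trimming), and flags proteins whose ratio lies strictly more than
``k_sd`` standard deviations from the mean.  The fold-change filter splits a
feature table into up/down lists at fixed cut values applied verbatim to the
table's stated scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["rppa_ratio_outliers", "filter_by_foldchange"]


def rppa_ratio_outliers(
    control: np.ndarray,
    treated: np.ndarray,
    k_sd: float = 2.0,
    protein_ids: list[str] | None = None,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Screen for ratio outliers: |ratio - mean| > k_sd * SD (strict).

    Ratios are treated/control on the linear scale by default
    (``log_scale=True`` screens log-ratios instead).  Mean and SD are
    computed in a single pass over all ratios, candidate outliers included.
    A ratio at exactly ``mean + k_sd*SD`` is NOT flagged.  Rows are returned
    sorted by ``|z|`` descending; columns: ``protein_id, control, treated,
    ratio, z, outlier``.
    """
    c = np.asarray(control, dtype=float)
    t = np.asarray(treated, dtype=float)
    if c.shape != t.shape or c.ndim != 1:
        raise ValueError("control and treated must be equal-length vectors")
    if len(c) < 3:
        raise ValueError("need at least 3 proteins")
    if np.any(c <= 0) or np.any(t <= 0):
        raise ValueError("intensities must be strictly positive")
    ratio = t / c
    screened = np.log(ratio) if log_scale else ratio
    mean = float(np.mean(screened))
    sd = float(np.std(screened, ddof=1))
    if sd == 0.0:
        warnings.warn("all ratios identical; no outliers can be flagged",
                      stacklevel=2)
        z = np.zeros_like(screened)
        flags = np.zeros(len(screened), dtype=bool)
    else:
        z = (screened - mean) / sd
        flags = np.abs(screened - mean) > k_sd * sd
    if protein_ids is None:
        protein_ids = [f"P{i:04d}" for i in range(len(c))]
    df = pd.DataFrame(
        dict(protein_id=protein_ids, control=c, treated=t,
             ratio=ratio, z=z, outlier=flags)
    )
    df.attrs["k_sd"] = k_sd
    df.attrs["scale"] = "log" if log_scale else "linear"
    return df.reindex(
        df["z"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)


def filter_by_foldchange(
    table: pd.DataFrame,
    value_col: str = "logfc",
    up_cut: float = 1.25,
    down_cut: float = 0.75,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split features into up/down lists at strict fold-change cuts.

    ``up`` contains rows with value > ``up_cut``; ``down`` rows with value
    < ``down_cut``; values between (inclusive) fall in neither list.  The
    cut values are recorded in each frame's ``attrs``.
    """
    if up_cut <= down_cut:
        raise ValueError("up_cut must exceed down_cut")
    if value_col not in table.columns:
        raise KeyError(f"missing fold-change column {value_col!r}")
    vals = table[value_col]
    up = table[vals > up_cut].copy()
    down = table[vals < down_cut].copy()
    for df, direction in ((up, "up"), (down, "down")):
        df.attrs.update(up_cut=up_cut, down_cut=down_cut, direction=direction)
    return up, down
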