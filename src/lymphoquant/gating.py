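"""Sequential cytometry gating: live -> CD45- -> CD31/gp38 quadrants.

Events arrive as a CSV-backed table with channels ``viability`` (dead-cell
dye), ``cd45``, ``cd31`` and ``gp38``.  Gating is sequential in the stated
order; the CD31 x gp38 quadrants on the live CD45- parent are LEC
(CD31+gp38+), BEC (CD31+gp38-), FRC (CD31-gp38+) and DN (CD31-gp38-).
Events at a gate boundary go to the marker-positive side (value >= threshold
is positive; for the viability dye, positive means dead).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.signal import argrelmin
from scipy.stats import gaussian_kde

from .datatypes import GateReport

__all__ = ["gate_populations", "estimate_threshold"]

REQUIRED_CHANNELS = ("viability", "cd45", "cd31", "gp38")


def estimate_threshold(values: np.ndarray, grid_points: int = 512) -> float:
    """Valley of a bimodal kernel-density estimate of one channel.

    Returns the deepest KDE local minimum between the two largest modes; a
    convenience default when instrument thresholds are unavailable.
    """
    v = np.asarray(values, dtype=float)
    kde = gaussian_kde(v)
    grid = np.linspace(v.min(), v.max(), grid_points)
    dens = kde(grid)
    minima = argrelmin(dens)[0]
    if len(minima) == 0:
        return float(np.median(v))
    # valley between the two tallest peaks
    from scipy.signal import argrelmax

    maxima = argrelmax(dens)[0]
    if len(maxima) >= 2:
        top2 = sorted(maxima[np.argsort(dens[maxima])[-2:]])
        between = [m for m in minima if top2[0] < m < top2[1]]
        if between:
            return float(grid[min(between, key=lambda m: dens[m])])
    return float(grid[minima[np.argmin(dens[minima])]])


def gate_populations(
    events: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
    tissue_mass_mg: float | None = None,
) -> GateReport:
    """Apply the sequential gating tree and report population statistics.

    ``thresholds`` maps channel name to gate value; missing entries are
    estimated by :func:`estimate_threshold`.  Percents are relative to the
    stated parent (live of total, CD45- of live, quadrants of live CD45-).
    ``lec_per_mg`` is the LEC count divided by ``tissue_mass_mg`` when a
    mass is provided.
    """
    for ch in REQUIRED_CHANNELS:
        if ch not in events.columns:
            raise KeyError(f"missing channel {ch!r}")
        if not np.all(np.isfinite(events[ch].to_numpy(dtype=float))):
            raise ValueError(f"non-finite values in channel {ch!r}")
    thr = dict(thresholds or {})
    for ch in REQUIRED_CHANNELS:
        if ch not in thr:
            thr[ch] = estimate_threshold(events[ch].to_numpy(dtype=float))

    viab = events["viability"].to_numpy(dtype=float)
    cd45 = events["cd45"].to_numpy(dtype=float)
    cd31 = events["cd31"].to_numpy(dtype=float)
    gp38 = events["gp38"].to_numpy(dtype=float)

    n_total = len(events)
    live = viab < thr["viability"]  # dye-positive (>=) events are dead
    cd45neg = live & (cd45 < thr["cd45"])
    cd31p = cd31 >= thr["cd31"]
    gp38p = gp38 >= thr["gp38"]
    lec = cd45neg & cd31p & gp38p
    bec = cd45neg & cd31p & ~gp38p
    frc = cd45neg & ~cd31p & gp38p
    dn = cd45neg & ~cd31p & ~gp38p

    counts = dict(
        total=n_total,
        live=int(live.sum()),
        live_cd45neg=int(cd45neg.sum()),
        LEC=int(lec.sum()),
        BEC=int(bec.sum()),
        FRC=int(frc.sum()),
        DN=int(dn.sum()),
    )
    if counts["live"] == 0:
        warnings.warn("no live events; downstream counts are all zero",
                      stacklevel=2)

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    percents = dict(
        live_of_total=pct(counts["live"], n_total),
        cd45neg_of_live=pct(counts["live_cd45neg"], counts["live"]),
        LEC_of_parent=pct(counts["LEC"], counts["live_cd45neg"]),
        BEC_of_parent=pct(counts["BEC"], counts["live_cd45neg"]),
        FRC_of_parent=pct(counts["FRC"], counts["live_cd45neg"]),
        DN_of_parent=pct(counts["DN"], counts["live_cd45neg"]),
        LEC_of_total=pct(counts["LEC"], n_total),
    )
    lec_per_mg = None
    if tissue_mass_mg is not None:
        if tissue_mass_mg <= 0:
            raise ValueError("tissue mass must be positive")
        lec_per_mg = counts["LEC"] / tissue_mass_mg
    return GateReport(
        counts=counts, percents=percents,
        thresholds={k: float(v) for k, v in thr.items()},
        lec_per_mg=lec_per_mg,
    )
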