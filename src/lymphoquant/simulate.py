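"""Synthetic ground-truth generators for every pipeline input.

Each generator renders an artifact (image or table) together with a
:class:`~lymphoquant.datatypes.GroundTruth` whose values are measured on the
rendered artifact itself, so downstream quantification can be checked against
exact truth.  All randomness flows from one integer seed through a named
stream per generator (``seed`` + operation tag), so adding a generator never
perturbs another's stream, and identical ``(seed, params)`` reproduce
byte-identical outputs.

Brightfield rendering uses Beer-Lambert optical-density mixing with the same
hematoxylin/DAB basis that :mod:`lymphoquant.vessels` assumes for
deconvolution.
"""

from __future__ import annotations

import zlib
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import draw
from skimage.color import hed2rgb
from skimage.segmentation import find_boundaries

from .datatypes import GroundTruth, ImageField

__all__ = [
    "generate_ihc_field",
    "generate_monolayer_field",
    "generate_nuclei_marker_field",
    "generate_sprouted_vessel",
    "generate_node_image",
    "generate_rppa_table",
    "generate_event_table",
    "generate_group_samples",
    "DEFAULT_POPULATION_FRACTIONS",
    "DEFAULT_CHANNEL_PARAMS",
]


def _rng(seed: int, tag: str) -> np.random.Generator:
    """Named random stream: one substream per (seed, operation tag)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(tag.encode())])
    )


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed without overlap in the field."""


# ---------------------------------------------------------------------------
# IHC brightfield field with podoplanin-DAB vessels on hematoxylin stroma
# ---------------------------------------------------------------------------

def _place_disks(
    rng: np.random.Generator,
    shape_px: tuple[int, int],
    radii_px: Sequence[float],
    margin_px: float = 2.0,
    max_tries: int = 2000,
) -> np.ndarray:
    """Rejection-sample non-overlapping disk centers (row, col) in pixels."""
    h, w = shape_px
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for r in radii_px:
        ok = False
        for _ in range(max_tries):
            cy = rng.uniform(r + margin_px, h - r - margin_px)
            cx = rng.uniform(r + margin_px, w - r - margin_px)
            if all(
                (cy - py) ** 2 + (cx - px) ** 2 > (r + pr + margin_px) ** 2
                for (py, px), pr in zip(centers, placed_r)
            ):
                centers.append((cy, cx))
                placed_r.append(r)
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place {len(radii_px)} objects of radius ~{r:.0f}px "
                f"in a {h}x{w} field without overlap"
            )
    return np.asarray(centers, dtype=float).reshape(-1, 2)


def generate_ihc_field(
    n_vessels: int = 5,
    radius_range_um: tuple[float, float] = (20.0, 40.0),
    lumen_fraction: float = 0.5,
    stain_noise: float = 0.03,
    pixel_size: float = 1.0,
    shape: tuple[int, int] = (512, 512),
    annulus_probability: float = 0.5,
    seed: int = 0,
) -> tuple[ImageField, GroundTruth]:
    """Render a podoplanin-DAB IHC field of vessel cross-sections on stroma.

    Vessels are annuli (ring wall + lumen hole, drawn with probability
    ``annulus_probability``) or solid ellipses; eccentricity is mild so the
    analytic filled-ellipse area ``pi*a*b`` is a valid oracle.
    ``lumen_fraction`` is the ratio of lumen radius to outer radius for
    annular vessels.

    Returns the RGB image plus a truth table with per-vessel centroid (um),
    rendered filled area (um^2, exact pixel count), analytic area, and
    analytic perimeter; the filled label mask and wall mask are stored in
    ``truth.masks``.
    """
    if n_vessels < 0:
        raise ValueError("n_vessels must be >= 0")
    lo, hi = radius_range_um
    if not (0 < lo <= hi):
        raise ValueError("radius range must be positive")
    if not (0.0 <= lumen_fraction < 1.0):
        raise ValueError("lumen_fraction must be in [0, 1)")
    rng = _rng(seed, "ihc_field")
    h, w = shape

    # sample mildly eccentric ellipses: a is the major semi-axis in um
    a_um = rng.uniform(lo, hi, size=n_vessels)
    b_um = a_um * rng.uniform(0.8, 1.0, size=n_vessels)
    theta = rng.uniform(0, np.pi, size=n_vessels)
    is_annulus = rng.random(n_vessels) < annulus_probability
    centers = _place_disks(rng, (h, w), a_um / pixel_size + 2.0)

    label = np.zeros((h, w), dtype=np.int32)  # filled vessel regions
    wall = np.zeros((h, w), dtype=bool)
    lumen = np.zeros((h, w), dtype=bool)
    rows = []
    for i in range(n_vessels):
        cy, cx = centers[i]
        a_px, b_px = a_um[i] / pixel_size, b_um[i] / pixel_size
        rr, cc = draw.ellipse(cy, cx, a_px, b_px, shape=(h, w), rotation=theta[i])
        label[rr, cc] = i + 1
        wall[rr, cc] = True
        if is_annulus[i] and lumen_fraction > 0:
            rr2, cc2 = draw.ellipse(
                cy, cx, a_px * lumen_fraction, b_px * lumen_fraction,
                shape=(h, w), rotation=theta[i],
            )
            wall[rr2, cc2] = False
            lumen[rr2, cc2] = True
        a, b = a_um[i], b_um[i]
        # Ramanujan approximation for the ellipse circumference
        hh = (a - b) ** 2 / (a + b) ** 2
        perim = np.pi * (a + b) * (1 + 3 * hh / (10 + np.sqrt(4 - 3 * hh)))
        rows.append(
            dict(
                vessel_id=i + 1,
                centroid_x_um=cx * pixel_size,
                centroid_y_um=cy * pixel_size,
                area_um2=float(np.sum(label == i + 1)) * pixel_size**2,
                area_analytic_um2=np.pi * a * b,
                perimeter_analytic_um=perim,
                is_annulus=bool(is_annulus[i]),
            )
        )

    # Beer-Lambert stain concentrations: hematoxylin stroma + DAB vessel wall
    hema = 0.35 + 0.10 * ndimage.gaussian_filter(
        rng.standard_normal((h, w)), sigma=8.0 / pixel_size
    )
    hema = np.clip(hema, 0.05, None)
    hema[wall] = 0.15
    hema[lumen] = 0.02  # lumen is open space, nearly white
    dab = np.zeros((h, w))
    dab[wall] = 0.9
    if stain_noise > 0:
        hema = hema + rng.normal(0, stain_noise, (h, w))
        dab = dab + rng.normal(0, stain_noise, (h, w))
    hed = np.stack([np.clip(hema, 0, None), np.zeros((h, w)), np.clip(dab, 0, None)], axis=-1)
    rgb = np.clip(hed2rgb(hed), 0.0, 1.0)

    image = ImageField(
        pixel_size=pixel_size, rgb=rgb, provenance=f"generate_ihc_field:{seed}"
    )
    truth = GroundTruth(
        kind="ihc_field",
        seed=seed,
        params=dict(
            n_vessels=n_vessels, radius_range_um=radius_range_um,
            lumen_fraction=lumen_fraction, stain_noise=stain_noise,
            pixel_size=pixel_size, shape=shape,
            annulus_probability=annulus_probability,
        ),
        truth_table=pd.DataFrame(
            rows,
            columns=[
                "vessel_id", "centroid_x_um", "centroid_y_um", "area_um2",
                "area_analytic_um2", "perimeter_analytic_um", "is_annulus",
            ],
        ),
        scalars=dict(field_area_mm2=h * w * pixel_size**2 / 1e6),
        masks=dict(label=label, wall=wall),
    )
    return image, truth


# ---------------------------------------------------------------------------
# Endothelial monolayer with junctional gaps
# ---------------------------------------------------------------------------

def _jittered_grid(
    rng: np.random.Generator, n: int, shape_px: tuple[int, int], jitter: float = 0.35
) -> np.ndarray:
    """n quasi-uniform points via a jittered grid (row, col), no overlap."""
    h, w = shape_px
    m = int(np.ceil(np.sqrt(n * h / w)))
    k = int(np.ceil(n / m))
    ys = (np.arange(m) + 0.5) * h / m
    xs = (np.arange(k) + 0.5) * w / k
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1)
    pts = pts[rng.permutation(len(pts))[:n]]
    pts[:, 0] += rng.uniform(-jitter, jitter, n) * h / m
    pts[:, 1] += rng.uniform(-jitter, jitter, n) * w / k
    pts[:, 0] = np.clip(pts[:, 0], 1, h - 2)
    pts[:, 1] = np.clip(pts[:, 1], 1, w - 2)
    return pts


def _voronoi_labels(points: np.ndarray, shape_px: tuple[int, int]) -> np.ndarray:
    """Nearest-seed (Voronoi) label image, labels 1..n."""
    h, w = shape_px
    yy, xx = np.mgrid[0:h, 0:w]
    _, idx = cKDTree(points).query(np.stack([yy.ravel(), xx.ravel()], axis=1))
    return (idx + 1).reshape(h, w).astype(np.int32)


def generate_monolayer_field(
    n_cells: int = 400,
    gap_fraction: float = 0.10,
    pixel_size: float = 1.0,
    shape: tuple[int, int] = (512, 512),
    gap_chunk_cells: int = 6,
    noise: float = 0.02,
    seed: int = 0,
) -> tuple[ImageField, GroundTruth]:
    """Render a confluent endothelial monolayer with planted junctional gaps.

    Cell territories are a jittered-grid Voronoi tessellation; the junction
    channel marks territory boundaries.  Gaps are planted by deleting
    contiguous clusters of ~``gap_chunk_cells`` whole territories until the
    enclosed junction-free hole area reaches ``gap_fraction`` of the field;
    the junction network is redrawn around each hole so every gap is an
    enclosed region much larger than a single cell interior.

    Truth records the realized gap fraction (pixel count of the rendered
    holes), which cells were removed, and which surviving cells border a gap
    (the non-cohesive cells).
    """
    if not (0.0 <= gap_fraction <= 0.5):
        raise ValueError("gap_fraction must be in [0, 0.5]")
    if n_cells < 4:
        raise ValueError("n_cells too small for a monolayer")
    rng = _rng(seed, "monolayer_field")
    h, w = shape
    pts = _jittered_grid(rng, n_cells, (h, w))
    labels0 = _voronoi_labels(pts, (h, w))

    # cell adjacency graph from the tessellation
    east = np.stack([labels0[:, :-1].ravel(), labels0[:, 1:].ravel()], axis=1)
    south = np.stack([labels0[:-1, :].ravel(), labels0[1:, :].ravel()], axis=1)
    pairs = np.concatenate([east, south])
    pairs = pairs[pairs[:, 0] != pairs[:, 1]]
    adj: dict[int, set[int]] = {i: set() for i in range(1, n_cells + 1)}
    for a, b in np.unique(np.sort(pairs, axis=1), axis=0):
        adj[int(a)].add(int(b))
        adj[int(b)].add(int(a))

    field_px = h * w
    removed: set[int] = set()
    # gaps are interior holes: cells touching the field border keep their
    # territory so every gap stays ringed by junction signal
    border = set(np.unique(np.concatenate([
        labels0[0, :], labels0[-1, :], labels0[:, 0], labels0[:, -1]
    ])).tolist())

    def render(lbl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        junction = find_boundaries(lbl, mode="thick")
        gap_px = (lbl == 0) & ~junction
        return junction, gap_px

    lbl = labels0.copy()
    junction, gap_px = render(lbl)
    if gap_fraction > 0:
        order = rng.permutation(np.arange(1, n_cells + 1))
        qi = 0
        while gap_px.sum() / field_px < gap_fraction:
            # grow a cluster of neighbouring cells around a fresh anchor
            while qi < n_cells and (int(order[qi]) in removed
                                    or int(order[qi]) in border):
                qi += 1
            if qi >= n_cells:
                raise ValueError(
                    f"gap_fraction={gap_fraction} infeasible for n_cells={n_cells}"
                )
            anchor = int(order[qi])
            qi += 1
            # near the target, shrink the cluster to the remaining deficit so
            # the realized fraction lands within one cell of the request
            deficit_px = (gap_fraction - gap_px.sum() / field_px) * field_px
            want = min(gap_chunk_cells,
                       max(1, int(round(deficit_px / (field_px / n_cells)))))
            cluster = {anchor}
            frontier = [anchor]
            while len(cluster) < want and frontier:
                nxt = [
                    v for u in frontier for v in sorted(adj[u])
                    if v not in cluster and v not in removed and v not in border
                ]
                if not nxt:
                    break
                take = nxt[: want - len(cluster)]
                cluster.update(take)
                frontier = take
            if len(cluster) < gap_chunk_cells and not any(
                v in removed for u in cluster for v in adj[u]
            ):
                # an isolated pocket this small would fall below the gap-size
                # gate downstream; keep the monolayer closed here instead
                continue
            removed.update(cluster)
            lbl[np.isin(labels0, list(cluster))] = 0
            junction, gap_px = render(lbl)

    realized = gap_px.sum() / field_px
    # non-cohesive: surviving cells whose territory touches a gap pixel
    dil = ndimage.binary_dilation(gap_px, structure=np.ones((3, 3)))
    border_labels = set(np.unique(lbl[dil])) - {0}
    survivors = [i for i in range(1, n_cells + 1) if i not in removed]

    nuclei = np.zeros((h, w), dtype=float)
    for i in survivors:
        rr, cc = draw.disk(tuple(pts[i - 1]), 3.0, shape=(h, w))
        nuclei[rr, cc] = 1.0
    junction_ch = junction.astype(float)
    if noise > 0:
        nuclei = np.clip(nuclei + rng.normal(0, noise, (h, w)), 0, 1.2)
        junction_ch = np.clip(junction_ch + rng.normal(0, noise, (h, w)), 0, 1.2)

    table = pd.DataFrame(
        dict(
            cell_id=survivors,
            centroid_y_um=[pts[i - 1, 0] * pixel_size for i in survivors],
            centroid_x_um=[pts[i - 1, 1] * pixel_size for i in survivors],
            non_cohesive=[i in border_labels for i in survivors],
        )
    )
    image = ImageField(
        pixel_size=pixel_size,
        channels=dict(junction=junction_ch, nuclei=nuclei),
        provenance=f"generate_monolayer_field:{seed}",
    )
    truth = GroundTruth(
        kind="monolayer_field",
        seed=seed,
        params=dict(
            n_cells=n_cells, gap_fraction=gap_fraction, pixel_size=pixel_size,
            shape=shape, gap_chunk_cells=gap_chunk_cells, noise=noise,
        ),
        truth_table=table,
        scalars=dict(
            gap_fraction=float(realized),
            n_cells=len(survivors),
            n_non_cohesive=int(table["non_cohesive"].sum()),
            non_cohesive_percent=100.0 * table["non_cohesive"].mean() if survivors else 0.0,
        ),
        masks=dict(territory=lbl, gap=gap_px),
    )
    return image, truth


# ---------------------------------------------------------------------------
# Nuclei + marker field (Ki67 / CellROX / live-dead style positivity)
# ---------------------------------------------------------------------------

def generate_nuclei_marker_field(
    n_nuclei: int = 500,
    f_positive: float = 0.3,
    colocalization: str = "nuclear",
    pixel_size: float = 1.0,
    shape: tuple[int, int] = (512, 512),
    nucleus_radius_um: float = 4.0,
    ring_um: float = 3.0,
    noise: float = 0.02,
    seed: int = 0,
) -> tuple[ImageField, GroundTruth]:
    """Render non-overlapping nuclei with a truth-marked positive fraction.

    The positive count is a deterministic assignment, ``round(f_positive *
    n_nuclei)``, not a binomial draw.  ``colocalization`` controls where
    marker signal lands:

    * ``"nuclear"`` — over the nucleus disk;
    * ``"nuclear_perinuclear"`` — nucleus plus a perinuclear ring
      (``ring_um`` wide), emulating nuclear + mitochondrial signal;
    * ``"off_target"`` — blobs placed away from every nucleus; the truth
      positive count is 0 by definition of the mode.
    """
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    if not (0.0 <= f_positive <= 1.0):
        raise ValueError("f_positive must be in [0, 1]")
    if colocalization not in ("nuclear", "nuclear_perinuclear", "off_target"):
        raise ValueError(f"unknown colocalization mode {colocalization!r}")
    rng = _rng(seed, "nuclei_marker_field")
    h, w = shape
    r_px = nucleus_radius_um / pixel_size
    ring_px = ring_um / pixel_size
    pts = _jittered_grid(rng, n_nuclei, (h, w), jitter=0.25)

    n_marked = int(round(f_positive * n_nuclei))
    marked = np.zeros(n_nuclei, dtype=bool)
    marked[rng.permutation(n_nuclei)[:n_marked]] = True

    nuclei = np.zeros((h, w), dtype=float)
    marker = np.zeros((h, w), dtype=float)
    radii = np.clip(rng.normal(r_px, 0.5, n_nuclei), r_px * 0.7, r_px * 1.3)
    for i in range(n_nuclei):
        rr, cc = draw.disk(tuple(pts[i]), radii[i], shape=(h, w))
        nuclei[rr, cc] = 1.0
        if marked[i] and colocalization != "off_target":
            rad = radii[i] + (ring_px if colocalization == "nuclear_perinuclear" else 0.0)
            mr, mc = draw.disk(tuple(pts[i]), rad, shape=(h, w))
            marker[mr, mc] = 1.0
    if colocalization == "off_target":
        # marker blobs in interstitial space, clear of all nuclei + rings
        tree = cKDTree(pts)
        placed = 0
        tries = 0
        while placed < n_marked and tries < 20000:
            tries += 1
            cand = np.array([rng.uniform(2, h - 2), rng.uniform(2, w - 2)])
            if tree.query(cand)[0] > r_px * 1.3 + ring_px + 3:
                rr, cc = draw.disk(tuple(cand), 2.0, shape=(h, w))
                marker[rr, cc] = 1.0
                placed += 1

    if noise > 0:
        nuclei = np.clip(nuclei + rng.normal(0, noise, (h, w)), 0, 1.2)
        marker = np.clip(marker + rng.normal(0, noise, (h, w)), 0, 1.2)

    truth_positive = 0 if colocalization == "off_target" else n_marked
    table = pd.DataFrame(
        dict(
            nucleus_id=np.arange(1, n_nuclei + 1),
            centroid_y_um=pts[:, 0] * pixel_size,
            centroid_x_um=pts[:, 1] * pixel_size,
            positive=marked if colocalization != "off_target" else np.zeros(n_nuclei, bool),
        )
    )
    image = ImageField(
        pixel_size=pixel_size,
        channels=dict(nuclei=nuclei, marker=marker),
        provenance=f"generate_nuclei_marker_field:{seed}",
    )
    truth = GroundTruth(
        kind="nuclei_marker_field",
        seed=seed,
        params=dict(
            n_nuclei=n_nuclei, f_positive=f_positive, colocalization=colocalization,
            pixel_size=pixel_size, shape=shape, nucleus_radius_um=nucleus_radius_um,
            ring_um=ring_um, noise=noise,
        ),
        truth_table=table,
        scalars=dict(
            n_positive=truth_positive,
            percent_positive=100.0 * truth_positive / n_nuclei,
        ),
    )
    return image, truth


# ---------------------------------------------------------------------------
# Sprouted vessel (mesentery explant) and metastatic node/lung image
# ---------------------------------------------------------------------------

def generate_sprouted_vessel(
    n_sprouts: int = 4,
    sprout_length_um: float = 40.0,
    trunk_width_um: float = 12.0,
    pixel_size: float = 1.0,
    shape: tuple[int, int] = (256, 512),
    sprout_width_um: float | None = None,
    noise: float = 0.02,
    seed: int = 0,
) -> tuple[ImageField, GroundTruth]:
    """Render a vessel trunk with ``n_sprouts`` perpendicular blind-ended spurs.

    The trunk runs horizontally; spurs alternate sides at jittered, well
    separated positions so each is an unambiguous skeleton branch.
    """
    if sprout_length_um <= trunk_width_um:
        raise ValueError("sprout_length must exceed trunk_width")
    if n_sprouts < 0:
        raise ValueError("n_sprouts must be >= 0")
    rng = _rng(seed, "sprouted_vessel")
    h, w = shape
    if sprout_width_um is None:
        sprout_width_um = trunk_width_um / 3.0
    tw = trunk_width_um / pixel_size
    sl = sprout_length_um / pixel_size
    sw = sprout_width_um / pixel_size
    y0 = h / 2
    x_lo, x_hi = 10 + sl, w - 10 - sl
    if n_sprouts > 0:
        spacing = (x_hi - x_lo) / n_sprouts
        if spacing < 2 * sw + 6:
            raise PlacementError("field too narrow for requested sprouts")
        xs = x_lo + (np.arange(n_sprouts) + 0.5) * spacing
        xs = xs + rng.uniform(-0.2, 0.2, n_sprouts) * spacing
    else:
        xs = np.array([])

    mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    mask |= (np.abs(yy - y0) <= tw / 2) & (xx >= 8) & (xx <= w - 8)
    lengths = []
    for i, x in enumerate(xs):
        side = 1 if i % 2 == 0 else -1
        y_tip = y0 + side * (tw / 2 + sl)
        lo_y, hi_y = sorted([y0, y_tip])
        mask |= (np.abs(xx - x) <= sw / 2) & (yy >= lo_y) & (yy <= hi_y)
        rr, cc = draw.disk((y_tip, x), sw / 2, shape=(h, w))
        mask[rr, cc] = True
        lengths.append(sprout_length_um)

    channel = mask.astype(float)
    if noise > 0:
        channel = np.clip(channel + rng.normal(0, noise, (h, w)), 0, 1.2)
    image = ImageField(
        pixel_size=pixel_size, channels=dict(vessel=channel),
        provenance=f"generate_sprouted_vessel:{seed}",
    )
    truth = GroundTruth(
        kind="sprouted_vessel",
        seed=seed,
        params=dict(
            n_sprouts=n_sprouts, sprout_length_um=sprout_length_um,
            trunk_width_um=trunk_width_um, pixel_size=pixel_size, shape=shape,
            sprout_width_um=sprout_width_um, noise=noise,
        ),
        truth_table=pd.DataFrame(dict(sprout_id=np.arange(1, n_sprouts + 1),
                                      length_um=lengths)),
        scalars=dict(
            n_sprouts=n_sprouts,
            vessel_area_mm2=float(mask.sum()) * pixel_size**2 / 1e6,
        ),
        masks=dict(vessel=mask),
    )
    return image, truth


def generate_node_image(
    tumor_fraction: float = 0.2,
    n_lesions: int = 3,
    pixel_size: float = 2.0,
    shape: tuple[int, int] = (512, 512),
    noise: float = 0.03,
    seed: int = 0,
) -> tuple[ImageField, GroundTruth]:
    """Render a lymph node (elliptical tissue) with planted tumor lesions.

    Lesions are non-overlapping disks inside the node whose summed area is
    ``tumor_fraction`` of the tissue area; truth records the realized pixel
    fraction and per-lesion pixel areas.
    """
    if not (0.0 <= tumor_fraction <= 0.9):
        raise ValueError("tumor_fraction must be in [0, 0.9]")
    if n_lesions < 0 or (tumor_fraction > 0 and n_lesions == 0):
        raise ValueError("n_lesions inconsistent with tumor_fraction")
    rng = _rng(seed, "node_image")
    h, w = shape
    tissue = np.zeros((h, w), dtype=bool)
    rr, cc = draw.ellipse(h / 2, w / 2, h * 0.42, w * 0.42, shape=(h, w))
    tissue[rr, cc] = True
    tissue_px = int(tissue.sum())

    tumor = np.zeros((h, w), dtype=bool)
    lesion_areas: list[float] = []
    if tumor_fraction > 0 and n_lesions > 0:
        target_px = tumor_fraction * tissue_px
        weights = rng.dirichlet(np.full(n_lesions, 4.0))
        radii = np.sqrt(weights * target_px / np.pi)
        # place larger lesions first; each center needs clearance >= its radius
        order = np.argsort(radii)[::-1]
        edt = ndimage.distance_transform_edt(tissue)
        centers: list[tuple[float, float]] = []
        placed_r: list[float] = []
        lesion_label = np.zeros((h, w), dtype=np.int32)
        for k, j in enumerate(order):
            r = radii[j]
            iy, ix = np.nonzero(edt >= r + 2)
            if len(iy) == 0:
                raise PlacementError("node too small for requested lesions")
            ok = False
            for _ in range(4000):
                t = rng.integers(len(iy))
                cy, cx = float(iy[t]), float(ix[t])
                if all(
                    (cy - py) ** 2 + (cx - px) ** 2 > (r + pr + 2) ** 2
                    for (py, px), pr in zip(centers, placed_r)
                ):
                    ok = True
                    break
            if not ok:
                raise PlacementError("could not place lesions without overlap")
            centers.append((cy, cx))
            placed_r.append(r)
            lr, lc = draw.disk((cy, cx), r, shape=(h, w))
            tumor[lr, lc] = True
            lesion_label[lr, lc] = k + 1
        for k in range(n_lesions):
            lesion_areas.append(float(np.sum(lesion_label == k + 1)) * pixel_size**2)
    tumor &= tissue
    realized = float(tumor.sum()) / tissue_px

    tumor_ch = np.where(tumor, 1.0, 0.0) + (rng.normal(0, noise, (h, w)) if noise else 0)
    tumor_ch = np.clip(np.where(tissue, tumor_ch, 0.0), 0, 1.2)
    tissue_ch = tissue.astype(float)
    image = ImageField(
        pixel_size=pixel_size,
        channels=dict(tumor=tumor_ch, tissue=tissue_ch),
        provenance=f"generate_node_image:{seed}",
    )
    truth = GroundTruth(
        kind="node_image",
        seed=seed,
        params=dict(
            tumor_fraction=tumor_fraction, n_lesions=n_lesions,
            pixel_size=pixel_size, shape=shape, noise=noise,
        ),
        truth_table=pd.DataFrame(
            dict(lesion_id=np.arange(1, len(lesion_areas) + 1),
                 area_um2=lesion_areas)
        ),
        scalars=dict(
            tumor_fraction=realized,
            tissue_area_mm2=tissue_px * pixel_size**2 / 1e6,
        ),
        masks=dict(tissue=tissue, tumor=tumor),
    )
    return image, truth


# ---------------------------------------------------------------------------
# RPPA ratio table and cytometry event table
# ---------------------------------------------------------------------------

def generate_rppa_table(
    n_proteins: int = 200,
    ratio_sd: float = 0.05,
    planted: Sequence[tuple[int, float]] = (),
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Paired control/treated intensities whose ratio is 1 + sd*noise.

    Bulk noise is a truncated standard normal (|z| <= 1.2) so the null ratio
    distribution has bounded support, keeping planted outliers (|z| >= 3
    recommended) strictly separable from the bulk.  ``planted`` is a list of
    ``(row index, z)`` deviations; truth records the planted index set.
    """
    if n_proteins < 3:
        raise ValueError("need at least 3 proteins")
    rng = _rng(seed, "rppa_table")
    z = rng.standard_normal(n_proteins)
    # resample tail draws until all bulk z are within +-1.2
    for _ in range(100):
        bad = np.abs(z) > 1.2
        if not bad.any():
            break
        z[bad] = rng.standard_normal(int(bad.sum()))
    ratios = 1.0 + ratio_sd * z
    for idx, zz in planted:
        if not (0 <= idx < n_proteins):
            raise ValueError(f"planted index {idx} out of range")
        ratios[idx] = 1.0 + ratio_sd * zz
    control = rng.lognormal(mean=np.log(10000.0), sigma=0.4, size=n_proteins)
    treated = control * ratios
    table = pd.DataFrame(
        dict(
            protein_id=[f"P{i:04d}" for i in range(n_proteins)],
            control=control,
            treated=treated,
        )
    )
    truth = GroundTruth(
        kind="rppa_table",
        seed=seed,
        params=dict(n_proteins=n_proteins, ratio_sd=ratio_sd, planted=list(planted)),
        truth_table=pd.DataFrame(
            dict(index=[i for i, _ in planted], z=[zz for _, zz in planted])
        ),
        scalars=dict(outlier_indices=sorted(i for i, _ in planted)),
    )
    return table, truth


DEFAULT_POPULATION_FRACTIONS: dict[str, float] = {
    "dead": 0.10, "cd45pos": 0.60, "lec": 0.05,
    "bec": 0.06, "frc": 0.12, "dn": 0.07,
}

# per-population (mean, sd) for each channel, arbitrary log-like units;
# viability dye is bright on dead cells
DEFAULT_CHANNEL_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "dead":    dict(viability=(3.5, 0.30), cd45=(2.8, 0.40), cd31=(1.0, 0.20), gp38=(1.0, 0.20)),
    "cd45pos": dict(viability=(0.8, 0.20), cd45=(3.2, 0.25), cd31=(1.0, 0.18), gp38=(1.0, 0.18)),
    "lec":     dict(viability=(0.8, 0.20), cd45=(1.0, 0.18), cd31=(3.0, 0.25), gp38=(3.0, 0.25)),
    "bec":     dict(viability=(0.8, 0.20), cd45=(1.0, 0.18), cd31=(3.0, 0.25), gp38=(1.0, 0.18)),
    "frc":     dict(viability=(0.8, 0.20), cd45=(1.0, 0.18), cd31=(1.0, 0.18), gp38=(3.0, 0.25)),
    "dn":      dict(viability=(0.8, 0.20), cd45=(1.0, 0.18), cd31=(1.0, 0.18), gp38=(1.0, 0.18)),
}


def generate_event_table(
    n_events: int = 50_000,
    population_fractions: dict[str, float] | None = None,
    channel_params: dict[str, dict[str, tuple[float, float]]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Cytometry event table with well-separated population distributions.

    ``population_fractions`` are fractions of all events and must sum to 1;
    labels are drawn multinomially and recorded per event in the truth table.
    Channels: ``viability`` (dead-cell dye), ``cd45``, ``cd31``, ``gp38``.
    """
    fr = dict(DEFAULT_POPULATION_FRACTIONS if population_fractions is None
              else population_fractions)
    if abs(sum(fr.values()) - 1.0) > 1e-6:
        raise ValueError("population fractions must sum to 1")
    params = DEFAULT_CHANNEL_PARAMS if channel_params is None else channel_params
    rng = _rng(seed, "event_table")
    pops = sorted(fr)
    counts = rng.multinomial(n_events, [fr[p] for p in pops])
    labels = np.repeat(pops, counts)
    labels = labels[rng.permutation(n_events)]
    data = {ch: np.empty(n_events) for ch in ("viability", "cd45", "cd31", "gp38")}
    for p in pops:
        sel = labels == p
        for ch in data:
            mu, sd = params[p][ch]
            data[ch][sel] = rng.normal(mu, sd, int(sel.sum()))
    table = pd.DataFrame(data)
    truth = GroundTruth(
        kind="event_table",
        seed=seed,
        params=dict(n_events=n_events, population_fractions=fr),
        truth_table=pd.DataFrame(dict(label=labels)),
        scalars={f"n_{p}": int(c) for p, c in zip(pops, counts)},
    )
    return table, truth


# ---------------------------------------------------------------------------
# Group measurement tables for the statistics layer
# ---------------------------------------------------------------------------

def generate_group_samples(
    n_groups: int = 2,
    n_per_group: int = 30,
    distribution: str = "normal",
    effect_multipliers: Sequence[float] | None = None,
    base_mean: float = 10.0,
    cv: float = 0.2,
    sd_multipliers: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Long-format measurement table with per-group effect multipliers.

    Group ``i`` has mean ``base_mean * effect_multipliers[i]`` and standard
    deviation ``cv * base_mean * sd_multipliers[i]``.  ``distribution`` is
    ``"normal"`` or ``"lognormal"`` (lognormal matched to the same mean).
    """
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    if distribution not in ("normal", "lognormal"):
        raise ValueError("distribution must be 'normal' or 'lognormal'")
    mult = list(effect_multipliers) if effect_multipliers is not None else [1.0] * n_groups
    sdm = list(sd_multipliers) if sd_multipliers is not None else [1.0] * n_groups
    if len(mult) != n_groups or len(sdm) != n_groups:
        raise ValueError("one multiplier per group required")
    rng = _rng(seed, "group_samples")
    frames = []
    for i in range(n_groups):
        mean_i = base_mean * mult[i]
        sd_i = cv * base_mean * sdm[i]
        if distribution == "normal":
            vals = rng.normal(mean_i, sd_i, n_per_group)
        else:
            s2 = np.log1p((sd_i / mean_i) ** 2)
            vals = rng.lognormal(np.log(mean_i) - s2 / 2, np.sqrt(s2), n_per_group)
        frames.append(pd.DataFrame(dict(group=f"g{i}", value=vals)))
    table = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        kind="group_samples",
        seed=seed,
        params=dict(
            n_groups=n_groups, n_per_group=n_per_group, distribution=distribution,
            effect_multipliers=mult, base_mean=base_mean, cv=cv, sd_multipliers=sdm,
        ),
        truth_table=pd.DataFrame(
            dict(group=[f"g{i}" for i in range(n_groups)],
                 true_mean=[base_mean * m for m in mult],
                 effect_multiplier=mult)
        ),
        scalars=dict(fold_changes=[m / mult[0] for m in mult]),
    )
    return table, truth
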