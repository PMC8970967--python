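"""Vessel segmentation and morphometry against analytic and truth oracles."""

import numpy as np
import pytest
from shapely.geometry import Polygon, box
from skimage import draw
from skimage.color import hed2rgb

from lymphoquant import simulate, vessels
from lymphoquant.datatypes import ImageField


def _disk_mask(radius_px, shape=(200, 200), center=None):
    m = np.zeros(shape, dtype=bool)
    c = center or (shape[0] // 2, shape[1] // 2)
    rr, cc = draw.disk(c, radius_px, shape=shape)
    m[rr, cc] = True
    return m


def _annulus_mask(r_out, r_in, shape=(200, 200)):
    m = _disk_mask(r_out, shape)
    m[_disk_mask(r_in, shape)] = False
    return m


# -- binarization ------------------------------------------------------------

def test_binarize_recovers_vessel_walls_on_synthetic_field():
    """Otsu on the DAB OD channel covers >=95% of wall, <=1% of background."""
    img, truth = simulate.generate_ihc_field(5, seed=1)
    res = vessels.deconvolve_and_binarize(img)
    wall = truth.masks["wall"]
    assert (res.mask & wall).sum() / wall.sum() >= 0.95
    assert (res.mask & ~wall).sum() / (~wall).sum() <= 0.01
    assert np.isfinite(res.threshold)


def test_binarize_all_white_image_is_empty():
    img = ImageField(pixel_size=1.0, rgb=np.ones((64, 64, 3)))
    with pytest.warns(UserWarning):
        res = vessels.deconvolve_and_binarize(img)
    assert not res.mask.any()


def test_binarize_pure_chromogen_is_full():
    hed = np.zeros((32, 32, 3))
    hed[..., 2] = 1.0  # pure DAB optical density
    img = ImageField(pixel_size=1.0, rgb=np.clip(hed2rgb(hed), 0, 1))
    res = vessels.deconvolve_and_binarize(img, policy="fixed", fixed_threshold=0.3)
    assert res.mask.all()


def test_binarize_requires_rgb():
    img = ImageField(pixel_size=1.0, channels=dict(x=np.zeros((8, 8))))
    with pytest.raises(ValueError):
        vessels.deconvolve_and_binarize(img)


# -- extraction and morphometry ----------------------------------------------

def test_disk_area_and_perimeter_oracles():
    """Solid disk r=50 px at 1 um/px: area ~ pi*50^2, perimeter ~ 2*pi*50."""
    recs, _ = vessels.extract_vessels(_disk_mask(50), pixel_size=1.0)
    assert len(recs) == 1
    assert recs[0].area_um2 == pytest.approx(np.pi * 50**2, rel=0.02)
    assert recs[0].perimeter_um == pytest.approx(2 * np.pi * 50, rel=0.05)
    assert recs[0].centroid_um == pytest.approx((100, 100), abs=0.5)


def test_annulus_filled_to_outer_disk_area():
    """Flood-fill counts the lumen: annulus area ~ outer disk area."""
    recs, _ = vessels.extract_vessels(_annulus_mask(30, 15), pixel_size=1.0)
    assert len(recs) == 1
    assert recs[0].area_um2 == pytest.approx(np.pi * 30**2, rel=0.03)


def test_empty_mask_yields_no_records():
    recs, lab = vessels.extract_vessels(np.zeros((50, 50), bool), 1.0)
    assert recs == [] and lab.max() == 0


def test_min_area_filter_discards_debris():
    m = _disk_mask(20, center=(50, 50))
    m |= _disk_mask(2, center=(150, 150))  # ~12 um^2 debris
    recs, _ = vessels.extract_vessels(m, 1.0, min_area_um2=50.0)
    assert len(recs) == 1


def test_fill_idempotence():
    """extract(fill(mask)) == extract(mask) in counts and areas."""
    from scipy.ndimage import binary_fill_holes

    m = _annulus_mask(30, 15)
    r1, _ = vessels.extract_vessels(m, 1.0)
    r2, _ = vessels.extract_vessels(binary_fill_holes(m), 1.0)
    assert len(r1) == len(r2)
    assert r1[0].area_um2 == r2[0].area_um2


def test_rotation_invariance():
    m = _annulus_mask(25, 10, shape=(120, 180))
    m |= _disk_mask(15, shape=(120, 180), center=(30, 140))
    r0, _ = vessels.extract_vessels(m, 1.0)
    r90, _ = vessels.extract_vessels(np.rot90(m), 1.0)
    assert len(r0) == len(r90)
    assert sorted(r.area_um2 for r in r0) == sorted(r.area_um2 for r in r90)
    # centroid transforms with the rotation: (x, y) -> (y, W-1-x)
    a0 = sorted(r0, key=lambda r: r.area_um2)
    a90 = sorted(r90, key=lambda r: r.area_um2)
    for r, q in zip(a0, a90):
        assert q.centroid_um[0] == pytest.approx(r.centroid_um[1], abs=1e-6)
        assert q.centroid_um[1] == pytest.approx(179 - r.centroid_um[0], abs=1e-6)


def test_scale_covariance():
    """Doubling pixel size quadruples areas and doubles perimeters."""
    m = _disk_mask(30)
    r1, _ = vessels.extract_vessels(m, 1.0)
    r2, _ = vessels.extract_vessels(m, 2.0)
    assert r2[0].area_um2 == pytest.approx(4 * r1[0].area_um2)
    assert r2[0].perimeter_um == pytest.approx(2 * r1[0].perimeter_um)


# -- manual ROI merge --------------------------------------------------------

def _square_roi(x0, y0, side):
    return box(x0, y0, x0 + side, y0 + side)


def test_roi_overlapping_auto_replaces_it():
    m = _disk_mask(20, center=(50, 50))
    recs, lab = vessels.extract_vessels(m, 1.0)
    roi = _square_roi(28, 28, 44)  # IoU with the disk ~ 0.65
    merged = vessels.merge_manual_rois(recs, lab, [roi], 1.0)
    assert len(merged) == 1
    assert merged[0].provenance == "manual"
    assert merged[0].area_um2 == pytest.approx(44 * 44)


def test_roi_disjoint_is_appended():
    m = _disk_mask(20, center=(50, 50))
    recs, lab = vessels.extract_vessels(m, 1.0)
    merged = vessels.merge_manual_rois(recs, lab, [_square_roi(120, 120, 30)], 1.0)
    assert len(merged) == 2
    assert sorted(r.provenance for r in merged) == ["auto", "manual"]


def test_empty_roiset_is_identity():
    m = _disk_mask(20, center=(50, 50))
    recs, lab = vessels.extract_vessels(m, 1.0)
    assert vessels.merge_manual_rois(recs, lab, [], 1.0) == recs


def test_self_intersecting_roi_rejected():
    bowtie = Polygon([(0, 0), (10, 10), (10, 0), (0, 10)])
    m = _disk_mask(20)
    recs, lab = vessels.extract_vessels(m, 1.0)
    with pytest.raises(ValueError):
        vessels.merge_manual_rois(recs, lab, [bowtie], 1.0)


# -- LVD ---------------------------------------------------------------------

def _records(n):
    return [
        __import__("lymphoquant").VesselRecord(
            id=i + 1, centroid_um=(10.0 * i + 5, 10.0), area_um2=100.0,
            perimeter_um=40.0,
        )
        for i in range(n)
    ]


def test_lvd_arithmetic():
    assert vessels.compute_lvd(_records(10), 2.0).lvd == 5.0
    assert vessels.compute_lvd([], 2.0).lvd == 0.0


def test_lvd_unit_conversion_from_mask():
    """4,000,000 stroma px at 0.5 um/px is 1.0 mm^2 -> 12 vessels give 12.0."""
    stroma = np.ones((2000, 2000), dtype=bool)
    res = vessels.compute_lvd(_records(12), stroma, pixel_size=0.5)
    assert res.stromal_area_mm2 == pytest.approx(1.0)
    assert res.lvd == pytest.approx(12.0)


def test_lvd_excludes_centroids_outside_stroma():
    stroma = np.zeros((100, 100), dtype=bool)
    stroma[:, :50] = True  # only x < 50 um is stroma
    recs = _records(5)  # centroids at x = 5, 15, 25, 35, 45
    recs += [
        __import__("lymphoquant").VesselRecord(
            id=9, centroid_um=(80.0, 10.0), area_um2=100.0, perimeter_um=40.0)
    ]
    res = vessels.compute_lvd(recs, stroma, pixel_size=1.0)
    assert res.n_vessels == 5
    assert res.excluded_outside_stroma == 1


def test_lvd_zero_area_rejected():
    with pytest.raises(ValueError):
        vessels.compute_lvd(_records(1), 0.0)
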