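"""Monolayer fluorescence quantification against generator truth."""

import numpy as np
import pytest

from lymphoquant import monolayer, simulate


# -- percent positive --------------------------------------------------------

def test_percent_positive_recovers_planted_fraction():
    img, truth = simulate.generate_nuclei_marker_field(500, 0.3, seed=1)
    fq = monolayer.percent_positive_cells(
        img.channels["nuclei"], img.channels["marker"], img.pixel_size
    )
    assert fq.percent == pytest.approx(truth.scalars["percent_positive"], abs=2.0)
    assert abs(fq.n_cells - 500) <= 10


def test_percent_positive_zero_marker_is_zero():
    img, _ = simulate.generate_nuclei_marker_field(200, 0.5, seed=2)
    fq = monolayer.percent_positive_cells(
        img.channels["nuclei"], np.zeros(img.shape), img.pixel_size
    )
    assert fq.percent == 0.0


def test_off_target_signal_scores_zero_under_perinuclear_rule():
    img, _ = simulate.generate_nuclei_marker_field(
        300, 0.4, colocalization="off_target", seed=3
    )
    fq = monolayer.percent_positive_cells(
        img.channels["nuclei"], img.channels["marker"], img.pixel_size,
        rule="nucleus_plus_perinuclear",
    )
    assert fq.percent == 0.0


def test_raising_marker_threshold_never_raises_percent():
    img, _ = simulate.generate_nuclei_marker_field(300, 0.4, seed=4)
    pcts = [
        monolayer.percent_positive_cells(
            img.channels["nuclei"], img.channels["marker"], img.pixel_size,
            marker_threshold=t,
        ).percent
        for t in (0.3, 0.5, 0.8, 1.5)
    ]
    assert all(b <= a for a, b in zip(pcts, pcts[1:]))


def test_empty_nuclei_channel_errors():
    with pytest.raises(ValueError, match="no cells"):
        monolayer.percent_positive_cells(
            np.zeros((64, 64)), np.zeros((64, 64)), 1.0
        )


# -- junction gaps -----------------------------------------------------------

def test_confluent_monolayer_has_no_gaps():
    img, _ = simulate.generate_monolayer_field(300, 0.0, seed=5)
    fq = monolayer.quantify_junction_gaps(
        img.channels["junction"], img.channels["nuclei"], img.pixel_size
    )
    assert fq.extras["gap_fraction"] == pytest.approx(0.0, abs=0.005)
    assert fq.percent == pytest.approx(0.0, abs=2.0)


def test_gap_fraction_recovery():
    img, truth = simulate.generate_monolayer_field(400, 0.10, seed=6)
    fq = monolayer.quantify_junction_gaps(
        img.channels["junction"], img.channels["nuclei"], img.pixel_size
    )
    assert fq.extras["gap_fraction"] == pytest.approx(
        truth.scalars["gap_fraction"], abs=0.01
    )
    assert fq.percent == pytest.approx(
        truth.scalars["non_cohesive_percent"], abs=5.0
    )


def test_raising_min_gap_area_never_raises_gap_count():
    img, _ = simulate.generate_monolayer_field(400, 0.15, seed=7)
    counts = [
        monolayer.quantify_junction_gaps(
            img.channels["junction"], img.channels["nuclei"], img.pixel_size,
            min_gap_area_um2=a,
        ).extras["n_gaps"]
        for a in (1000, 2000, 5000, 20000)
    ]
    assert all(b <= a for a, b in zip(counts, counts[1:]))


def test_no_junction_signal_errors():
    with pytest.raises(ValueError, match="junction"):
        monolayer.quantify_junction_gaps(
            np.zeros((64, 64)), np.ones((64, 64)), 1.0
        )


# -- hotspots ----------------------------------------------------------------

def test_hotspot_uniform_positives_near_global_fraction():
    """Uniform 20% positives: mean hotspot percent within 5 points of 20."""
    vals = []
    for seed in range(50):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 512, size=(500, 2))
        flags = rng.random(500) < 0.2
        fq = monolayer.hotspot_positive_fraction(pts, flags, (512, 512))
        vals.append(fq.percent)
    assert abs(np.mean(vals) - 20.0) <= 5.0


def test_hotspot_concentrated_positives_dominate():
    rng = np.random.default_rng(0)
    cluster = rng.uniform(20, 180, size=(200, 2))  # dense positives, one window
    background = rng.uniform(0, 512, size=(30, 2))
    pts = np.vstack([cluster, background])
    flags = np.arange(len(pts)) < len(cluster)
    fq = monolayer.hotspot_positive_fraction(pts, flags, (512, 512))
    assert fq.percent >= 90.0


def test_hotspot_zero_positives_is_zero():
    rng = np.random.default_rng(1)
    pts = rng.uniform(0, 512, size=(100, 2))
    fq = monolayer.hotspot_positive_fraction(
        pts, np.zeros(100, bool), (512, 512)
    )
    assert fq.percent == 0.0


def test_hotspot_window_larger_than_field_rejected():
    with pytest.raises(ValueError):
        monolayer.hotspot_positive_fraction(
            np.zeros((20, 2)), np.zeros(20, bool), (100, 100), window_um=200
        )


# -- invasion ----------------------------------------------------------------

def test_percent_invasion_arithmetic():
    """500 cells over 10% of the membrane, 100,000 seeded -> 5.0%."""
    roll = monolayer.percent_invasion(
        {"w1": [100, 100, 100, 100, 100]}, field_area_fraction=0.1,
        seeded=100_000,
    )
    assert roll.per_well["w1"] == pytest.approx(5.0)
    assert roll.biological == pytest.approx(5.0)


def test_percent_invasion_biological_mean_of_wells():
    roll = monolayer.percent_invasion(
        {"w1": [40], "w2": [50], "w3": [60]}, 0.1, 10_000
    )
    assert roll.biological == pytest.approx(5.0)
    assert roll.n_wells == 3


def test_percent_invasion_zero_counts():
    roll = monolayer.percent_invasion({"w1": [0, 0, 0]}, 0.2, 1000)
    assert roll.biological == 0.0


def test_percent_invasion_field_order_invariance():
    a = monolayer.percent_invasion({"w1": [10, 20, 30]}, 0.1, 1000)
    b = monolayer.percent_invasion({"w1": [30, 10, 20]}, 0.1, 1000)
    assert a.per_well == b.per_well and a.biological == b.biological


def test_percent_invasion_validations():
    with pytest.raises(ValueError):
        monolayer.percent_invasion({"w": [1]}, 0.1, 0)
    with pytest.raises(ValueError):
        monolayer.percent_invasion({}, 0.1, 100)
    with pytest.raises(ValueError):
        monolayer.percent_invasion({"w": [1]}, 1.5, 100)
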