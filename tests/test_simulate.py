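"""Generator contracts: determinism, truth consistency, monotonicity."""

import numpy as np
import pandas as pd
import pytest

from lymphoquant import simulate


def _image_bytes(img):
    parts = []
    if img.rgb is not None:
        parts.append(img.rgb.tobytes())
    for name in sorted(img.channels):
        parts.append(img.channels[name].tobytes())
    return b"".join(parts)


GEN_CALLS = {
    "ihc": lambda s: simulate.generate_ihc_field(5, seed=s),
    "monolayer": lambda s: simulate.generate_monolayer_field(200, 0.1, seed=s),
    "nuclei": lambda s: simulate.generate_nuclei_marker_field(100, 0.3, seed=s),
    "sprouts": lambda s: simulate.generate_sprouted_vessel(3, seed=s),
    "node": lambda s: simulate.generate_node_image(0.2, 3, seed=s),
}


@pytest.mark.parametrize("name", sorted(GEN_CALLS))
def test_image_generators_are_deterministic(name):
    """Same (seed, params) twice -> byte-identical image and truth table."""
    img1, t1 = GEN_CALLS[name](7)
    img2, t2 = GEN_CALLS[name](7)
    assert _image_bytes(img1) == _image_bytes(img2)
    pd.testing.assert_frame_equal(t1.truth_table, t2.truth_table)
    img3, _ = GEN_CALLS[name](8)
    assert _image_bytes(img1) != _image_bytes(img3)


def test_table_generators_are_deterministic():
    for gen in (
        lambda s: simulate.generate_rppa_table(50, seed=s)[0],
        lambda s: simulate.generate_event_table(2000, seed=s)[0],
        lambda s: simulate.generate_group_samples(seed=s)[0],
    ):
        pd.testing.assert_frame_equal(gen(3), gen(3))
        assert not gen(3).equals(gen(4))


def test_generator_streams_are_independent():
    """The named-stream design: one generator's draw never shifts another's."""
    img_a, _ = simulate.generate_ihc_field(3, seed=11)
    simulate.generate_monolayer_field(100, 0.1, seed=11)
    img_b, _ = simulate.generate_ihc_field(3, seed=11)
    assert _image_bytes(img_a) == _image_bytes(img_b)


# -- IHC field ---------------------------------------------------------------

def test_ihc_empty_field_has_no_vessels():
    img, truth = simulate.generate_ihc_field(0, seed=1)
    assert len(truth.truth_table) == 0
    assert truth.masks["label"].max() == 0
    assert img.rgb.shape == (512, 512, 3)


def test_ihc_truth_area_matches_analytic_ellipse():
    """Rendered per-vessel area within 3% of pi*a*b for the sampled axes."""
    _, truth = simulate.generate_ihc_field(
        5, radius_range_um=(20, 40), seed=5
    )
    t = truth.truth_table
    assert len(t) == 5
    rel = np.abs(t.area_um2 - t.area_analytic_um2) / t.area_analytic_um2
    assert (rel < 0.03).all()


def test_ihc_truth_area_equals_label_mask_area():
    """Truth consistency: truth areas are exact pixel counts of the labels."""
    _, truth = simulate.generate_ihc_field(4, pixel_size=2.0, seed=9)
    lab = truth.masks["label"]
    for row in truth.truth_table.itertuples():
        assert row.area_um2 == pytest.approx(
            np.sum(lab == row.vessel_id) * 4.0
        )


def test_ihc_placement_failure_raises():
    with pytest.raises(simulate.PlacementError):
        simulate.generate_ihc_field(
            200, radius_range_um=(40, 40), shape=(128, 128), seed=0
        )


# -- monolayer ---------------------------------------------------------------

def test_monolayer_zero_gap_is_fully_closed():
    _, truth = simulate.generate_monolayer_field(300, 0.0, seed=2)
    assert truth.scalars["gap_fraction"] == 0.0
    assert truth.masks["gap"].sum() == 0
    assert truth.scalars["non_cohesive_percent"] == 0.0


def test_monolayer_realized_gap_tracks_request():
    _, truth = simulate.generate_monolayer_field(400, 0.10, seed=3)
    assert truth.scalars["gap_fraction"] == pytest.approx(0.10, abs=0.01)


def test_monolayer_truth_matches_rendered_gap_pixels():
    img, truth = simulate.generate_monolayer_field(400, 0.15, seed=4)
    gap = truth.masks["gap"]
    assert truth.scalars["gap_fraction"] == pytest.approx(gap.mean())
    # gaps are junction-free in the rendered channel (up to additive noise)
    assert img.channels["junction"][gap].max() < 0.5


def test_monolayer_gap_monotonicity():
    """Raising the requested gap fraction strictly raises the truth gap."""
    fracs = [0.0, 0.05, 0.10, 0.20]
    realized = [
        simulate.generate_monolayer_field(400, f, seed=6)[1].scalars["gap_fraction"]
        for f in fracs
    ]
    assert all(b > a for a, b in zip(realized, realized[1:]))


def test_monolayer_infeasible_gap_raises():
    with pytest.raises(ValueError):
        simulate.generate_monolayer_field(100, 0.9, seed=0)


# -- nuclei/marker -----------------------------------------------------------

def test_nuclei_truth_count_is_deterministic_assignment():
    _, truth = simulate.generate_nuclei_marker_field(500, 0.3, seed=1)
    assert truth.scalars["n_positive"] == 150
    assert truth.truth_table["positive"].sum() == 150


def test_nuclei_zero_positive_marker_empty_over_nuclei():
    img, truth = simulate.generate_nuclei_marker_field(
        200, 0.0, noise=0.0, seed=1
    )
    assert truth.scalars["n_positive"] == 0
    assert img.channels["marker"][img.channels["nuclei"] > 0.5].max() == 0.0


def test_nuclei_off_target_truth_is_zero():
    _, truth = simulate.generate_nuclei_marker_field(
        200, 0.4, colocalization="off_target", seed=1
    )
    assert truth.scalars["n_positive"] == 0


def test_nuclei_positive_fraction_monotonicity():
    counts = [
        simulate.generate_nuclei_marker_field(400, f, seed=2)[1].scalars["n_positive"]
        for f in (0.1, 0.3, 0.5)
    ]
    assert counts == [40, 120, 200]


# -- sprouted vessel and node ------------------------------------------------

def test_sprout_counts_by_construction():
    for n in (0, 4):
        _, truth = simulate.generate_sprouted_vessel(n, seed=3)
        assert truth.scalars["n_sprouts"] == n
        assert len(truth.truth_table) == n


def test_sprout_requires_length_above_trunk_width():
    with pytest.raises(ValueError):
        simulate.generate_sprouted_vessel(2, sprout_length_um=10,
                                          trunk_width_um=12, seed=0)


def test_node_tumor_fraction_within_tolerance():
    _, truth = simulate.generate_node_image(0.2, 3, seed=4)
    assert truth.scalars["tumor_fraction"] == pytest.approx(0.2, abs=0.01)


def test_node_fraction_monotonicity():
    vals = [
        simulate.generate_node_image(f, 3, seed=5)[1].scalars["tumor_fraction"]
        for f in (0.05, 0.2, 0.4)
    ]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_node_truth_equals_planted_pixels():
    _, truth = simulate.generate_node_image(0.3, 4, seed=6)
    tumor, tissue = truth.masks["tumor"], truth.masks["tissue"]
    assert truth.scalars["tumor_fraction"] == pytest.approx(
        tumor.sum() / tissue.sum()
    )
    assert truth.truth_table["area_um2"].sum() == pytest.approx(
        tumor.sum() * truth.params["pixel_size"] ** 2
    )


# -- tables ------------------------------------------------------------------

def test_rppa_zero_noise_gives_unit_ratios():
    table, truth = simulate.generate_rppa_table(50, ratio_sd=0.0, seed=1)
    np.testing.assert_allclose(table.treated / table.control, 1.0, rtol=1e-12)
    assert truth.scalars["outlier_indices"] == []


def test_rppa_planted_truth_set():
    _, truth = simulate.generate_rppa_table(
        200, 0.05, planted=[(7, 5.0)], seed=2
    )
    assert truth.scalars["outlier_indices"] == [7]


def test_event_table_multinomial_truth_counts():
    """Planted 5% LECs at n=50,000 land near 2,500 (multinomial draw)."""
    table, truth = simulate.generate_event_table(50_000, seed=3)
    labels = truth.truth_table["label"]
    n_lec = (labels == "lec").sum()
    assert n_lec == truth.scalars["n_lec"]
    sd = np.sqrt(50_000 * 0.05 * 0.95)
    assert abs(n_lec - 2500) < 5 * sd
    assert len(table) == 50_000


def test_event_fractions_must_sum_to_one():
    with pytest.raises(ValueError):
        simulate.generate_event_table(
            100, population_fractions=dict(dead=0.5, cd45pos=0.2, lec=0.1,
                                           bec=0.1, frc=0.05, dn=0.1),
            seed=0,
        )


def test_group_samples_unit_multipliers_give_unit_folds():
    _, truth = simulate.generate_group_samples(
        3, 10, effect_multipliers=[1, 1, 1], seed=4
    )
    assert truth.scalars["fold_changes"] == [1.0, 1.0, 1.0]


def test_group_samples_mean_ratio_near_multiplier():
    """effect multiplier 3 at n=30: sample mean ratio within 3 SEM of 3."""
    table, truth = simulate.generate_group_samples(
        2, 30, effect_multipliers=[1.0, 3.0], seed=5
    )
    means = table.groupby("group")["value"].mean()
    sems = table.groupby("group")["value"].sem()
    ratio = means["g1"] / means["g0"]
    # conservative error propagation on the ratio
    sem_ratio = ratio * np.sqrt((sems["g0"] / means["g0"]) ** 2
                                + (sems["g1"] / means["g1"]) ** 2)
    assert abs(ratio - 3.0) < 3 * sem_ratio
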