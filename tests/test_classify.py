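"""Intake aggregation arithmetic, whole-grain exposure and the
mean-of-ratios convention for percent of grain from whole grain."""

import numpy as np
import pandas as pd
import pytest

from grainscore.classify import (build_intake_profile, build_intake_profiles,
                                 compute_wg_exposure, food_group_cell_columns,
                                 group_mean_pct_grain, tier_block_totals)

from conftest import recalls_frame


def test_empty_records_give_all_zero_profile(toy_catalog):
    prof = build_intake_profiles(recalls_frame(), toy_catalog, ["P1"])
    row = prof.loc["P1"]
    assert row["energy_kcal"] == 0.0
    assert (row[food_group_cell_columns()] == 0).all()
    assert row["fiber"] == 0.0
    assert row["macro_pct_carbohydrate"] == 0.0


def test_hand_summed_two_food_menu(toy_catalog):
    # 100 g WG bread + 50 g refined pasta, densities from the toy catalog
    recalls = recalls_frame(("P1", "B1", 100.0), ("P1", "R1", 50.0))
    row = build_intake_profile(recalls, toy_catalog, "P1")
    assert row["energy_kcal"] == pytest.approx(100 * 2.5 + 50 * 1.5)     # 325
    assert row["fiber"] == pytest.approx(100 * 0.05 + 50 * 0.02)         # 6.0
    assert row["sodium"] == pytest.approx(100 * 5.0 + 50 * 0.02)         # 501
    assert row["carbohydrate"] == pytest.approx(100 * 0.45 + 50 * 0.30)  # 60
    assert row["macro_pct_carbohydrate"] == pytest.approx(60 * 4 / 325 * 100)
    assert row["fg_whole_grains_t13"] == 100.0
    assert row["fg_refined_grains_t13"] == 50.0


def test_single_food_fiber():
    from conftest import make_food
    from grainscore.catalog_io import validate_catalog
    cat = validate_catalog(pd.DataFrame([make_food("X1", "fruit", 1, energy=1.0, fiber=0.05)]))
    row = build_intake_profile(recalls_frame(("P1", "X1", 100.0)), cat, "P1")
    assert row["fiber"] == pytest.approx(5.0)


def test_profiles_additive_over_record_partitions(small_sim):
    _, catalog, participants, recalls = small_sim
    ids = participants["participant_id"]
    full = build_intake_profiles(recalls, catalog, ids)
    half = len(recalls) // 2
    part_a = build_intake_profiles(recalls.iloc[:half], catalog, ids)
    part_b = build_intake_profiles(recalls.iloc[half:], catalog, ids)
    drop = [c for c in full.columns if c.startswith("macro_pct")]
    pd.testing.assert_frame_equal(
        part_a.drop(columns=drop) + part_b.drop(columns=drop),
        full.drop(columns=drop), check_exact=False, rtol=1e-9)


def test_tier_block_totals_consistent(small_sim):
    _, catalog, participants, recalls = small_sim
    prof = build_intake_profiles(recalls, catalog, participants["participant_id"])
    totals = tier_block_totals(prof)
    all_cells = prof[food_group_cell_columns()].sum(axis=1)
    np.testing.assert_allclose(
        totals.sum(axis=1).to_numpy(), all_cells.to_numpy(), rtol=1e-9)


def test_wg_exposure_hand_case(toy_catalog):
    # 60 g WG bread (30 g/serving) + 40 g refined pasta
    recalls = recalls_frame(("P1", "B1", 60.0), ("P1", "R1", 40.0))
    exp = compute_wg_exposure(recalls, toy_catalog, ["P1"])
    row = exp.loc["P1"]
    assert row["wg_grams"] == 60.0
    assert row["wg_servings"] == pytest.approx(2.0)
    assert row["total_grain_grams"] == 100.0
    assert row["pct_grain_from_wg"] == pytest.approx(60.0)


def test_no_grain_diet_counts_as_zero_percent(toy_catalog):
    exp = compute_wg_exposure(recalls_frame(("P1", "F1", 150.0)), toy_catalog, ["P1"])
    row = exp.loc["P1"]
    assert row["wg_grams"] == 0.0
    assert row["total_grain_grams"] == 0.0
    assert row["pct_grain_from_wg"] == 0.0


def test_wg_grams_match_food_group_cells(small_sim):
    _, catalog, participants, recalls = small_sim
    ids = participants["participant_id"]
    prof = build_intake_profiles(recalls, catalog, ids)
    exp = compute_wg_exposure(recalls, catalog, ids)
    np.testing.assert_allclose(
        exp["wg_grams"].to_numpy(),
        (prof["fg_whole_grains_t13"] + prof["fg_whole_grains_t4"]).to_numpy(),
        rtol=1e-9)
    assert (exp["wg_grams"] <= exp["total_grain_grams"] + 1e-9).all()
    assert exp["pct_grain_from_wg"].between(0, 100).all()


def test_group_mean_is_mean_of_ratios(toy_catalog):
    # (wg, total): (10,100)=10%, (50,100)=50%, (30,50)=60%
    recalls = recalls_frame(
        ("P1", "B1", 10.0), ("P1", "R1", 90.0),
        ("P2", "B1", 50.0), ("P2", "R1", 50.0),
        ("P3", "B1", 30.0), ("P3", "R1", 20.0),
    )
    exp = compute_wg_exposure(recalls, toy_catalog, ["P1", "P2", "P3"])
    mean_of_ratios = group_mean_pct_grain(exp, np.ones(3))
    assert mean_of_ratios == pytest.approx(40.0)
    ratio_of_means = 100 * exp["wg_grams"].mean() / exp["total_grain_grams"].mean()
    assert ratio_of_means == pytest.approx(36.0)
    assert mean_of_ratios != ratio_of_means

    # equal-weight two-participant example: 20% and 40% average to 30%
    recalls2 = recalls_frame(("A", "B1", 20.0), ("A", "R1", 80.0),
                             ("B", "B1", 40.0), ("B", "R1", 60.0))
    exp2 = compute_wg_exposure(recalls2, toy_catalog, ["A", "B"])
    assert group_mean_pct_grain(exp2, np.ones(2)) == pytest.approx(30.0)


def test_group_mean_requires_nonempty_group(toy_catalog):
    exp = compute_wg_exposure(recalls_frame(), toy_catalog, [])
    with pytest.raises(ValueError, match="nonempty"):
        group_mean_pct_grain(exp, np.array([]))
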