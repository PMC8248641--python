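"""Top-source ranking by BNS food group: coverage, determinism and
recovery of a constructed dominant source."""

import numpy as np
import pandas as pd
import pytest

from grainscore import SimulationConfig, generate_catalog, generate_survey
from grainscore.catalog_io import replicate_columns, validate_catalog
from grainscore.classify import compute_wg_exposure
from grainscore.simulate import WG_BNS_GROUPS
from grainscore.sources import percent_change, rank_wg_sources, top_total
from grainscore.stratify import assign_wg_groups

from conftest import make_food, recalls_frame


def _assignments(recalls, catalog, participants):
    exp = compute_wg_exposure(recalls, catalog, participants["participant_id"])
    ages = participants.set_index("participant_id")["age_years"]
    return assign_wg_groups(exp, ages)


def test_single_wg_food_covers_everything():
    rows = [
        make_food("WG1", "whole_grains", 1, "whole grain and whole wheat bread",
                  True, 30.0, energy=2.0, fiber=0.06),
        make_food("R1", "refined_grains", 1, "pasta", False, 70.0, energy=1.5),
    ]
    catalog = validate_catalog(pd.DataFrame(rows))
    # six adult consumers so tertiles are formable
    recs = [(f"P{i}", "WG1", 10.0 * (i + 1)) for i in range(6)]
    recalls = recalls_frame(*recs)
    participants = pd.DataFrame({
        "participant_id": [f"P{i}" for i in range(6)],
        "age_years": [40.0] * 6, "weight": [1.0] * 6,
    })
    asg = _assignments(recalls, catalog, participants)
    tables = rank_wg_sources(recalls, catalog, asg, None,
                             participants.set_index("participant_id")["weight"],
                             adjusted=False)
    table = tables[("adult", "high_wg")]
    assert len(table.rows) == 1
    assert table.rows["bns_group"].iloc[0] == "whole grain and whole wheat bread"
    assert table.pct_of_total_wg == pytest.approx(100.0)


@pytest.fixture(scope="module")
def dominant_sim():
    """One BNS group constructed to carry 80% of WG grams."""
    shares = {WG_BNS_GROUPS[0]: 0.80}
    rest = 0.20 / 5
    for label in WG_BNS_GROUPS[1:6]:
        shares[label] = rest
    config = SimulationConfig(seed=23, n_children=1, n_adults=2000,
                              n_replicates=8, n_foods_per_category=6,
                              wg_bns_shares=shares)
    catalog = generate_catalog(config)
    participants, recalls = generate_survey(config, catalog)
    participants = participants[participants["age_years"] >= 19].reset_index(drop=True)
    recalls = recalls[recalls["participant_id"].isin(participants["participant_id"])]
    return config, catalog, participants, recalls


def test_constructed_dominant_source_recovered(dominant_sim):
    _, catalog, participants, recalls = dominant_sim
    asg = _assignments(recalls, catalog, participants)
    w = participants.set_index("participant_id")["weight"]
    tables = rank_wg_sources(recalls, catalog, asg, None, w, adjusted=False)
    for group in ("low_wg", "mid_wg", "high_wg"):
        table = tables[("adult", group)]
        assert table.rows["bns_group"].iloc[0] == WG_BNS_GROUPS[0]
        share = 100.0 * table.rows["mean_grams"].iloc[0] / table.total_wg_grams
        assert share == pytest.approx(80.0, abs=3.0)


def test_coverage_invariants_and_catalog_order_invariance(dominant_sim):
    _, catalog, participants, recalls = dominant_sim
    asg = _assignments(recalls, catalog, participants)
    w = participants.set_index("participant_id")["weight"]
    tables = rank_wg_sources(recalls, catalog, asg, None, w, adjusted=False)

    shuffled = catalog.sample(frac=1.0, random_state=9).reset_index(drop=True)
    tables_shuffled = rank_wg_sources(recalls, shuffled, asg, None, w, adjusted=False)

    for key, table in tables.items():
        assert table.top10_total_grams <= table.total_wg_grams + 1e-9
        assert 0.0 <= table.pct_of_total_wg <= 100.0
        diffs = np.diff(table.rows["mean_grams"].to_numpy())
        assert (diffs <= 1e-12).all()
        pd.testing.assert_frame_equal(table.rows, tables_shuffled[key].rows)


def test_adjusted_ranking_runs_with_covariates(small_sim):
    _, catalog, participants, recalls = small_sim
    from grainscore.classify import build_intake_profiles
    from grainscore.survey import build_covariates
    asg = _assignments(recalls, catalog, participants)
    part = participants.set_index("participant_id")
    prof = build_intake_profiles(recalls, catalog, participants["participant_id"])
    cov = {
        s: build_covariates(part.loc[asg.index[asg["stratum"] == s]],
                            prof["energy_kcal"])
        for s in ("child", "adult")
    }
    rep = part[replicate_columns(participants)]
    tables = rank_wg_sources(recalls, catalog, asg, cov, part["weight"], rep,
                             adjusted=True)
    assert ("adult", "high_wg") in tables
    table = tables[("adult", "high_wg")]
    assert (table.rows["se"] > 0).any()


def test_top_total_and_percent_change_helpers():
    rows = pd.DataFrame({
        "bns_group": list("abcdefghijk"),
        "mean_grams": [11.0, 10, 9, 8, 7, 6, 5, 4, 3, 2, 1],
        "se": 0.1,
    })
    assert top_total(rows) == pytest.approx(65.0)  # top 10 of 11
    assert percent_change(25.0, 200.0) == pytest.approx(700.0)
    assert percent_change(100.0, 48.0) == pytest.approx(-52.0)
    with pytest.raises(ZeroDivisionError):
        percent_change(0.0, 1.0)
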