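"""Shared fixtures: a hand-sized food catalog with round densities for
arithmetic oracles, and small simulated surveys."""

import numpy as np
import pandas as pd
import pytest

from grainscore import SimulationConfig, generate_catalog, generate_survey
from grainscore.catalog_io import nutrient_columns, validate_catalog
from grainscore.schema import ENERGY_COL


def make_food(food_code, cfg_group, cfg_tier=None, bns_group="misc",
              is_whole_grain=False, grams_per_serving=None, energy=1.0, **densities):
    row = {
        "food_code": food_code,
        "description": f"toy {food_code}",
        "cfg_group": cfg_group,
        "cfg_tier": cfg_tier if cfg_tier is not None else np.nan,
        "bns_group": bns_group,
        "is_whole_grain": is_whole_grain,
        "grams_per_serving": grams_per_serving if grams_per_serving is not None else np.nan,
        ENERGY_COL: energy,
    }
    for col in nutrient_columns():
        row[col] = 0.0
    for nid, dens in densities.items():
        row["nut_" + nid] = dens
    return row


@pytest.fixture
def toy_catalog():
    """Three foods with round numbers: a WG bread (tier 2, 30 g/serving),
    a refined pasta (tier 1) and an apple."""
    rows = [
        make_food("B1", "whole_grains", 2, "whole grain and whole wheat bread",
                  True, 30.0, energy=2.5, fiber=0.05, sodium=5.0, carbohydrate=0.45),
        make_food("R1", "refined_grains", 1, "pasta", False, 70.0,
                  energy=1.5, fiber=0.02, sodium=0.02, carbohydrate=0.30),
        make_food("F1", "fruit", 1, "fresh fruit", False, 120.0,
                  energy=0.5, fiber=0.024, vitamin_c=0.05, carbohydrate=0.14),
    ]
    return validate_catalog(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated survey reused across read-only tests."""
    config = SimulationConfig(seed=11, n_children=300, n_adults=300, n_replicates=16)
    catalog = generate_catalog(config)
    participants, recalls = generate_survey(config, catalog)
    return config, catalog, participants, recalls


def recalls_frame(*rows):
    return pd.DataFrame(rows, columns=["participant_id", "food_code", "grams"])
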