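"""Per-participant intake aggregation from 24-h recall records.

Everything here is plain grams-times-density arithmetic over the recall
table joined to the food catalog:

* nutrient and energy intake: sum over records of ``grams x density``;
* food-group gram totals in the reporting cells (ten CFG categories split
  into tiers 1-3 vs tier 4, plus the three non-CFG buckets);
* whole-grain (WG) exposure: WG grams, WG servings, total grain grams
  (refined + whole, tiers 1-4) and the percent of grain intake from WG.

Percent-of-grain is computed per participant as ``100 * wg / total_grain``
and averaged as a mean of ratios (not a ratio of means); participants with
no grain intake contribute 0%.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import schema
from .catalog_io import nutrient_columns

logger = logging.getLogger(__name__)

MACRO_PCT_COLS = {
    "carbohydrate": "macro_pct_carbohydrate",
    "total_fat": "macro_pct_fat",
    "protein": "macro_pct_protein",
}


def food_group_cell_columns() -> list[str]:
    return [f"fg_{cat}_{blk}" for cat, blk in schema.food_group_cells()]


def _tier_block(row: pd.Series) -> str:
    if row["cfg_group"] in schema.CFG_CATEGORIES:
        return "t13" if int(row["cfg_tier"]) <= 3 else "t4"
    return "non_cfg"


def build_intake_profiles(
    recalls: pd.DataFrame,
    catalog: pd.DataFrame,
    participant_ids: pd.Series | list | None = None,
) -> pd.DataFrame:
    """Intake profiles for every participant.

    Returns one row per participant (all of ``participant_ids`` when given,
    else every id present in ``recalls``) with energy, the 22 nutrients,
    percent of energy from the three macronutrients (4/9/4 kcal/g) and the
    food-group gram cells.  Participants without records get all-zero rows.
    """
    cat = catalog.copy()
    cat["_cell"] = "fg_" + cat["cfg_group"] + "_" + cat.apply(_tier_block, axis=1)

    nut_cols = nutrient_columns()
    merged = recalls.merge(
        cat[["food_code", schema.ENERGY_COL, "_cell"] + nut_cols],
        on="food_code",
        how="left",
        validate="many_to_one",
    )
    g = merged["grams"].to_numpy(dtype=float)

    amounts = pd.DataFrame(
        merged[nut_cols].to_numpy(dtype=float) * g[:, None],
        columns=list(schema.NUTRIENT_IDS),
    )
    amounts.insert(0, "energy_kcal", merged[schema.ENERGY_COL].to_numpy(dtype=float) * g)
    amounts["participant_id"] = merged["participant_id"].to_numpy()
    totals = amounts.groupby("participant_id", sort=True).sum()

    fg = (
        merged.assign(grams=g)
        .pivot_table(index="participant_id", columns="_cell", values="grams",
                     aggfunc="sum", fill_value=0.0)
    )
    out = totals.join(fg, how="left")

    if participant_ids is not None:
        out = out.reindex(pd.Index(participant_ids, name="participant_id"))
    for col in food_group_cell_columns():
        if col not in out.columns:
            out[col] = 0.0
    out = out.fillna(0.0)[
        ["energy_kcal"] + list(schema.NUTRIENT_IDS) + food_group_cell_columns()
    ]

    energy = out["energy_kcal"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        for macro, col in MACRO_PCT_COLS.items():
            pct = out[macro].to_numpy() * schema.KCAL_PER_G[macro] / energy * 100.0
            out[col] = np.where(energy > 0, pct, 0.0)
    return out


def build_intake_profile(records: pd.DataFrame, catalog: pd.DataFrame,
                         participant_id: str) -> pd.Series:
    """Single-participant convenience wrapper around build_intake_profiles."""
    sub = records[records["participant_id"] == participant_id]
    return build_intake_profiles(sub, catalog, [participant_id]).iloc[0]


def tier_block_totals(profiles: pd.DataFrame) -> pd.DataFrame:
    """Derived block totals: sum of the ten CFG t13 cells, the ten t4 cells
    and the three non-CFG cells."""
    out = pd.DataFrame(index=profiles.index)
    out["total_t13"] = profiles[[f"fg_{c}_t13" for c in schema.CFG_CATEGORIES]].sum(axis=1)
    out["total_t4"] = profiles[[f"fg_{c}_t4" for c in schema.CFG_CATEGORIES]].sum(axis=1)
    out["total_non_cfg"] = profiles[
        [f"fg_{c}_non_cfg" for c in schema.NON_CFG_CATEGORIES]
    ].sum(axis=1)
    return out


def compute_wg_exposure(
    recalls: pd.DataFrame,
    catalog: pd.DataFrame,
    participant_ids: pd.Series | list | None = None,
) -> pd.DataFrame:
    """Whole-grain exposure per participant.

    ``wg_servings`` is NaN (with a logged note) for participants who ate a
    WG food whose catalog entry lacks grams_per_serving.
    """
    cat = catalog.set_index("food_code")
    merged = recalls.merge(
        cat[["cfg_group", "is_whole_grain", "grams_per_serving"]],
        left_on="food_code",
        right_index=True,
        how="left",
    )
    g = merged["grams"].to_numpy(dtype=float)
    is_wg = merged["is_whole_grain"].to_numpy(dtype=bool)
    is_grain = merged["cfg_group"].isin(["whole_grains", "refined_grains"]).to_numpy()

    by = merged.assign(
        _wg=np.where(is_wg, g, 0.0),
        _grain=np.where(is_grain, g, 0.0),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        servings = np.where(is_wg, g / merged["grams_per_serving"].to_numpy(dtype=float), 0.0)
    by["_serv"] = servings  # NaN propagates when a WG food lacks a serving size

    agg = by.groupby("participant_id", sort=True).agg(
        wg_grams=("_wg", "sum"),
        total_grain_grams=("_grain", "sum"),
        wg_servings=("_serv", lambda s: s.sum(skipna=False)),
    )
    if participant_ids is not None:
        agg = agg.reindex(pd.Index(participant_ids, name="participant_id"))
        agg[["wg_grams", "total_grain_grams"]] = agg[["wg_grams", "total_grain_grams"]].fillna(0.0)
        agg["wg_servings"] = agg["wg_servings"].fillna(0.0)

    n_undefined = int(agg["wg_servings"].isna().sum())
    if n_undefined:
        logger.warning(
            "wg_servings undefined for %d participants (WG food without grams_per_serving)",
            n_undefined,
        )
    total = agg["total_grain_grams"].to_numpy()
    wg = agg["wg_grams"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * wg / total
    # zero-grain diets contribute 0% rather than being excluded
    agg["pct_grain_from_wg"] = np.where(total > 0, pct, 0.0)
    return agg


def group_mean_pct_grain(exposures: pd.DataFrame, weights: np.ndarray | pd.Series) -> float:
    """Survey-weighted mean of the per-participant percent of grain intake
    from whole grains (a mean of ratios, not a ratio of means)."""
    if len(exposures) == 0:
        raise ValueError("group_mean_pct_grain needs a nonempty group")
    w = np.asarray(weights, dtype=float)
    pct = exposures["pct_grain_from_wg"].to_numpy(dtype=float)
    if w.shape[0] != pct.shape[0]:
        raise ValueError("weights and exposures differ in length")
    return float(np.average(pct, weights=w))
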