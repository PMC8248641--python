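"""Shared vocabulary for the whole-grain dietary analysis.

Food categories follow the 2007 Canada Food Guide (CFG) grouping used in the
CCHS 2015 nutrition survey: ten CFG food categories carrying a 4-tier
alignment class (tiers 1-2 aligned, 3 partially aligned, 4 not aligned),
plus three non-CFG buckets (discretionary foods, other foods and recipes,
and foods not classified).  Whole-grain (WG) foods are the "Grain
products - whole" category, any tier 1-4.
"""

from __future__ import annotations

# The ten CFG food categories (carry a tier 1-4).
CFG_CATEGORIES: tuple[str, ...] = (
    "whole_grains",
    "refined_grains",
    "fruit",
    "vegetables",
    "dairy_alternatives",
    "meat_poultry",
    "processed_meats",
    "fish_shellfish",
    "legumes_nuts_seeds",
    "eggs",
)

# Non-CFG buckets (no tier).
NON_CFG_CATEGORIES: tuple[str, ...] = ("discretionary", "other", "unclassified")

ALL_CATEGORIES: tuple[str, ...] = CFG_CATEGORIES + NON_CFG_CATEGORIES

TIERS = (1, 2, 3, 4)

# Tier blocks used for reporting: tiers 1-3 pooled (aligned / partially
# aligned), tier 4 alone, and the non-CFG bucket.
TIER_BLOCKS = ("t13", "t4", "non_cfg")

# The 22 analysis nutrients, in reporting order, with catalog/profile units.
NUTRIENTS: dict[str, str] = {
    "carbohydrate": "g",
    "fiber": "g",
    "total_sugar": "g",
    "total_fat": "g",
    "saturated_fat": "g",
    "protein": "g",
    "vitamin_b12": "ug",
    "vitamin_b6": "ug",
    "vitamin_c": "mg",
    "folate": "ug",
    "folic_acid": "ug",
    "vitamin_d": "ug",
    "niacin": "mg",
    "vitamin_a": "ug_rae",
    "riboflavin": "mg",
    "thiamin": "mg",
    "sodium": "mg",
    "potassium": "mg",
    "zinc": "mg",
    "calcium": "mg",
    "iron": "mg",
    "magnesium": "mg",
}

NUTRIENT_IDS: tuple[str, ...] = tuple(NUTRIENTS)

# Atwater factors (kcal per gram) for percent-of-energy macronutrients.
KCAL_PER_G = {"carbohydrate": 4.0, "total_fat": 9.0, "protein": 4.0}

# NRF 9.3 default nutrient sets (modified index: total diet per 2000 kcal;
# total sugar substitutes for added sugar, which the survey does not report).
NRF_ENCOURAGE: tuple[str, ...] = (
    "fiber",
    "protein",
    "vitamin_d",
    "vitamin_c",
    "iron",
    "calcium",
    "potassium",
    "vitamin_a",
    "magnesium",
)
NRF_LIMIT: tuple[str, ...] = ("total_sugar", "sodium", "saturated_fat")

# Placeholder Health-Canada-style daily values (non-normative; editable via
# dv.csv).  Units match NUTRIENTS.
DEFAULT_DV: dict[str, float] = {
    "fiber": 28.0,
    "protein": 50.0,
    "vitamin_d": 20.0,
    "vitamin_c": 90.0,
    "iron": 18.0,
    "calcium": 1300.0,
    "potassium": 4700.0,
    "vitamin_a": 900.0,
    "magnesium": 420.0,
    "total_sugar": 100.0,
    "sodium": 2300.0,
    "saturated_fat": 20.0,
}

# WG exposure groups, ordinal.
WG_GROUPS: tuple[str, ...] = ("no_wg", "low_wg", "mid_wg", "high_wg")
WG_GROUP_SCORE: dict[str, int] = {g: i for i, g in enumerate(WG_GROUPS)}

ADULT_AGE_MIN = 19  # adult stratum: age >= 19 y; child stratum: 1-18 y
STRATA = ("child", "adult")

# Energy density column in the catalog (kcal per gram of food).
ENERGY_COL = "energy_kcal_per_g"
NUTRIENT_PREFIX = "nut_"
REPLICATE_PREFIX = "bsw_"


def stratum_of(age_years: float) -> str:
    """Age stratum: ``child`` for 1-18 y, ``adult`` for >= 19 y."""
    return "adult" if age_years >= ADULT_AGE_MIN else "child"


def food_group_cells() -> list[tuple[str, str]]:
    """The stored per-participant food-group cells.

    Ten CFG categories x {t13, t4} plus the three non-CFG buckets; the three
    block totals (tier 1-3, tier 4, non-CFG) are derived, not stored.
    """
    cells = [(cat, blk) for cat in CFG_CATEGORIES for blk in ("t13", "t4")]
    cells += [(cat, "non_cfg") for cat in NON_CFG_CATEGORIES]
    return cells
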