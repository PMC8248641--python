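"""Published CCHS 2015 whole-grain reference estimates.

Row-level estimates transcribed from the published population analysis of
the 2015 Canadian Community Health Survey - Nutrition: the top-10 BNS food
sources of whole grain (adjusted least-squares mean grams/day with SE, per
age stratum and WG intake group) and selected adjusted nutrient / food-group
means.  They serve as fixed inputs for derived arithmetic — top-10 coverage
subtotals, between-group percent contrasts — computed by package code; no
aggregate is stored, only the printed per-row values.
"""

from __future__ import annotations

import pandas as pd

CEREAL = "whole grain, oat, and high fibre breakfast cereal"
BREAD = "whole grain and whole wheat bread"


def _table(rows: list[tuple[str, float, float]]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["bns_group", "mean_grams", "se"])


#: Top-10 BNS sources of WG food, children (1-18 y), by WG intake group.
TOP_SOURCES_CHILD: dict[str, pd.DataFrame] = {
    "low_wg": _table([
        ("other breakfast cereal", 6.4, 0.6),
        (CEREAL, 6.4, 0.9),
        (BREAD, 2.6, 0.4),
        ("salty and high-fat snacks (including tortilla chips)", 1.2, 0.1),
        ("sweet snacks, sugar, candies", 0.7, 0.2),
        ("rolls, bagels, pita bread, croutons, dumplings, matzo, tortilla", 0.6, 0.2),
        ("plain popcorn and pretzels", 0.4, 0.1),
        ("cereal grains and flours", 0.3, 0.1),
        ("crackers and crispbreads", 0.2, 0.1),
        ("rice", 0.2, 0.1),
    ]),
    "mid_wg": _table([
        (BREAD, 27.4, 1.8),
        (CEREAL, 10.8, 1.1),
        ("rolls, bagels, pita bread, croutons, dumplings, matzo, tortilla", 3.4, 0.7),
        ("other breakfast cereal", 3.3, 0.8),
        ("rice", 2.4, 1.1),
        ("salty and high-fat snacks (including tortilla chips)", 1.8, 0.4),
        ("pancakes and waffles", 1.4, 0.4),
        ("sweet snacks, sugar, candies", 1.3, 0.4),
        ("cereal grains and flours", 0.6, 0.3),
        ("granola bar", 0.5, 0.4),
    ]),
    "high_wg": _table([
        (CEREAL, 56.4, 5.9),
        (BREAD, 38.7, 2.6),
        ("rice", 18.5, 3.1),
        ("rolls, bagels, pita bread, croutons, dumplings, matzo, tortilla", 16.3, 3.3),
        ("other breakfast cereal", 6.6, 1.5),
        ("salty and high-fat snacks (including tortilla chips)", 6.0, 1.0),
        ("pasta", 5.1, 2.1),
        ("pancakes and waffles", 3.9, 1.5),
        ("cereal grains and flours", 3.3, 0.8),
        ("sweet snacks, sugar, candies", 2.1, 0.6),
    ]),
}

#: Top-10 BNS sources of WG food, adults (>= 19 y), by WG intake group.
TOP_SOURCES_ADULT: dict[str, pd.DataFrame] = {
    "low_wg": _table([
        (CEREAL, 11.0, 0.6),
        (BREAD, 7.9, 0.6),
        ("other breakfast cereal", 2.7, 0.4),
        ("salty and high-fat snacks (including tortilla chips)", 1.3, 0.1),
        ("crackers and crispbreads", 1.1, 0.3),
        ("rolls, bagels, pita bread, croutons, dumplings, matzo, tortilla", 1.0, 0.4),
        ("sweet snacks, sugar, candies", 1.0, 0.2),
        ("granola bars", 0.5, 0.2),
        ("muffins and English muffins", 0.5, 0.4),
        ("cereal grains and flours", 0.4, 0.2),
    ]),
    "mid_wg": _table([
        (BREAD, 40.3, 1.6),
        (CEREAL, 15.1, 1.8),
        ("rolls, bagels, pita bread, croutons, dumplings, matzo, tortilla", 4.9, 1.1),
        ("rice", 2.9, 0.7),
        ("salty and high-fat snacks (including tortilla chips)", 1.9, 0.4),
        ("other breakfast cereal", 1.2, 0.3),
        ("cereal grains and flours", 1.1, 0.4),
        ("pasta", 0.7, 0.3),
        ("other whole grain breads", 0.7, 0.2),
        ("sweet snacks, sugar, candies", 0.7, 0.2),
    ]),
    "high_wg": _table([
        (CEREAL, 89.8, 12.4),
        (BREAD, 45.5, 2.8),
        ("rice", 35.8, 9.2),
        ("rolls, bagels, pita bread, croutons, dumplings, matzo, tortilla", 26.1, 14.5),
        ("cereal grains and flours", 9.3, 2.0),
        ("pasta", 4.3, 1.2),
        ("salty and high-fat snacks (including tortilla chips)", 2.1, 0.5),
        ("plain popcorn and pretzels", 1.5, 0.9),
        ("sweet snacks, sugar, candies", 0.9, 0.4),
        ("muffins", 0.9, 0.4),
    ]),
}

#: Adjusted folic acid intake (ug/d, least-squares means) by WG group.
FOLIC_ACID_LSMEANS: dict[str, dict[str, float]] = {
    "child": {"no_wg": 147.0, "low_wg": 151.0, "mid_wg": 124.0, "high_wg": 116.0},
    "adult": {"no_wg": 123.0, "low_wg": 109.0, "mid_wg": 94.0, "high_wg": 79.0},
}

#: Adjusted discretionary-food intake (g/d, least-squares means), adults.
DISCRETIONARY_LSMEANS_ADULT: dict[str, float] = {
    "no_wg": 315.0, "low_wg": 251.0, "mid_wg": 228.0, "high_wg": 163.0,
}
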