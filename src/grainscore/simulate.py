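"""Synthetic catalogs, recall surveys and bootstrap replicate weights.

The generator emulates the structure of a 24-h recall nutrition survey in
which roughly half of participants eat no whole-grain (WG) food, WG grams
among consumers are heavy-right-tailed, and per-2000-kcal nutrient intakes
carry a controllable linear association with WG grams.

Construction, per participant:

1. WG consumption: Bernoulli(``prob_wg_consumer``) per age stratum; consumers
   draw WG grams from a log-normal (``wg_grams_distribution``), reproducing
   the heavy tail behind the observed tertile means (roughly 19 -> 163 g/d in
   children, 29 -> 220 g/d in adults).
2. Target per-2000-kcal intake of each nutrient:
   ``T_n = baseline_n + nutrient_effect[n] * wg_grams + noise`` so the
   expected energy-standardised intake is linear in WG grams with the
   configured slope (the ground truth that recovery tests check).
3. A food basket is drawn: WG foods split across BNS source groups, refined
   grains declining with WG intake, and one food from each remaining
   category.  Composite "mixed dish" foods (one per nutrient, zero energy)
   and an energy filler then top the basket up to the target intake vector
   and target energy, so the linear structure holds exactly except for the
   rare basket that already exceeds a target (residuals clip at zero).
4. Sampling weights are log-normal with the configured coefficient of
   variation; replicate weights follow a Rao-Wu-style rescaled bootstrap
   over simulated primary sampling units, each replicate rescaled so its
   weight total equals the full-sample total.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import schema
from .catalog_io import nutrient_columns, validate_catalog
from .errors import ValidationError

# Typical daily intake per 2000 kcal used as the intercept of the generating
# model (units as in schema.NUTRIENTS; values in the range national dietary
# surveillance reports).
BASELINE_PER2000: dict[str, float] = {
    "carbohydrate": 240.0,
    "fiber": 14.0,
    "total_sugar": 100.0,
    "total_fat": 66.0,
    "saturated_fat": 23.0,
    "protein": 72.0,
    "vitamin_b12": 3.9,
    "vitamin_b6": 1.5,
    "vitamin_c": 110.0,
    "folate": 445.0,
    "folic_acid": 140.0,
    "vitamin_d": 5.1,
    "niacin": 34.0,
    "vitamin_a": 600.0,
    "riboflavin": 1.8,
    "thiamin": 1.6,
    "sodium": 2600.0,
    "potassium": 2400.0,
    "zinc": 9.2,
    "calcium": 880.0,
    "iron": 11.8,
    "magnesium": 245.0,
}

# Default ground-truth slopes: change in per-2000-kcal intake per gram of WG
# food, matched to the adjusted gradients national data show (fiber,
# minerals up; folic acid down via displacement of fortified refined grain).
DEFAULT_NUTRIENT_EFFECT: dict[str, float] = {
    "fiber": 0.04,
    "magnesium": 0.45,
    "iron": 0.012,
    "potassium": 1.0,
    "calcium": 0.5,
    "folic_acid": -0.19,
}

# BNS source groups for WG foods; the first six always appear so rankings
# have realistic competitors (breakfast cereal and bread dominate).
WG_BNS_GROUPS: tuple[str, ...] = (
    "whole grain, oat, and high fibre breakfast cereal",
    "whole grain and whole wheat bread",
    "rice",
    "rolls, bagels, pita bread, croutons, dumplings, matzo, tortilla",
    "other breakfast cereal",
    "salty and high-fat snacks (including tortilla chips)",
    "cereal grains and flours",
    "pasta",
    "sweet snacks, sugar, candies",
    "pancakes and waffles",
)

DEFAULT_WG_BNS_SHARES: dict[str, float] = {
    WG_BNS_GROUPS[0]: 0.32,
    WG_BNS_GROUPS[1]: 0.28,
    WG_BNS_GROUPS[2]: 0.10,
    WG_BNS_GROUPS[3]: 0.09,
    WG_BNS_GROUPS[4]: 0.06,
    WG_BNS_GROUPS[5]: 0.05,
    WG_BNS_GROUPS[6]: 0.04,
    WG_BNS_GROUPS[7]: 0.03,
    WG_BNS_GROUPS[8]: 0.02,
    WG_BNS_GROUPS[9]: 0.01,
}

# Mean grams when a category is eaten (rough population-scale magnitudes).
CATEGORY_MEAN_GRAMS: dict[str, float] = {
    "fruit": 250.0,
    "vegetables": 180.0,
    "dairy_alternatives": 300.0,
    "meat_poultry": 90.0,
    "processed_meats": 20.0,
    "fish_shellfish": 15.0,
    "legumes_nuts_seeds": 25.0,
    "eggs": 18.0,
    "discretionary": 200.0,
    "other": 120.0,
    "unclassified": 150.0,
}

COMPOSITE_PREFIX = "MIX_"
FILLER_CODE = "MIX_ENERGY"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic survey; defaults are the emulated study
    conditions (about 50%/54% non-consumers, heavy-tailed WG grams,
    child-only energy-WG association)."""

    seed: int = 0
    n_children: int = 500
    n_adults: int = 500
    n_foods_per_category: int = 8
    prob_wg_consumer: dict[str, float] = field(
        default_factory=lambda: {"child": 0.50, "adult": 0.46}
    )
    wg_grams_distribution: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"child": (3.9, 1.0), "adult": (4.2, 1.0)}
    )
    nutrient_effect: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NUTRIENT_EFFECT)
    )
    energy_distribution: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"child": (1800.0, 450.0), "adult": (1900.0, 550.0)}
    )
    # kcal of extra energy per WG gram; positive for children only, mirroring
    # the child-specific unadjusted energy gradient.
    energy_wg_slope: dict[str, float] = field(
        default_factory=lambda: {"child": 1.2, "adult": 0.0}
    )
    n_replicates: int = 100
    weight_cv: float = 0.5
    n_psu: int = 50
    nutrient_noise_cv: float = 0.25
    wg_bns_shares: dict[str, float] | None = None
    include_composites: bool = True

    def __post_init__(self) -> None:
        for s, p in self.prob_wg_consumer.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"prob_wg_consumer[{s}]={p} outside [0, 1]")
        if self.n_replicates < 8:
            raise ValidationError("n_replicates must be >= 8")
        for name in ("n_children", "n_adults", "n_foods_per_category", "n_psu"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.weight_cv < 0 or self.nutrient_noise_cv < 0:
            raise ValidationError("coefficients of variation must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("wg_grams_distribution", "energy_distribution"):
            if key in raw:
                raw[key] = {s: tuple(v) for s, v in raw[key].items()}
        return cls(**raw)


def _catalog_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 0])


def _survey_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 1])


def generate_catalog(config: SimulationConfig) -> pd.DataFrame:
    """Random food catalog: ``n_foods_per_category`` foods in each of the 13
    categories, plus (by default) the composite mixed-dish foods the survey
    generator uses to hit target nutrient vectors.

    WG foods cycle through tiers 1-4 and the BNS source groups so that, at
    the default size, they span all tiers and at least six source groups.
    """
    rng = _catalog_rng(config)
    nut_cols = nutrient_columns()
    baselines = np.array([BASELINE_PER2000[n] for n in schema.NUTRIENT_IDS])
    rows: list[dict] = []

    for cat in schema.ALL_CATEGORIES:
        for i in range(config.n_foods_per_category):
            code = f"{cat[:4].upper()}{i:03d}"
            is_cfg = cat in schema.CFG_CATEGORIES
            tier = schema.TIERS[i % 4] if is_cfg else np.nan
            if cat == "whole_grains":
                bns = WG_BNS_GROUPS[i % len(WG_BNS_GROUPS)]
            else:
                bns = f"{cat.replace('_', ' ')} group {i % 3 + 1}"
            # density scaled so a realistic basket stays below the target
            # intake, leaving headroom for the composite top-up foods
            dens = rng.uniform(0.0, baselines / 2000.0)
            row = {
                "food_code": code,
                "description": f"synthetic {cat.replace('_', ' ')} food {i}",
                "cfg_group": cat,
                "cfg_tier": tier,
                "bns_group": bns,
                "is_whole_grain": cat == "whole_grains",
                "grams_per_serving": float(np.round(rng.uniform(25.0, 60.0), 1)) if is_cfg else np.nan,
                schema.ENERGY_COL: float(np.round(rng.uniform(0.2, 2.0), 3)),
            }
            row.update({c: float(d) for c, d in zip(nut_cols, dens)})
            rows.append(row)

    if config.include_composites:
        for nid in schema.NUTRIENT_IDS:
            row = {
                "food_code": COMPOSITE_PREFIX + nid.upper(),
                "description": f"synthetic mixed-dish composite carrying {nid}",
                "cfg_group": "unclassified",
                "cfg_tier": np.nan,
                "bns_group": "mixed dishes",
                "is_whole_grain": False,
                "grams_per_serving": np.nan,
                schema.ENERGY_COL: 0.0,
            }
            row.update({c: 0.0 for c in nut_cols})
            row[schema.NUTRIENT_PREFIX + nid] = BASELINE_PER2000[nid] / 100.0
            rows.append(row)
        filler = {
            "food_code": FILLER_CODE,
            "description": "synthetic energy filler (fats and oils)",
            "cfg_group": "other",
            "cfg_tier": np.nan,
            "bns_group": "fats and oils",
            "is_whole_grain": False,
            "grams_per_serving": np.nan,
            schema.ENERGY_COL: 9.0,
        }
        filler.update({c: 0.0 for c in nut_cols})
        rows.append(filler)

    return validate_catalog(pd.DataFrame(rows))


def _wg_share_vector(config: SimulationConfig, wg_foods: pd.DataFrame) -> np.ndarray:
    shares = config.wg_bns_shares or DEFAULT_WG_BNS_SHARES
    labels = wg_foods["bns_group"].to_numpy()
    per_label_count = pd.Series(labels).value_counts()
    w = np.array([
        shares.get(lab, 0.005) / per_label_count[lab] for lab in labels
    ])
    total = w.sum()
    if total <= 0:
        raise ValidationError("wg_bns_shares assigns zero mass to every WG food")
    return w / total


def generate_survey(
    config: SimulationConfig, catalog: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate ``(participants, recalls)`` for the configured survey.

    Requires a catalog produced with ``include_composites=True`` (the
    composite foods are what pin per-2000-kcal intakes to the configured
    linear model).
    """
    rng = _survey_rng(config)
    n = config.n_children + config.n_adults
    stratum = np.array(["child"] * config.n_children + ["adult"] * config.n_adults)
    is_adult = stratum == "adult"

    age = np.where(
        is_adult,
        rng.uniform(19.0, 90.0, n),
        rng.uniform(1.0, 18.9, n),  # stays < 19 after rounding to 0.1 y
    ).round(1)
    gender = np.where(rng.random(n) < 0.5, "female", "male")
    household_size = 1 + rng.poisson(1.5, n)
    income = np.round(rng.lognormal(11.0, 0.7, n), 0)
    bmi = np.where(is_adult, np.clip(rng.normal(27.0, 5.0, n), 15.0, 55.0).round(1), np.nan)
    bmi_z = np.where(~is_adult, rng.uniform(0.0, 100.0, n).round(1), np.nan)
    supplement = rng.random(n) < 0.4

    # WG exposure
    wg = np.zeros(n)
    for s in schema.STRATA:
        mask = stratum == s
        consumer = rng.random(mask.sum()) < config.prob_wg_consumer[s]
        meanlog, sdlog = config.wg_grams_distribution[s]
        grams = rng.lognormal(meanlog, sdlog, mask.sum())
        wg[mask] = np.where(consumer, grams, 0.0)

    # target energy
    energy_target = np.empty(n)
    for s in schema.STRATA:
        mask = stratum == s
        mu, sd = config.energy_distribution[s]
        energy_target[mask] = rng.normal(mu, sd, mask.sum()) + config.energy_wg_slope[s] * wg[mask]
    energy_target = np.clip(energy_target, 500.0, None)

    # target per-2000-kcal nutrient intakes: baseline + slope * wg + noise
    baselines = np.array([BASELINE_PER2000[nid] for nid in schema.NUTRIENT_IDS])
    slopes = np.array([config.nutrient_effect.get(nid, 0.0) for nid in schema.NUTRIENT_IDS])
    noise = rng.normal(0.0, config.nutrient_noise_cv * baselines, (n, len(baselines)))
    target_per2000 = np.clip(baselines + np.outer(wg, slopes) + noise, 0.0, None)

    # ----- basket construction: grams matrix participants x foods
    foods = catalog.reset_index(drop=True)
    n_foods = len(foods)
    grams_mx = np.zeros((n, n_foods))

    wg_idx = np.flatnonzero(foods["is_whole_grain"].to_numpy())
    if wg_idx.size == 0:
        raise ValidationError("catalog has no whole-grain foods")
    share = _wg_share_vector(config, foods.iloc[wg_idx])
    jitter = rng.dirichlet(share * 40.0 + 1e-3, size=n)
    grams_mx[:, wg_idx] = jitter * wg[:, None]

    refined_idx = np.flatnonzero((foods["cfg_group"] == "refined_grains").to_numpy())
    refined_total = rng.gamma(2.0, 90.0, n) * np.exp(-0.0015 * wg)
    pick = rng.integers(0, refined_idx.size, n)
    grams_mx[np.arange(n), refined_idx[pick]] += np.round(refined_total, 2)

    basket_cats = [
        c for c in schema.ALL_CATEGORIES
        if c not in ("whole_grains", "refined_grains", "other", "unclassified")
    ]
    for cat in basket_cats:
        idx = np.flatnonzero((foods["cfg_group"] == cat).to_numpy())
        eaten = rng.random(n) < 0.7
        amount = np.round(rng.gamma(2.0, CATEGORY_MEAN_GRAMS[cat] / 2.0, n), 2) * eaten
        pick = rng.integers(0, idx.size, n)
        grams_mx[np.arange(n), idx[pick]] += amount

    # ----- composite top-up to the target nutrient vector and energy
    nut_cols = nutrient_columns()
    density = foods[nut_cols].to_numpy(dtype=float)
    energy_density = foods[schema.ENERGY_COL].to_numpy(dtype=float)

    composite_idx = {
        nid: int(np.flatnonzero((foods["food_code"] == COMPOSITE_PREFIX + nid.upper()).to_numpy())[0])
        for nid in schema.NUTRIENT_IDS
        if (foods["food_code"] == COMPOSITE_PREFIX + nid.upper()).any()
    }
    filler_pos = np.flatnonzero((foods["food_code"] == FILLER_CODE).to_numpy())
    if len(composite_idx) != len(schema.NUTRIENT_IDS) or filler_pos.size == 0:
        raise ValidationError(
            "generate_survey needs a catalog with composite foods "
            "(generate_catalog(..., include_composites=True))"
        )

    basket_energy = grams_mx @ energy_density
    filler_grams = np.clip(energy_target - basket_energy, 0.0, None) / 9.0
    grams_mx[:, filler_pos[0]] = np.round(filler_grams, 2)
    energy_real = grams_mx @ energy_density

    target_amount = target_per2000 * energy_real[:, None] / 2000.0
    basket_amount = grams_mx @ density
    for j, nid in enumerate(schema.NUTRIENT_IDS):
        col = composite_idx[nid]
        dens = density[col, j]
        residual = np.clip(target_amount[:, j] - basket_amount[:, j], 0.0, None)
        grams_mx[:, col] = residual / dens

    # ----- weights
    sigma = float(np.sqrt(np.log1p(config.weight_cv ** 2)))
    weight = rng.lognormal(np.log(1000.0) - sigma ** 2 / 2.0, sigma, n)
    psu = rng.integers(0, config.n_psu, n)
    rep = _rao_wu_replicates(rng, weight, psu, config.n_psu, config.n_replicates)

    pid = np.array([f"P{i:06d}" for i in range(n)])
    participants = pd.DataFrame(
        {
            "participant_id": pid,
            "age_years": age,
            "gender": gender,
            "household_size": household_size,
            "household_income": income,
            "bmi": bmi,
            "bmi_z_pctile": bmi_z,
            "supplement_use": supplement,
            "weight": weight,
        }
    )
    rep_frame = pd.DataFrame(
        rep,
        columns=[f"{schema.REPLICATE_PREFIX}{b + 1}" for b in range(config.n_replicates)],
    )
    participants = pd.concat([participants, rep_frame], axis=1)

    ri, ci = np.nonzero(grams_mx > 0)
    recalls = pd.DataFrame(
        {
            "participant_id": pid[ri],
            "food_code": foods["food_code"].to_numpy()[ci],
            "grams": grams_mx[ri, ci],
        }
    )
    return participants, recalls


def _rao_wu_replicates(
    rng: np.random.Generator,
    weight: np.ndarray,
    psu: np.ndarray,
    n_psu: int,
    n_replicates: int,
) -> np.ndarray:
    """Rao-Wu-style rescaled bootstrap: resample K-1 of the K primary
    sampling units with replacement per replicate, scale member weights by
    K/(K-1) times the selection count, then calibrate each replicate so its
    total equals the full-sample weight total."""
    total = weight.sum()
    k = n_psu
    rep = np.empty((weight.size, n_replicates))
    for b in range(n_replicates):
        draws = rng.integers(0, k, k - 1)
        counts = np.bincount(draws, minlength=k)
        mult = counts[psu] * (k / (k - 1))
        w_b = weight * mult
        tot_b = w_b.sum()
        if tot_b <= 0:  # pathological replicate; keep calibration exact
            w_b = weight.copy()
            tot_b = total
        rep[:, b] = w_b * (total / tot_b)
    return rep
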