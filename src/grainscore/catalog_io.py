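"""Reading, writing and validating the four analysis tables.

All tables are comma-separated UTF-8 with a header row:

* ``catalog.csv`` — one row per food code: CFG category/tier, BNS food-source
  group, whole-grain flag, grams per serving, energy density (kcal/g) and
  nutrient densities in ``nut_<id>`` columns (amount per gram, units fixed by
  the DV table).
* ``recalls.csv`` — one row per food eaten by a participant on the 24-h
  recall: ``participant_id, food_code, grams``.
* ``participants.csv`` — demographics, covariate inputs, the main sampling
  weight and bootstrap replicate weights in ``bsw_1..bsw_B``.
* ``dv.csv`` — daily-value configuration: ``nutrient_id, role, dv, unit``
  with role in {encourage, limit}.

Units are declared once in the DV table and assumed consistent in the
catalog; no unit conversion is performed.  A nutrient column absent from the
catalog is treated as density 0 with a logged warning, matching
food-composition-database practice for unassayed nutrients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema
from .errors import ConfigurationError, IntegrityError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

CATALOG_BASE_COLUMNS = [
    "food_code",
    "description",
    "cfg_group",
    "cfg_tier",
    "bns_group",
    "is_whole_grain",
    "grams_per_serving",
    schema.ENERGY_COL,
]

RECALL_COLUMNS = ["participant_id", "food_code", "grams"]

PARTICIPANT_BASE_COLUMNS = [
    "participant_id",
    "age_years",
    "gender",
    "household_size",
    "household_income",
    "bmi",
    "bmi_z_pctile",
    "supplement_use",
    "weight",
]


def nutrient_columns() -> list[str]:
    return [schema.NUTRIENT_PREFIX + n for n in schema.NUTRIENT_IDS]


@dataclass
class DVTable:
    """Daily-value configuration for the NRF 9.3 score.

    ``encourage`` holds the 9 nutrients whose capped %DV is summed;
    ``limit`` the 3 whose uncapped %DV is subtracted.  ``energy_basis_kcal``
    is the energy standardisation basis and ``cap_percent`` the per-nutrient
    cap on encourage contributions.
    """

    encourage: dict[str, float]
    limit: dict[str, float]
    units: dict[str, str] = field(default_factory=dict)
    energy_basis_kcal: float = 2000.0
    cap_percent: float = 100.0

    def __post_init__(self) -> None:
        if len(self.encourage) != 9:
            raise ValidationError(
                f"DV table must list exactly 9 encourage nutrients, got {len(self.encourage)}"
            )
        if len(self.limit) != 3:
            raise ValidationError(
                f"DV table must list exactly 3 limit nutrients, got {len(self.limit)}"
            )
        overlap = set(self.encourage) & set(self.limit)
        if overlap:
            raise ValidationError(f"nutrients in both encourage and limit sets: {sorted(overlap)}")
        for nid, dv in {**self.encourage, **self.limit}.items():
            if not np.isfinite(dv) or dv <= 0:
                raise ValidationError(f"daily value for {nid!r} must be positive, got {dv}")
        if self.energy_basis_kcal <= 0 or self.cap_percent <= 0:
            raise ValidationError("energy basis and cap must be positive")

    @property
    def nutrients(self) -> list[str]:
        return list(self.encourage) + list(self.limit)


def default_dv_table(energy_basis_kcal: float = 2000.0, cap_percent: float = 100.0) -> DVTable:
    """DV table with the default 9+3 nutrient sets and placeholder daily
    values (Health-Canada-style, non-normative)."""
    return DVTable(
        encourage={n: schema.DEFAULT_DV[n] for n in schema.NRF_ENCOURAGE},
        limit={n: schema.DEFAULT_DV[n] for n in schema.NRF_LIMIT},
        units={n: schema.NUTRIENTS[n] for n in schema.NRF_ENCOURAGE + schema.NRF_LIMIT},
        energy_basis_kcal=energy_basis_kcal,
        cap_percent=cap_percent,
    )


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns: {missing}")


def _parse_bool(series: pd.Series, what: str) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False,
    }
    out = []
    for v in series:
        if isinstance(v, (bool, np.bool_)):
            out.append(bool(v))
            continue
        if isinstance(v, (int, np.integer, float, np.floating)) and v in (0, 1):
            out.append(bool(v))
            continue
        key = str(v).strip().lower()
        if key not in mapping:
            raise ValidationError(f"{what}: cannot parse boolean value {v!r}")
        out.append(mapping[key])
    return pd.Series(out, index=series.index)


# ---------------------------------------------------------------------------
# catalog


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Validate a food catalog in place and return it.

    Checks the category/tier/whole-grain invariants row by row so error
    messages can name the offending food code.
    """
    _require_columns(catalog, CATALOG_BASE_COLUMNS, "catalog")
    if catalog["food_code"].duplicated().any():
        dups = sorted(catalog.loc[catalog["food_code"].duplicated(), "food_code"].unique())
        raise IntegrityError(f"duplicate food codes in catalog: {dups}")

    catalog = catalog.copy()
    catalog["is_whole_grain"] = _parse_bool(catalog["is_whole_grain"], "catalog.is_whole_grain")

    missing_nut = [c for c in nutrient_columns() if c not in catalog.columns]
    if missing_nut:
        logger.warning(
            "catalog lacks %d nutrient columns (%s...); treating their densities as 0",
            len(missing_nut), missing_nut[0],
        )
        for c in missing_nut:
            catalog[c] = 0.0
    num_cols = nutrient_columns() + [schema.ENERGY_COL]
    catalog[num_cols] = catalog[num_cols].fillna(0.0)

    for _, row in catalog.iterrows():
        code = row["food_code"]
        group = row["cfg_group"]
        if group not in schema.ALL_CATEGORIES:
            raise ValidationError(f"food {code!r}: unknown cfg_group {group!r}")
        tier = row["cfg_tier"]
        has_tier = pd.notna(tier)
        if group in schema.CFG_CATEGORIES:
            if not has_tier:
                raise ValidationError(f"food {code!r}: CFG category {group!r} requires a tier")
            if int(tier) not in schema.TIERS:
                raise ValidationError(f"food {code!r}: cfg_tier {tier} outside 1-4")
        elif has_tier:
            raise ValidationError(f"food {code!r}: non-CFG category {group!r} must not carry a tier")
        wg_flag = bool(row["is_whole_grain"])
        if wg_flag != (group == "whole_grains"):
            raise IntegrityError(
                f"food {code!r}: is_whole_grain={wg_flag} inconsistent with cfg_group={group!r}"
            )
        gps = row["grams_per_serving"]
        if pd.notna(gps) and gps <= 0:
            raise ValidationError(f"food {code!r}: grams_per_serving must be > 0, got {gps}")
        for c in num_cols:
            if row[c] < 0:
                raise ValidationError(f"food {code!r}: negative density in {c}")
    return catalog


def read_catalog(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"food_code": str})
    return validate_catalog(df)


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    catalog.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# recalls


def validate_recalls(recalls: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    _require_columns(recalls, RECALL_COLUMNS, "recalls")
    grams = recalls["grams"].to_numpy(dtype=float)
    if not np.all(np.isfinite(grams)):
        raise ValidationError("recalls contain non-finite gram amounts")
    if (grams < 0).any():
        raise ValidationError("recalls contain negative gram amounts")
    known = set(catalog["food_code"])
    unknown = sorted(set(recalls["food_code"]) - known)
    if unknown:
        raise IntegrityError(f"recall food codes not in catalog: {unknown}")
    return recalls


def read_recalls(path: str | Path, catalog: pd.DataFrame) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "food_code": str})
    return validate_recalls(df, catalog)


def write_recalls(recalls: pd.DataFrame, path: str | Path) -> None:
    recalls.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# participants


def replicate_columns(participants: pd.DataFrame) -> list[str]:
    cols = [c for c in participants.columns if c.startswith(schema.REPLICATE_PREFIX)]
    return sorted(cols, key=lambda c: int(c[len(schema.REPLICATE_PREFIX):]))


def validate_participants(participants: pd.DataFrame) -> pd.DataFrame:
    _require_columns(participants, PARTICIPANT_BASE_COLUMNS, "participants")
    if participants["participant_id"].duplicated().any():
        raise IntegrityError("duplicate participant ids")
    p = participants.copy()
    p["supplement_use"] = _parse_bool(p["supplement_use"], "participants.supplement_use")
    if (p["age_years"] < 1).any():
        raise ValidationError("age_years must be >= 1")
    bad_gender = set(p["gender"]) - {"female", "male"}
    if bad_gender:
        raise ValidationError(f"unknown gender values: {sorted(bad_gender)}")
    if (p["household_size"] < 1).any():
        raise ValidationError("household_size must be >= 1")
    if (p["household_income"] < 0).any():
        raise ValidationError("household_income must be >= 0")
    if (p["weight"] <= 0).any():
        raise ValidationError("sampling weights must be > 0")
    adult = p["age_years"] >= schema.ADULT_AGE_MIN
    if p.loc[adult, "bmi"].isna().any():
        raise ValidationError("adults (age >= 19) must carry bmi")
    if p.loc[~adult, "bmi_z_pctile"].isna().any():
        raise ValidationError("children (age 1-18) must carry bmi_z_pctile")
    if p.loc[adult, "bmi_z_pctile"].notna().any() or p.loc[~adult, "bmi"].notna().any():
        raise ValidationError("bmi and bmi_z_pctile are mutually exclusive by age stratum")
    rep = replicate_columns(p)
    if rep:
        w = p[rep].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)) or (w < 0).any():
            raise ValidationError("replicate weights must be finite and >= 0")
    return p


def read_participants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    return validate_participants(df)


def write_participants(participants: pd.DataFrame, path: str | Path) -> None:
    participants.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# DV table


def read_dv(path: str | Path, energy_basis_kcal: float = 2000.0,
            cap_percent: float = 100.0) -> DVTable:
    df = pd.read_csv(path)
    _require_columns(df, ["nutrient_id", "role", "dv", "unit"], "dv table")
    bad_roles = set(df["role"]) - {"encourage", "limit"}
    if bad_roles:
        raise ConfigurationError(f"unknown DV roles: {sorted(bad_roles)}")
    enc = df[df["role"] == "encourage"]
    lim = df[df["role"] == "limit"]
    return DVTable(
        encourage=dict(zip(enc["nutrient_id"], enc["dv"].astype(float))),
        limit=dict(zip(lim["nutrient_id"], lim["dv"].astype(float))),
        units=dict(zip(df["nutrient_id"], df["unit"])),
        energy_basis_kcal=energy_basis_kcal,
        cap_percent=cap_percent,
    )


def write_dv(dv: DVTable, path: str | Path) -> None:
    rows = [
        {"nutrient_id": n, "role": role, "dv": val, "unit": dv.units.get(n, "")}
        for role, table in (("encourage", dv.encourage), ("limit", dv.limit))
        for n, val in table.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
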