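"""End-to-end orchestration: inputs -> classification -> stratification ->
scoring -> survey estimation -> top sources -> report bundle.

The report bundle mirrors the standard reporting layout of a whole-grain
surveillance analysis, per age stratum:

* ``exposure``      — per-WG-group weighted means of WG grams, servings and
                      percent of grain from WG (mean of ratios), group sizes,
                      chi-square p-values for categorical demographics;
* ``nutrients``     — 22 adjusted nutrient least-squares means + SE per
                      group, linear-trend p and a Bonferroni flag (alpha/22);
* ``food_groups``   — adjusted food-group gram means for the tier cells and
                      block totals, Bonferroni flag (alpha/24);
* ``nrf``           — adjusted NRF 9.3 group means, trend p, pairwise
                      Tukey-Kramer contrasts and boxplot-ready weighted
                      quantiles (5/25/50/75/95, median and mean);
* ``top_sources``   — ranked BNS sources of WG per consumer group.

Every stage logs one line with row counts; any stage error is re-raised
with the stage name attached.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, schema
from .catalog_io import (DVTable, default_dv_table, read_catalog, read_dv,
                         read_participants, read_recalls, replicate_columns,
                         write_catalog, write_dv, write_participants, write_recalls)
from .classify import (build_intake_profiles, compute_wg_exposure,
                       food_group_cell_columns, group_mean_pct_grain, tier_block_totals)
from .errors import GrainscoreError, ValidationError
from .nrf import nrf93_profiles
from .simulate import SimulationConfig, generate_catalog, generate_survey
from .sources import rank_wg_sources
from .stratify import assign_wg_groups
from .survey import (bonferroni_threshold, build_covariates, linear_trend_test,
                     tukey_kramer, weighted_chi2, weighted_lsmeans, weighted_quantile)

logger = logging.getLogger(__name__)

FOOD_GROUP_LABELS = {f"fg_{c}_{b}": f"{c} {b}" for c, b in schema.food_group_cells()}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``input_dir`` (directory holding catalog.csv,
    recalls.csv, participants.csv and optionally dv.csv) or ``simulation``
    must be supplied.
    """

    input_dir: str | Path | None = None
    simulation: SimulationConfig | None = None
    seed: int | None = None
    alpha: float = 0.05
    m_nut: int = 22
    m_fg: int = 24
    energy_basis_kcal: float = 2000.0
    cap_percent: float = 100.0
    n_energy_levels: int = 5
    exclude_extreme_energy: bool = False
    adjusted_sources: bool = True

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulation is None):
            raise ValidationError("supply exactly one of input_dir or simulation")
        if self.m_nut < 1 or self.m_fg < 1:
            raise ValidationError("outcome counts must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")


@dataclass
class ReportBundle:
    exposure: dict[str, pd.DataFrame]
    demographics: dict[str, pd.DataFrame]
    nutrients: dict[str, pd.DataFrame]
    food_groups: dict[str, pd.DataFrame]
    nrf_summary: dict[str, pd.DataFrame]
    nrf_pairwise: dict[str, pd.DataFrame]
    top_sources: dict[tuple[str, str], object]
    run_log: dict = field(default_factory=dict)


def load_inputs(config: RunConfig):
    """Load or simulate the four input tables."""
    if config.simulation is not None:
        sim = config.simulation
        if config.seed is not None and config.seed != sim.seed:
            sim = SimulationConfig(**{**sim.__dict__, "seed": config.seed})
        catalog = generate_catalog(sim)
        participants, recalls = generate_survey(sim, catalog)
        dv = default_dv_table(config.energy_basis_kcal, config.cap_percent)
        return catalog, recalls, participants, dv
    d = Path(config.input_dir)
    catalog = read_catalog(d / "catalog.csv")
    recalls = read_recalls(d / "recalls.csv", catalog)
    participants = read_participants(d / "participants.csv")
    dv_path = d / "dv.csv"
    dv = (read_dv(dv_path, config.energy_basis_kcal, config.cap_percent)
          if dv_path.exists() else default_dv_table(config.energy_basis_kcal, config.cap_percent))
    return catalog, recalls, participants, dv


def write_inputs(catalog, recalls, participants, dv: DVTable, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_catalog(catalog, out / "catalog.csv")
    write_recalls(recalls, out / "recalls.csv")
    write_participants(participants, out / "participants.csv")
    write_dv(dv, out / "dv.csv")


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except GrainscoreError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
        return wrapped
    return deco


def _weighted_group_stats(values: pd.Series, groups: pd.Series, weights: pd.Series,
                          rep: np.ndarray | None) -> pd.DataFrame:
    rows = []
    for g in groups.cat.categories:
        m = (groups == g).to_numpy()
        if not m.any():
            continue
        y, w = values.to_numpy(dtype=float)[m], weights.to_numpy(dtype=float)[m]
        mean = float(np.average(y, weights=w))
        if rep is not None:
            reps = (rep[m] * y[:, None]).sum(axis=0) / rep[m].sum(axis=0)
            se = float(np.sqrt(np.mean((reps - mean) ** 2)))
        else:
            nw = w / w.sum()
            se = float(np.sqrt(np.sum(nw ** 2 * (y - mean) ** 2)))
        rows.append({"group": str(g), "mean": mean, "se": se, "n": int(m.sum())})
    return pd.DataFrame(rows)


def _adjusted_outcome_table(outcomes: pd.DataFrame, labels: dict[str, str],
                            groups: pd.Series, scores: np.ndarray,
                            covariates: pd.DataFrame, weights: np.ndarray,
                            rep: np.ndarray | None, threshold: float) -> pd.DataFrame:
    rows = []
    for col, label in labels.items():
        y = outcomes[col].to_numpy(dtype=float)
        fit = weighted_lsmeans(y, groups, covariates, weights, rep)
        trend = linear_trend_test(y, scores, covariates, weights, rep)
        row = {"outcome": label}
        for g in schema.WG_GROUPS:
            row[f"lsmean_{g}"] = fit.estimate.get(g, np.nan)
            row[f"se_{g}"] = fit.se.get(g, np.nan)
        row["trend_p"] = trend.p
        row["significant"] = trend.p <= threshold
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> ReportBundle:
    """Run the full analysis; optionally write the report CSVs + run log."""
    catalog, recalls, participants, dv = _stage("load")(load_inputs)(config)
    logger.info("inputs: %d foods, %d recall rows, %d participants",
                len(catalog), len(recalls), len(participants))

    ids = participants["participant_id"]
    profiles = _stage("classify")(build_intake_profiles)(recalls, catalog, ids)
    exposures = _stage("classify")(compute_wg_exposure)(recalls, catalog, ids)
    ages = participants.set_index("participant_id")["age_years"]
    assignments = _stage("stratify")(assign_wg_groups)(exposures, ages)
    scores_df = _stage("score")(nrf93_profiles)(profiles, dv)

    part = participants.set_index("participant_id")
    if config.exclude_extreme_energy:
        keep = (profiles["energy_kcal"] >= 200) & (profiles["energy_kcal"] <= 8000)
        logger.info("excluding %d extreme-energy participants", int((~keep).sum()))
        part = part.loc[keep.to_numpy()]

    rep_cols = replicate_columns(participants)
    warnings: list[str] = []
    bundle = ReportBundle({}, {}, {}, {}, {}, {}, {}, {})

    for stratum in schema.STRATA:
        s_ids = assignments.index[(assignments["stratum"] == stratum)
                                  & assignments.index.isin(part.index)]
        if len(s_ids) == 0:
            warnings.append(f"no participants in stratum {stratum}")
            continue
        p_s = part.loc[s_ids]
        prof_s = profiles.loc[s_ids]
        cov = build_covariates(p_s, prof_s["energy_kcal"], config.n_energy_levels)
        model_ids = cov.index
        grp = assignments.loc[model_ids, "group"]
        sc = assignments.loc[model_ids, "group_score"].to_numpy(dtype=float)
        w = p_s.loc[model_ids, "weight"]
        rep = p_s.loc[model_ids, rep_cols].to_numpy(dtype=float) if rep_cols else None
        logger.info("stratum %s: %d participants modelled", stratum, len(model_ids))

        # exposure table (unadjusted, Table-1 analogue)
        expo_rows = []
        exp_s = exposures.loc[model_ids]
        for g in schema.WG_GROUPS:
            m = (grp == g).to_numpy()
            if not m.any():
                continue
            sub, sw = exp_s.loc[m], w.to_numpy(dtype=float)[m]
            expo_rows.append({
                "group": g,
                "n": int(m.sum()),
                "wg_grams": float(np.average(sub["wg_grams"], weights=sw)),
                "wg_servings": float(np.average(sub["wg_servings"].fillna(0.0), weights=sw)),
                "pct_grain_from_wg": group_mean_pct_grain(sub, sw),
                "energy_kcal": float(np.average(prof_s.loc[model_ids, "energy_kcal"][m], weights=sw)),
            })
        bundle.exposure[stratum] = pd.DataFrame(expo_rows)

        demo_rows = []
        for var in ("gender", "supplement_use", "overweight_obese", "low_income"):
            vals = cov[var]
            res = weighted_chi2(vals, grp, w.to_numpy(dtype=float), rep)
            demo_rows.append({"variable": var, "chi2": res.statistic, "df": res.df,
                              "p": res.p, "design_effect": res.design_effect})
        bundle.demographics[stratum] = pd.DataFrame(demo_rows)

        thr_nut = bonferroni_threshold(config.alpha, config.m_nut)
        nut_labels = {n: n for n in schema.NUTRIENT_IDS}
        bundle.nutrients[stratum] = _stage("estimate")(_adjusted_outcome_table)(
            prof_s.loc[model_ids], nut_labels, grp, sc, cov,
            w.to_numpy(dtype=float), rep, thr_nut)

        thr_fg = bonferroni_threshold(config.alpha, config.m_fg)
        fg = prof_s.loc[model_ids, food_group_cell_columns()].join(
            tier_block_totals(prof_s.loc[model_ids]))
        fg_labels = dict(FOOD_GROUP_LABELS)
        fg_labels.update({"total_t13": "total tier 1-3", "total_t4": "total tier 4",
                          "total_non_cfg": "total non-CFG"})
        bundle.food_groups[stratum] = _stage("estimate")(_adjusted_outcome_table)(
            fg, fg_labels, grp, sc, cov, w.to_numpy(dtype=float), rep, thr_fg)

        # diet quality: adjusted means, trend, pairwise contrasts, quantiles
        nrf_s = scores_df.loc[model_ids, "score"]
        valid = nrf_s.notna()
        if (~valid).any():
            warnings.append(f"{int((~valid).sum())} zero-energy participants "
                            f"excluded from NRF in stratum {stratum}")
        y = nrf_s[valid].to_numpy(dtype=float)
        g_v = grp[valid.to_numpy()]
        cov_v = cov.loc[valid.to_numpy()]
        w_v = w[valid.to_numpy()].to_numpy(dtype=float)
        rep_v = rep[valid.to_numpy()] if rep is not None else None
        fit = weighted_lsmeans(y, g_v, cov_v, w_v, rep_v)
        trend = linear_trend_test(y, sc[valid.to_numpy()], cov_v, w_v, rep_v)
        qrows = []
        for g in schema.WG_GROUPS:
            m = (g_v == g).to_numpy()
            if not m.any():
                continue
            quant = weighted_quantile(y[m], w_v[m], [0.05, 0.25, 0.5, 0.75, 0.95])
            qrows.append({
                "group": g, "lsmean": fit.estimate[g], "se": fit.se[g],
                "mean": float(np.average(y[m], weights=w_v[m])),
                "p5": quant[0], "p25": quant[1], "median": quant[2],
                "p75": quant[3], "p95": quant[4], "n": int(m.sum()),
                "trend_p": trend.p,
            })
        bundle.nrf_summary[stratum] = pd.DataFrame(qrows)
        bundle.nrf_pairwise[stratum] = tukey_kramer(fit)

    cov_by_stratum = {}
    for stratum in schema.STRATA:
        s_ids = assignments.index[(assignments["stratum"] == stratum)
                                  & assignments.index.isin(part.index)]
        if len(s_ids):
            cov_by_stratum[stratum] = build_covariates(
                part.loc[s_ids], profiles.loc[s_ids, "energy_kcal"], config.n_energy_levels)
    model_index = pd.Index(np.concatenate([c.index for c in cov_by_stratum.values()]))
    assign_model = assignments.loc[assignments.index.isin(model_index)]
    rep_frame = part[rep_cols] if rep_cols else None
    bundle.top_sources = _stage("topsources")(rank_wg_sources)(
        recalls, catalog, assign_model, cov_by_stratum, part["weight"],
        rep_frame, adjusted=config.adjusted_sources)

    bundle.run_log = {
        "version": __version__,
        "seed": (config.simulation.seed if config.simulation is not None else config.seed),
        "n_participants": int(len(participants)),
        "n_recall_rows": int(len(recalls)),
        "n_foods": int(len(catalog)),
        "alpha": config.alpha,
        "nutrient_threshold": bonferroni_threshold(config.alpha, config.m_nut),
        "food_group_threshold": bonferroni_threshold(config.alpha, config.m_fg),
        "warnings": warnings,
    }

    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def _write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("exposure", "demographics", "nutrients", "food_groups",
                 "nrf_summary", "nrf_pairwise"):
        for stratum, frame in getattr(bundle, name).items():
            frame.to_csv(out / f"{name}_{stratum}.csv", index=False)
    for (stratum, group), table in bundle.top_sources.items():
        frame = table.rows.copy()
        frame.insert(0, "rank", np.arange(1, len(frame) + 1))
        summary = pd.DataFrame([{"rank": "total", "bns_group": "top-10 total",
                                 "mean_grams": table.top10_total_grams,
                                 "se": np.nan}])
        pd.concat([frame, summary], ignore_index=True).to_csv(
            out / f"topsources_{stratum}_{group}.csv", index=False)
    with open(out / "run_log.json", "w") as fh:
        json.dump(bundle.run_log, fh, indent=2)
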