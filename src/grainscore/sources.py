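"""Top food sources of whole grain by BNS food group.

For each (age stratum, WG intake group) the per-participant grams of WG
foods are summed within each BNS source group (0 for non-eaters of that
group), the group-level means are estimated — covariate-adjusted
least-squares means by default, raw weighted means behind a flag — and the
sources are ranked.  The table reports the top-10 subtotal and its share of
total WG-food intake.  Because least-squares means are linear in the
outcome, the sum of all per-source adjusted means equals the adjusted mean
of total WG grams exactly, so the share is a true coverage percentage.

Ties on equal means break lexicographically on the BNS label, so output is
deterministic and invariant to catalog row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey import weighted_lsmeans

logger = logging.getLogger(__name__)


@dataclass
class TopSourcesTable:
    stratum: str
    wg_group: str
    rows: pd.DataFrame  # bns_group, mean_grams, se — sorted descending
    top10_total_grams: float
    total_wg_grams: float
    pct_of_total_wg: float


def participant_bns_wg_grams(recalls: pd.DataFrame, catalog: pd.DataFrame,
                             participant_ids) -> pd.DataFrame:
    """Per-participant daily grams of WG food by BNS source group
    (participants x BNS groups, zero-filled)."""
    wg_codes = catalog.loc[catalog["is_whole_grain"], ["food_code", "bns_group"]]
    sub = recalls.merge(wg_codes, on="food_code", how="inner")
    pivot = sub.pivot_table(index="participant_id", columns="bns_group",
                            values="grams", aggfunc="sum", fill_value=0.0)
    pivot = pivot.reindex(pd.Index(participant_ids, name="participant_id")).fillna(0.0)
    return pivot


def rank_wg_sources(
    recalls: pd.DataFrame,
    catalog: pd.DataFrame,
    assignments: pd.DataFrame,
    covariates_by_stratum: dict[str, pd.DataFrame] | None,
    weights: pd.Series,
    replicate_weights: pd.DataFrame | None = None,
    adjusted: bool = True,
    top_n: int = 10,
) -> dict[tuple[str, str], TopSourcesTable]:
    """Rank BNS sources of WG food for every (stratum, consumer WG group).

    ``assignments`` is the frame from
    :func:`grainscore.stratify.assign_wg_groups`; ``covariates_by_stratum``
    maps stratum name to the covariate frame used for adjustment (ignored
    when ``adjusted`` is False).  The no-WG group is omitted: its WG intake
    is identically zero.
    """
    bns = participant_bns_wg_grams(recalls, catalog, assignments.index)
    out: dict[tuple[str, str], TopSourcesTable] = {}

    for stratum in assignments["stratum"].unique():
        mask = (assignments["stratum"] == stratum).to_numpy()
        ids = assignments.index[mask]
        grp = assignments.loc[ids, "group"]
        w = weights.reindex(ids).to_numpy(dtype=float)
        rep = (replicate_weights.reindex(ids).to_numpy(dtype=float)
               if replicate_weights is not None else None)
        cov = None
        if adjusted and covariates_by_stratum is not None:
            cov = covariates_by_stratum[stratum].reindex(ids)

        per_source: dict[str, object] = {}
        for label in bns.columns:
            y = bns.loc[ids, label].to_numpy(dtype=float)
            if adjusted:
                per_source[label] = weighted_lsmeans(y, grp, cov, w, rep)
            else:
                per_source[label] = _raw_group_means(y, grp, w, rep)
        total_y = bns.loc[ids].sum(axis=1).to_numpy(dtype=float)
        total_fit = (weighted_lsmeans(total_y, grp, cov, w, rep) if adjusted
                     else _raw_group_means(total_y, grp, w, rep))

        for g in total_fit.groups:
            if g == "no_wg":
                continue
            rows = pd.DataFrame(
                {
                    "bns_group": list(per_source),
                    "mean_grams": [per_source[s].estimate[g] for s in per_source],
                    "se": [per_source[s].se[g] for s in per_source],
                }
            ).sort_values(["mean_grams", "bns_group"],
                          ascending=[False, True], kind="stable").reset_index(drop=True)
            top = rows.head(top_n)
            top_total = float(top["mean_grams"].sum())
            total_mean = float(total_fit.estimate[g])
            pct = 100.0 * top_total / total_mean if total_mean > 0 else np.nan
            if np.isfinite(pct) and (pct < 0 or pct > 100):
                logger.warning(
                    "top-%d share %.1f%% outside [0, 100] for (%s, %s); "
                    "adjusted source means include negative values — clipping",
                    top_n, pct, stratum, g,
                )
                pct = float(np.clip(pct, 0.0, 100.0))
            out[(str(stratum), str(g))] = TopSourcesTable(
                stratum=str(stratum),
                wg_group=str(g),
                rows=rows,
                top10_total_grams=top_total,
                total_wg_grams=total_mean,
                pct_of_total_wg=pct,
            )
    return out


@dataclass
class _RawMeans:
    groups: list
    estimate: dict
    se: dict


def _raw_group_means(y: np.ndarray, groups: pd.Series, w: np.ndarray,
                     rep: np.ndarray | None) -> _RawMeans:
    order = [g for g in groups.cat.categories if (groups == g).any()] \
        if hasattr(groups, "cat") else sorted(pd.unique(groups))
    est, se = {}, {}
    for g in order:
        m = (groups == g).to_numpy()
        est[g] = float(np.average(y[m], weights=w[m]))
        if rep is not None:
            reps = (rep[m] * y[m, None]).sum(axis=0) / rep[m].sum(axis=0)
            se[g] = float(np.sqrt(np.mean((reps - est[g]) ** 2)))
        else:
            mw = w[m] / w[m].sum()
            se[g] = float(np.sqrt(np.sum(mw ** 2 * (y[m] - est[g]) ** 2)))
    return _RawMeans(groups=order, estimate=est, se=se)


def top_total(rows: pd.DataFrame, top_n: int = 10) -> float:
    """Sum of the leading ``top_n`` source means of a ranked table."""
    return float(rows.sort_values(["mean_grams", "bns_group"],
                                  ascending=[False, True])
                 .head(top_n)["mean_grams"].sum())


def percent_change(reference: float, comparison: float) -> float:
    """Percent change from ``reference`` to ``comparison``
    (positive = increase)."""
    if reference == 0:
        raise ZeroDivisionError("reference value must be nonzero")
    return 100.0 * (comparison - reference) / reference
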