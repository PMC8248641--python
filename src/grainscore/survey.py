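"""Survey-weighted estimation with bootstrap replicate-weight variance.

The estimators mirror standard complex-survey practice for a design that
ships a main sampling weight plus B bootstrap replicate weights:

* point estimates use the main weight (weighted least squares for adjusted
  means and trends, weighted contingency tables for chi-square);
* variances re-estimate the statistic under each replicate weight vector and
  take ``v = mean_b (theta_b - theta_hat)^2``, the usual estimator for
  rescaled-bootstrap replicate designs; Wald tests use a t reference with
  B - 1 degrees of freedom;
* adjusted group means are population marginal means: the fitted model is
  evaluated at each exposure group with continuous covariates at their
  weighted means and categorical covariates averaged over their weighted
  observed distribution.

When no replicate weights are supplied every estimator falls back to its
classical model-based counterpart (and with equal weights reduces exactly to
unweighted OLS / Pearson chi-square), which the test suite exploits as an
oracle.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import EstimationError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# covariate derivation


def derive_low_income(household_size, household_income):
    """Low-income flag from household size and gross income (CAD), census
    dictionary style thresholds: size 1 <= 19,999; size 2-3 <= 39,999;
    size >= 4 <= 59,999."""
    size = np.asarray(household_size)
    income = np.asarray(household_income, dtype=float)
    if (income < 0).any():
        raise ValidationError("household income must be >= 0")
    if (size < 1).any():
        raise ValidationError("household size must be >= 1")
    threshold = np.where(size <= 1, 19_999.0, np.where(size <= 3, 39_999.0, 59_999.0))
    out = income <= threshold
    return bool(out) if out.ndim == 0 else out


def derive_overweight(age_years, bmi=None, bmi_z_pctile=None):
    """Overweight/obesity flag: adults (>= 19 y) BMI >= 25 kg/m^2; children
    BMI-for-age z-score percentile >= 75."""
    age = np.asarray(age_years, dtype=float)
    scalar = age.ndim == 0
    age = np.atleast_1d(age)
    bmi = np.full(age.shape, np.nan) if bmi is None else np.atleast_1d(np.asarray(bmi, dtype=float))
    z = (np.full(age.shape, np.nan) if bmi_z_pctile is None
         else np.atleast_1d(np.asarray(bmi_z_pctile, dtype=float)))
    adult = age >= 19
    if np.isnan(bmi[adult]).any():
        raise ValidationError("adults require bmi for the overweight flag")
    if np.isnan(z[~adult]).any():
        raise ValidationError("children require bmi_z_pctile for the overweight flag")
    out = np.where(adult, bmi >= 25.0, z >= 75.0)
    return bool(out[0]) if scalar else out


def weighted_quantile(values, weights, probs):
    """Inverse of the weighted empirical CDF (lowest value whose cumulative
    weight share reaches p)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w) / w.sum()
    return np.array([v[np.searchsorted(cum, p, side="left")] for p in np.atleast_1d(probs)])


def derive_energy_categories(energy, weights, n_levels: int = 5) -> pd.Categorical:
    """Ordinal energy-intake categories at weighted quantile cut points
    (default quintiles), used to adjust for energy non-linearly."""
    if n_levels < 2:
        raise ValidationError("n_levels must be >= 2")
    edges = weighted_quantile(energy, weights, [i / n_levels for i in range(1, n_levels)])
    codes = np.searchsorted(edges, np.asarray(energy, dtype=float), side="left")
    return pd.Categorical(codes, categories=list(range(n_levels)), ordered=True)


def build_covariates(participants: pd.DataFrame, energy: pd.Series,
                     n_energy_levels: int = 5) -> pd.DataFrame:
    """Covariate set for the adjusted models: energy category (weighted
    quantiles), continuous age, gender, overweight/obesity, low income and
    supplement use.  Call per age stratum so energy cut points are
    stratum-specific.  Rows with missing covariates are dropped with a log
    entry (listwise deletion)."""
    p = participants.set_index("participant_id") if "participant_id" in participants else participants
    energy = energy.reindex(p.index)
    cov = pd.DataFrame(index=p.index)
    cov["energy_cat"] = derive_energy_categories(
        energy.to_numpy(dtype=float), p["weight"].to_numpy(dtype=float), n_energy_levels
    )
    cov["age_years"] = p["age_years"].astype(float)
    cov["gender"] = p["gender"].astype("category")
    cov["overweight_obese"] = derive_overweight(
        p["age_years"].to_numpy(dtype=float),
        p["bmi"].to_numpy(dtype=float),
        p["bmi_z_pctile"].to_numpy(dtype=float),
    )
    cov["low_income"] = derive_low_income(
        p["household_size"].to_numpy(), p["household_income"].to_numpy(dtype=float)
    )
    cov["supplement_use"] = p["supplement_use"].astype(bool)
    n_before = len(cov)
    cov = cov.dropna()
    if len(cov) < n_before:
        logger.warning("dropped %d participants with missing covariates", n_before - len(cov))
    return cov


# ---------------------------------------------------------------------------
# design-matrix helpers


def _covariate_matrix(covariates: pd.DataFrame | None) -> pd.DataFrame:
    """Expand covariates to numeric columns: categoricals/bools to
    drop-first dummies, numerics passed through."""
    if covariates is None or covariates.shape[1] == 0:
        return pd.DataFrame(index=None if covariates is None else covariates.index)
    parts = []
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype.kind in "biufc" and s.dtype != bool:
            parts.append(s.astype(float).rename(col))
        else:
            if isinstance(s.dtype, pd.CategoricalDtype):
                s = s.cat.remove_unused_categories()
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
    return pd.concat(parts, axis=1)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = []
        for j in range(X.shape[1]):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                aliased.append(names[j])
        raise EstimationError(f"design matrix is rank deficient; aliased terms: {aliased}")


def _wls_beta(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return beta


def _replicate_matrix(replicate_weights) -> np.ndarray | None:
    if replicate_weights is None:
        return None
    arr = np.asarray(replicate_weights, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("replicate weights must be a 2-D array (participants x B)")
    return arr


# ---------------------------------------------------------------------------
# adjusted group means


@dataclass
class GroupMeansFit:
    """Adjusted (least-squares) group means with replicate or model SEs.

    Carries enough of the fitted model to derive pairwise contrasts."""

    groups: list
    estimate: dict
    se: dict
    n_per_group: dict
    df_resid: float
    # internals for contrasts
    _ref_rows: dict = field(repr=False, default_factory=dict)
    _beta: np.ndarray | None = field(repr=False, default=None)
    _cov_beta: np.ndarray | None = field(repr=False, default=None)
    _replicate_lsmeans: np.ndarray | None = field(repr=False, default=None)  # B x G
    _df_error: float = field(repr=False, default=np.nan)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.groups,
                "lsmean": [self.estimate[g] for g in self.groups],
                "se": [self.se[g] for g in self.groups],
                "n": [self.n_per_group[g] for g in self.groups],
            }
        )


def _lsmean_design(group_labels: pd.Series, covariates: pd.DataFrame | None,
                   weights: np.ndarray):
    """Full design matrix (intercept + drop-first group dummies + expanded
    covariates) and the weighted reference row per group."""
    groups = pd.Series(group_labels).astype("category").cat.remove_unused_categories()
    order = list(groups.cat.categories)
    gdum = pd.get_dummies(groups, prefix="group", drop_first=True, dtype=float)
    gdum.index = group_labels.index if hasattr(group_labels, "index") else gdum.index
    cmat = _covariate_matrix(covariates)
    if len(cmat.columns) > 0:
        cmat = cmat.loc[gdum.index]
    X = pd.concat([gdum, cmat], axis=1)
    X.insert(0, "Intercept", 1.0)

    # reference grid: covariates at weighted means, group dummies switched
    cov_mean = (
        np.average(cmat.to_numpy(dtype=float), axis=0, weights=weights)
        if len(cmat.columns) else np.empty(0)
    )
    ref_rows = {}
    for g in order:
        row = np.concatenate([[1.0],
                              [1.0 if f"group_{g}" == c else 0.0 for c in gdum.columns],
                              cov_mean])
        ref_rows[g] = row
    return X, order, ref_rows


def weighted_lsmeans(
    outcome,
    group_labels,
    covariates: pd.DataFrame | None,
    weights,
    replicate_weights=None,
) -> GroupMeansFit:
    """Covariate-adjusted group means from a survey-weighted linear model.

    SEs come from replicate-weight refits when ``replicate_weights`` is
    given (sd over replicates around the full-sample estimate, df = B - 1),
    else from the model-based WLS covariance.
    """
    y = np.asarray(outcome, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not isinstance(group_labels, pd.Series):
        group_labels = pd.Series(group_labels)
    nonempty = group_labels.value_counts()
    if (nonempty > 0).sum() < 2:
        raise EstimationError("need at least 2 nonempty groups")

    X_df, order, ref_rows = _lsmean_design(group_labels, covariates, w)
    X = X_df.to_numpy(dtype=float)
    _check_rank(X * np.sqrt(w)[:, None], list(X_df.columns))

    model = sm.WLS(y, X, weights=w)
    fit = model.fit()
    beta = fit.params
    lsmeans = {g: float(ref_rows[g] @ beta) for g in order}

    n_per_group = {g: int((group_labels == g).sum()) for g in order}
    rep = _replicate_matrix(replicate_weights)
    if rep is not None:
        B = rep.shape[1]
        rep_ls = np.empty((B, len(order)))
        for b in range(B):
            beta_b = _wls_beta(X, y, rep[:, b])
            rep_ls[b] = [ref_rows[g] @ beta_b for g in order]
        point = np.array([lsmeans[g] for g in order])
        se_vec = np.sqrt(np.mean((rep_ls - point) ** 2, axis=0))
        se = {g: float(s) for g, s in zip(order, se_vec)}
        df_error = B - 1
        cov_beta = None
        rep_store = rep_ls
    else:
        cov_beta = np.asarray(fit.cov_params())
        se = {g: float(np.sqrt(ref_rows[g] @ cov_beta @ ref_rows[g])) for g in order}
        df_error = float(fit.df_resid)
        rep_store = None

    return GroupMeansFit(
        groups=order,
        estimate=lsmeans,
        se=se,
        n_per_group=n_per_group,
        df_resid=float(fit.df_resid),
        _ref_rows=ref_rows,
        _beta=np.asarray(beta),
        _cov_beta=cov_beta,
        _replicate_lsmeans=rep_store,
        _df_error=df_error,
    )


# ---------------------------------------------------------------------------
# trend test


@dataclass
class TrendResult:
    slope: float
    se: float
    p: float
    df: float


def linear_trend_test(
    outcome,
    group_scores,
    covariates: pd.DataFrame | None,
    weights,
    replicate_weights=None,
) -> TrendResult:
    """Two-sided Wald test of the slope of the ordinal exposure score in a
    survey-weighted covariate-adjusted linear regression."""
    y = np.asarray(outcome, dtype=float)
    s = np.asarray(group_scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.unique(s).size < 2:
        raise EstimationError("trend test undefined with < 2 distinct group scores")

    cmat = _covariate_matrix(covariates)
    cols = [np.ones_like(y), s]
    names = ["Intercept", "score"]
    if len(cmat.columns):
        cols.extend(cmat[c].to_numpy(dtype=float) for c in cmat.columns)
        names.extend(cmat.columns)
    X = np.column_stack(cols)
    _check_rank(X * np.sqrt(w)[:, None], names)

    fit = sm.WLS(y, X, weights=w).fit()
    slope = float(fit.params[1])

    rep = _replicate_matrix(replicate_weights)
    if rep is not None:
        B = rep.shape[1]
        slopes = np.array([_wls_beta(X, y, rep[:, b])[1] for b in range(B)])
        se = float(np.sqrt(np.mean((slopes - slope) ** 2)))
        df = B - 1
    else:
        se = float(fit.bse[1])
        df = float(fit.df_resid)

    if se == 0.0:
        p = 1.0 if slope == 0.0 else 0.0
    else:
        p = float(2.0 * stats.t.sf(abs(slope) / se, df))
    return TrendResult(slope=slope, se=se, p=p, df=df)


# ---------------------------------------------------------------------------
# categorical chi-square


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p: float
    design_effect: float


def weighted_chi2(values, group_labels, weights, replicate_weights=None) -> Chi2Result:
    """Pearson chi-square on the survey-weighted contingency table, scaled
    to the unweighted sample size, with a first-order design-effect
    correction estimated from replicate weights when provided (mean
    estimated design effect of the cell proportions, Rao-Scott style)."""
    v = pd.Series(values).reset_index(drop=True)
    g = pd.Series(group_labels).reset_index(drop=True)
    w = np.asarray(weights, dtype=float)
    n = len(v)

    table = pd.crosstab(v, g, values=w, aggfunc="sum").fillna(0.0)
    # collapse empty rows/columns
    keep_r = table.sum(axis=1) > 0
    keep_c = table.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        logger.warning("collapsing empty rows/columns in weighted contingency table")
        table = table.loc[keep_r, keep_c]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise EstimationError("chi-square test undefined: need >= 2 levels and >= 2 groups")

    props = table.to_numpy() / table.to_numpy().sum()
    observed = props * n
    rowsum = observed.sum(axis=1, keepdims=True)
    colsum = observed.sum(axis=0, keepdims=True)
    expected = rowsum @ colsum / n
    stat = float(((observed - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)

    deff = 1.0
    rep = _replicate_matrix(replicate_weights)
    if rep is not None:
        deffs = []
        levels_v, levels_g = list(table.index), list(table.columns)
        for lv, lg in itertools.product(levels_v, levels_g):
            cell = ((v == lv) & (g == lg)).to_numpy()
            p_hat = float(np.average(cell, weights=w))
            if p_hat <= 0.0 or p_hat >= 1.0:
                continue
            p_b = (rep * cell[:, None]).sum(axis=0) / rep.sum(axis=0)
            v_rep = float(np.mean((p_b - p_hat) ** 2))
            v_srs = p_hat * (1.0 - p_hat) / n
            if v_srs > 0:
                deffs.append(v_rep / v_srs)
        if deffs:
            deff = float(np.mean(deffs))
            stat = stat / deff

    return Chi2Result(statistic=stat, df=df, p=float(stats.chi2.sf(stat, df)), design_effect=deff)


# ---------------------------------------------------------------------------
# multiple comparisons


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return alpha / m


def tukey_kramer(fit: GroupMeansFit) -> pd.DataFrame:
    """All pairwise adjusted-mean contrasts with studentized-range
    (Tukey-Kramer) adjusted p-values.

    Uses replicate-weight SEs of each difference when the fit carried
    replicate weights, else the model-based contrast SE; the studentized
    range has k = number of groups and the fit's error df.
    """
    k = len(fit.groups)
    rows = []
    for a, b in itertools.combinations(fit.groups, 2):
        diff = fit.estimate[a] - fit.estimate[b]
        if fit._replicate_lsmeans is not None:
            ia, ib = fit.groups.index(a), fit.groups.index(b)
            rep_diff = fit._replicate_lsmeans[:, ia] - fit._replicate_lsmeans[:, ib]
            se = float(np.sqrt(np.mean((rep_diff - diff) ** 2)))
        else:
            c = fit._ref_rows[a] - fit._ref_rows[b]
            se = float(np.sqrt(c @ fit._cov_beta @ c))
        if se == 0.0:
            p_adj = 1.0 if diff == 0.0 else 0.0
        else:
            q = abs(diff) / se * np.sqrt(2.0)
            p_adj = float(stats.studentized_range.sf(q, k, fit._df_error))
        rows.append({"group_a": a, "group_b": b, "difference": float(diff),
                     "se": se, "p_adj": min(max(p_adj, 0.0), 1.0)})
    return pd.DataFrame(rows)
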