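"""Survey-weighted estimators against classical oracles.

Every weighted estimator must collapse to its textbook unweighted
counterpart under equal weights, and the weighted fits must agree with an
independently coded normal-equations solver.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grainscore.errors import EstimationError, ValidationError
from grainscore.survey import (bonferroni_threshold, derive_energy_categories,
                               derive_low_income, derive_overweight,
                               linear_trend_test, tukey_kramer, weighted_chi2,
                               weighted_lsmeans, weighted_quantile)


# ---------------------------------------------------------------------------
# covariate derivation


@pytest.mark.parametrize(
    "size, income, expected",
    [
        (1, 19_999, True), (1, 20_000, False),
        (2, 39_999, True), (3, 40_000, False),
        (4, 59_999, True), (6, 59_999, True), (5, 60_000, False),
    ],
)
def test_low_income_thresholds(size, income, expected):
    assert derive_low_income(size, income) is expected


def test_low_income_rejects_negative_income():
    with pytest.raises(ValidationError):
        derive_low_income(2, -1.0)


@pytest.mark.parametrize(
    "age, bmi, z, expected",
    [
        (30, 25.0, None, True), (30, 24.9, None, False),
        (10, None, 75.0, True), (10, None, 74.9, False),
    ],
)
def test_overweight_boundaries(age, bmi, z, expected):
    assert derive_overweight(age, bmi=bmi, bmi_z_pctile=z) is expected


def test_overweight_missing_measure_rejected():
    with pytest.raises(ValidationError):
        derive_overweight(30, bmi=None, bmi_z_pctile=50.0)


def test_energy_quintiles_are_balanced_under_equal_weights():
    rng = np.random.default_rng(0)
    energy = rng.normal(2000, 400, 1000)
    cats = derive_energy_categories(energy, np.ones(1000), 5)
    counts = pd.Series(cats).value_counts()
    assert counts.max() - counts.min() <= 1


# ---------------------------------------------------------------------------
# adjusted means


def _oracle_lsmeans(y, groups, cov, w):
    """Independent normal-equations solver + reference-grid prediction."""
    levels = sorted(set(groups))
    dummies = np.column_stack([(np.asarray(groups) == g).astype(float)
                               for g in levels[1:]])
    X = np.column_stack([np.ones(len(y)), dummies] +
                        ([np.asarray(cov, dtype=float)] if cov is not None else []))
    W = np.diag(w)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    out = {}
    for i, g in enumerate(levels):
        row = [1.0] + [1.0 if j == i - 1 else 0.0 for j in range(len(levels) - 1)]
        if cov is not None:
            row.append(np.average(cov, weights=w))
        out[g] = float(np.asarray(row) @ beta)
    return out


def test_equal_weights_no_covariates_reduce_to_group_means():
    rng = np.random.default_rng(1)
    y = rng.normal(size=90)
    groups = pd.Series(np.repeat(["a", "b", "c"], 30))
    fit = weighted_lsmeans(y, groups, None, np.ones(90))
    for g in ("a", "b", "c"):
        assert fit.estimate[g] == pytest.approx(y[groups == g].mean(), abs=1e-8)


def test_matches_normal_equations_oracle_on_random_designs():
    rng = np.random.default_rng(2)
    for _ in range(10):
        n = 200
        y = rng.normal(size=n)
        groups = pd.Series(rng.choice(["g0", "g1", "g2", "g3"], n))
        cov = rng.normal(size=n)
        w = rng.uniform(0.2, 3.0, n)
        fit = weighted_lsmeans(y, groups, pd.DataFrame({"x": cov}), w)
        oracle = _oracle_lsmeans(y, groups, cov, w)
        for g, val in oracle.items():
            assert fit.estimate[g] == pytest.approx(val, abs=1e-8)


def test_balanced_orthogonal_covariate_leaves_group_means():
    # covariate pattern identical within every group -> adjustment is a no-op
    y = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0])
    groups = pd.Series(["a"] * 4 + ["b"] * 4)
    cov = pd.DataFrame({"x": [-1, -1, 1, 1, -1, -1, 1, 1]})
    fit = weighted_lsmeans(y, groups, cov, np.ones(8))
    assert fit.estimate["a"] == pytest.approx(2.5)
    assert fit.estimate["b"] == pytest.approx(11.5)


def test_rank_deficiency_names_aliased_terms():
    y = np.arange(6, dtype=float)
    groups = pd.Series(["a", "a", "a", "b", "b", "b"])
    cov = pd.DataFrame({"x": [0, 0, 0, 1, 1, 1]})  # aliased with group
    with pytest.raises(EstimationError, match="aliased"):
        weighted_lsmeans(y, groups, cov, np.ones(6))


def test_replicate_se_close_to_model_se():
    """On an i.i.d. equal-weight sample, bootstrap-replicate SEs should land
    near the model-based SEs."""
    rng = np.random.default_rng(3)
    n, B = 600, 60
    y = rng.normal(size=n)
    groups = pd.Series(np.repeat(["a", "b", "c"], n // 3))
    w = np.ones(n)
    # each participant its own sampling unit: multinomial bootstrap weights
    rep = rng.multinomial(n, np.ones(n) / n, size=B).T.astype(float)
    rep *= n / rep.sum(axis=0, keepdims=True)
    fit_rep = weighted_lsmeans(y, groups, None, w, rep)
    fit_mod = weighted_lsmeans(y, groups, None, w)
    for g in ("a", "b", "c"):
        assert fit_rep.se[g] == pytest.approx(fit_mod.se[g], rel=0.35)


# ---------------------------------------------------------------------------
# trend test


def test_constant_outcome_gives_p_one():
    res = linear_trend_test(np.ones(40), np.tile([0, 1, 2, 3], 10), None,
                            np.ones(40))
    assert res.slope == pytest.approx(0.0)
    assert res.p == 1.0


def test_perfect_trend_is_arbitrarily_significant():
    scores = np.tile([0.0, 1.0, 2.0, 3.0], 10)
    res = linear_trend_test(scores.copy(), scores, None, np.ones(40))
    assert res.slope == pytest.approx(1.0)
    assert res.p < 1e-12


def test_trend_undefined_with_single_score():
    with pytest.raises(EstimationError):
        linear_trend_test(np.ones(10), np.zeros(10), None, np.ones(10))


def test_trend_slope_equals_lsmean_step_when_linear():
    """When adjusted means are exactly linear in the ordinal score the trend
    slope equals the per-step difference."""
    rng = np.random.default_rng(4)
    n = 400
    scores = rng.integers(0, 4, n).astype(float)
    cov = pd.DataFrame({"x": rng.normal(size=n)})
    y = 2.0 + 1.5 * scores + 0.8 * cov["x"].to_numpy()
    w = rng.uniform(0.5, 2.0, n)
    res = linear_trend_test(y, scores, cov, w)
    fit = weighted_lsmeans(y, pd.Series(scores.astype(int)), cov, w)
    steps = np.diff([fit.estimate[g] for g in fit.groups])
    assert res.slope == pytest.approx(1.5, abs=1e-8)
    np.testing.assert_allclose(steps, 1.5, atol=1e-8)


# ---------------------------------------------------------------------------
# chi-square


def test_identical_distributions_give_zero_statistic():
    v = pd.Series(["x", "y"] * 20)
    g = pd.Series(["a"] * 20 + ["b"] * 20)
    res = weighted_chi2(v, g, np.ones(40))
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_matches_classical_pearson_with_equal_weights():
    rng = np.random.default_rng(5)
    v = pd.Series(rng.choice(["x", "y", "z"], 300))
    g = pd.Series(rng.choice(["a", "b"], 300))
    res = weighted_chi2(v, g, np.ones(300))
    stat, p, df, _ = stats.chi2_contingency(pd.crosstab(v, g), correction=False)
    assert res.statistic == pytest.approx(stat, abs=1e-8)
    assert res.p == pytest.approx(p, abs=1e-8)
    assert res.df == df


def test_single_level_variable_undefined():
    with pytest.raises(EstimationError):
        weighted_chi2(pd.Series(["x"] * 20), pd.Series(["a", "b"] * 10), np.ones(20))


def test_design_effect_shrinks_statistic_under_clustering():
    """Cluster-correlated replicate weights should yield a design effect > 1
    and a smaller corrected statistic."""
    rng = np.random.default_rng(6)
    n, B, n_clust = 400, 50, 20
    clust = rng.integers(0, n_clust, n)
    v = pd.Series(np.where((clust % 2 == 0) ^ (rng.random(n) < 0.15), "x", "y"))
    g = pd.Series(rng.choice(["a", "b"], n))
    w = np.ones(n)
    rep = np.empty((n, B))
    for b in range(B):
        draws = rng.integers(0, n_clust, n_clust - 1)
        counts = np.bincount(draws, minlength=n_clust)
        wb = counts[clust] * (n_clust / (n_clust - 1))
        rep[:, b] = wb * n / wb.sum()
    res_corr = weighted_chi2(v, g, w, rep)
    res_raw = weighted_chi2(v, g, w)
    assert res_corr.design_effect > 1.0
    assert res_corr.statistic < res_raw.statistic


# ---------------------------------------------------------------------------
# multiple comparisons


@pytest.mark.parametrize("alpha, m, expected", [(0.05, 22, 0.05 / 22),
                                                (0.05, 24, 0.05 / 24),
                                                (0.05, 1, 0.05)])
def test_bonferroni(alpha, m, expected):
    assert bonferroni_threshold(alpha, m) == pytest.approx(expected)


def test_bonferroni_validation():
    with pytest.raises(ValidationError):
        bonferroni_threshold(1.5, 4)
    with pytest.raises(ValidationError):
        bonferroni_threshold(0.05, 0)


def test_tukey_identical_groups_p_one():
    y = np.tile(np.array([1.0, 2.0, 3.0]), 4)
    groups = pd.Series(np.repeat(["a", "b"], 6))
    fit = weighted_lsmeans(y, groups, None, np.ones(12))
    contrasts = tukey_kramer(fit)
    row = contrasts.iloc[0]
    assert row["difference"] == pytest.approx(0.0, abs=1e-12)
    assert row["p_adj"] == pytest.approx(1.0)


def test_tukey_antisymmetry():
    rng = np.random.default_rng(7)
    y = rng.normal(size=80)
    groups = pd.Series(rng.choice(list("abcd"), 80))
    fit = weighted_lsmeans(y, groups, None, np.ones(80))
    contrasts = tukey_kramer(fit)
    assert len(contrasts) == 6
    for _, row in contrasts.iterrows():
        assert row["difference"] == pytest.approx(
            fit.estimate[row["group_a"]] - fit.estimate[row["group_b"]], abs=1e-12)


def test_tukey_matches_published_critical_value():
    """4 balanced groups of 6, error df = 20: a difference engineered to hit
    the published 5% studentized-range point q(4, 20) = 3.958 must get an
    adjusted p of 0.050 to 3 decimals."""
    noise = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
    # MSE = 4 * 6 / 20 = 1.2; se(diff) = sqrt(1.2 * 2/6); q = diff*sqrt(2)/se
    se_diff = np.sqrt(1.2 * 2.0 / 6.0)
    diff = 3.958 * se_diff / np.sqrt(2.0)
    means = [0.0, diff, 50.0, 100.0]
    y = np.concatenate([m + noise for m in means])
    groups = pd.Series(np.repeat(["a", "b", "c", "d"], 6))
    fit = weighted_lsmeans(y, groups, None, np.ones(24))
    assert fit.df_resid == pytest.approx(20.0)
    contrasts = tukey_kramer(fit).set_index(["group_a", "group_b"])
    p = contrasts.loc[("a", "b"), "p_adj"]
    assert p == pytest.approx(0.050, abs=1e-3)


def test_weighted_quantile_inverse_cdf():
    vals = np.array([1.0, 2.0, 3.0, 4.0])
    w = np.array([1.0, 1.0, 1.0, 1.0])
    np.testing.assert_allclose(weighted_quantile(vals, w, [0.25, 0.5, 1.0]),
                               [1.0, 2.0, 4.0])
    # weight mass concentrated on the last value pulls quantiles up
    w2 = np.array([0.1, 0.1, 0.1, 10.0])
    assert weighted_quantile(vals, w2, [0.5])[0] == 4.0
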