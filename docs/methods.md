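# Methods

This note documents the models, conventions and numerical choices behind
`grainscore`, and what its synthetic-data tests do and do not establish.

## Food classification and intake aggregation

Each catalog food carries a CFG category (ten food categories with an
alignment tier 1–4, plus three untier-ed buckets: discretionary foods,
other foods and recipes, foods not classified), a BNS source-group label, a
whole-grain flag (true exactly for the "Grain products – whole" category),
optional grams per serving, an energy density (kcal/g) and per-gram
nutrient densities for the 22 analysis nutrients. Units are fixed once in
the DV table (g, mg, µg, µg RAE per nutrient); there is no conversion
layer. A nutrient column missing from a catalog is treated as density 0
with a logged warning, the usual convention for unassayed nutrients in food
composition databases.

Intakes are linear aggregations: nutrient and energy intake are
`Σ grams × density` over a participant's recall records, and food-group
cells sum grams within (category, tier block), where tiers 1–3 pool the
fully and partially aligned foods and tier 4 stands alone. Macronutrient
percent of energy uses the 4/9/4 kcal/g Atwater factors.

### Whole-grain exposure

`wg_grams` sums grams of WG-flagged foods; `wg_servings` divides by
per-food serving sizes (undefined, with a log entry, if a consumed WG food
lacks one); total grain is refined + whole grains over all four tiers. The
percent of grain intake from WG is computed **per participant** as
`100 × wg / total_grain` and averaged as a mean of ratios — not as a ratio
of group means, which is a different statistic (the test suite demonstrates
the inequality on a 3-participant example). Participants with no grain
intake contribute 0% rather than being excluded, so a no-WG group that
includes grain-free diets still reports 0 ± 0%.

### Stratification

WG consumers are split within age stratum (child 1–18 y, adult ≥ 19 y) at
the unweighted empirical 1/3 and 2/3 quantiles of WG grams. Unweighted
cuts are deliberate: they produce near-equal group counts, the signature of
tertile designs in survey reports. The quantile is the type-1
(inverse-CDF) definition, `q_p = x_(⌈np⌉)` on the sorted sample, and
boundary-valued participants fall to the lower group — deterministic and
order-independent. If every consumer ties, all land in the low group with
a warning. A stratum that contains participants but fewer than 3 consumers
is an error; a stratum with no participants at all is skipped.

## Modified NRF 9.3

The Nutrient Rich Food Index 9.3 is adapted to the whole diet: each
nutrient's daily amount is standardised to the energy basis
(`amount × basis / energy`, basis default 2000 kcal), expressed as a
percent of its daily value, the nine encourage contributions are capped
(default 100%) and summed, and the three uncapped limit contributions are
subtracted. The operation order — energy-adjust, then %DV, then cap — is
the only one under which the per-basis phrasing and the cap are both
well defined per participant. Consequences verified by property tests:

* ceiling of exactly 900 (9 × 100% minus zero);
* scale invariance: scaling all amounts and energy together is a no-op;
* monotone non-decreasing in encourage nutrients (flat past the cap),
  strictly decreasing in limit nutrients.

The 2000-kcal basis is used throughout, although source material for this
style of index sometimes states the 900 maximum "per 1000 kcal"; the basis
and the cap are both configurable (`DVTable.energy_basis_kcal`,
`DVTable.cap_percent`) so the 1000-kcal variant needs no code change. The
shipped daily values are Health-Canada-style placeholders (e.g. fiber 28 g,
sodium 2300 mg) marked non-normative; analyses of real data should supply
their own `dv.csv`. Zero-energy intakes score NaN and are excluded from
group summaries with a log entry.

## Survey-weighted estimation

Point estimates use the main sampling weight. Adjusted group means come
from a weighted least-squares regression of the outcome on WG-group
indicators plus covariates, evaluated as population marginal means: the
fitted model is predicted at each group with continuous covariates at their
weighted means and categorical covariates at their weighted observed
proportions (not equal cell weighting — the convention most consistent with
survey-weighted reporting; the reference grid is explicit in the code and
could be swapped). The trend test regresses on the ordinal group score
(0–3) with the same covariates and Wald-tests the slope two-sided.

Covariates follow the standard confounder set for diet-quality contrasts:
energy intake as a categorical variable (within-stratum weighted quintiles
by default, capturing non-linear energy differences across WG groups),
continuous age, gender, overweight/obesity (adults BMI ≥ 25 kg/m²,
children BMI-for-age percentile ≥ 75), low income (household gross income
thresholds by size: 1 person ≤ \$19,999; 2–3 ≤ \$39,999; ≥ 4 ≤ \$59,999)
and supplement use. Missing covariates are handled by listwise deletion
with logged counts. Extreme-energy records are retained by default with an
optional exclusion flag.

### Variance

When replicate weights are supplied, every statistic is re-estimated under
each of the B replicate weight vectors and
`v = (1/B) Σ_b (θ_b − θ̂)²`, the standard estimator for rescaled-bootstrap
replicate designs; Wald tests use a t reference with B − 1 degrees of
freedom. Without replicate weights the estimators fall back to model-based
WLS covariance, and with equal weights they reduce exactly to unweighted
OLS / Pearson chi-square — the test suite uses this reduction, plus an
independently coded normal-equations solver, as oracles.

The weighted chi-square scales the weighted contingency proportions to the
unweighted sample size and applies a first-order Rao–Scott-style
correction: the statistic is divided by the mean estimated design effect of
the cell proportions (replicate variance over binomial variance).
Tukey–Kramer contrasts convert each pairwise difference to a studentized
range statistic `q = √2 |diff| / SE(diff)` with k = number of groups and
the replicate (or residual) degrees of freedom; a frozen published critical
value, q₀.₀₅(4, 20) = 3.958, anchors the test of this mapping.

## Synthetic data generator

The generator emulates the structure such an analysis observes on national
data: roughly half of participants (child stratum 50%, adult 46% by
default) consume no WG food; consumer WG grams are log-normal
(meanlog/sdlog defaults 3.9/1.0 children, 4.2/1.0 adults), reproducing the
heavy right tail behind tertile means around 19→163 g/d (children) and
29→220 g/d (adults); energy is normal (1800 ± 450 kcal children,
1900 ± 550 adults) with a positive energy–WG slope for children only
(1.2 kcal per WG gram), mirroring the child-specific unadjusted energy
gradient.

The ground truth that recovery tests target is linear:
`per-2000-kcal intake of nutrient n = baseline_n + slope_n × wg + noise`
(noise CV 0.25). Default slopes encode the qualitative adjusted gradients
seen in national data — fiber +0.04 g, magnesium +0.45 mg, potassium
+1.0 mg, calcium +0.5 mg, iron +0.012 mg and folic acid −0.19 µg per WG
gram — with all other nutrients null. Mechanically, a realistic basket
(WG foods split across BNS groups with breakfast cereal and bread dominant,
refined grains declining in WG, one food per remaining category) is topped
up to the target intake vector by zero-energy composite "mixed dish" foods
(one per nutrient) and an energy filler, so the linear structure holds
exactly except when a basket already exceeds a target (the residual clips
at zero — rare at the default baselines). Sampling weights are log-normal
with CV 0.5; replicate weights are a Rao–Wu-style rescaled bootstrap over
50 simulated PSUs (B = 100 by default), each replicate calibrated to the
full-sample weight total.

What the generator does **not** emulate: multi-stage stratified clustering
with unequal PSU sizes, misreporting and usual-intake (within-person)
variance, correlated food co-consumption patterns, and real food
composition correlations (nutrients are conditionally independent given WG
grams). Passing recovery tests therefore establishes that the estimators
are correct for a calibrated replicate-weight design with linear
exposure–outcome structure — not that the pipeline is robust to
misreporting or informative cluster sampling.

## Problem sizes and numerical conventions

* Recovery simulations in the test suite use 50 seeds at n = 2000 per
  stratum with B = 100 replicates — large enough that the null-trend
  rejection rate and 2-SE coverage are informative, small enough that the
  full suite runs in well under a minute of simulation time.
* Ranking ties in top-source tables break lexicographically on the BNS
  label; output is invariant to catalog row order.
* Rank-deficient design matrices raise an estimation error naming the
  aliased terms rather than silently dropping them.
* Trend tests define p = 1 when both slope and SE are zero (constant
  outcome) and p = 0 for a nonzero slope with zero SE (perfect fit).
* Adjusted source means can be slightly negative, so a top-10 share can
  nominally exceed 100%; shares are clipped to [0, 100] with a warning.

## Known limitations

* WG exposure counts grams of WG *foods*, not grams of whole grain per se;
  foods outside the CFG classification (mixed dishes) contribute nutrients
  but no WG grams, understating true WG intake.
* The chi-square design correction is first-order only (no second-order
  Satterthwaite adjustment), and there is no finite-population correction
  or Taylor-linearisation variance path.
* Tukey–Kramer p-values with replicate SEs treat the replicate degrees of
  freedom as exact, which is approximate for small B.
* The published-value arithmetic in `scripts/acceptance.py` necessarily
  takes the published per-row estimates as inputs; only desk-scale
  arithmetic (sums, ratios, thresholds, the score ceiling) is
  re-derivable without the restricted source microdata.
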