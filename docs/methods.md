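# Methods

`causalhurdle` estimates average and heterogeneous effects of a binary
treatment (e.g. enrolment in a subsidised health-insurance scheme) on
zero-inflated healthcare-utilisation counts, under unconfoundedness and
overlap. This note documents the statistical procedure, the synthetic data
that exercises it, and the numerical and design choices a maintainer would
want to know.

## The estimation problem

For covariates X, binary treatment D and a non-negative integer outcome Y
(counts of inpatient days or outpatient visits), the targets are the ATE
τ = E[Y(1) − Y(0)] and the CATE function τ(x) = E[Y(1) − Y(0) | X = x].
Identification assumes unconfoundedness (Y(d) ⟂ D | X) and overlap
(0 < e(x) = P(D=1|X=x) < 1). Because utilisation data carry a large mass at
zero, the outcome regression is decomposed as a hurdle (two-part) model

    m(x) = E[Y | X=x] = P(Y>0 | X=x) · E[Y | Y>0, X=x] = m1(x) · m2(x),

and three outcome models are analysed throughout: the *two-part* model (Y),
the *participation* component (1{Y>0}) and the *consumption* component
(Y on the Y>0 rows). The consumption component conditions on post-treatment
participation; it is reported as a descriptive decomposition, not a separate
causal contrast on the full population (its DR scores are computed on the
users' subpopulation, with the propensity re-estimated there by default —
a `consumption_propensity="full"` flag switches to the full-sample
propensity).

## Nuisance estimation: two-part super learners

e(x), m1(x) and m2(x) are estimated by stacking ("super learner"):
out-of-fold predictions from a library of base learners (K = 5 folds) are
combined by an **unconstrained OLS metalearner** — intercept included,
coefficients may be negative and need not sum to one. Binary tasks use
weighted log loss, count tasks weighted MSE. The shipped libraries are

* binary: binomial GLM, L1-penalised logistic, random forest, gradient
  boosting (plus an optional MLP in the "full" profile);
* count: gaussian GLM, Poisson GLM, lasso, random forest, gradient boosting
  (the "full" profile adds Poisson/negative-binomial lasso variants and an
  MLP; the negative-binomial and neural members are excluded from the default
  because they are fragile at desk scale and contribute little weight).

A learner that fails in any fold is dropped with a warning rather than
aborting the library. Unconstrained stacking can leave [0,1] for binary
tasks: the ensemble output is clipped to [0,1] when used as a probability or
propensity, and count predictions are floored at 0; `m̂ = m̂1·m̂2` holds
exactly by construction. The ensemble row of the cross-validated loss table
comes from a second K-fold pass that refits only the metalearner on the
training folds' out-of-fold base predictions — cheaper than renesting the
entire stack and adequate for ranking. The MLP member ignores non-uniform
sample weights (scikit-learn limitation, logged); all other fits take
frequency weights.

## CATE estimation: honest causal forest

The forest is implemented from first principles (gradient pseudo-outcome
splitting, honesty, forest-weight prediction), with grf-style semantics:

* **Residualisation.** Trees operate on Dres = D − ê(X) and Yres = Y − m̂(X)
  with nuisances predicted out-of-fold (see cross-fitting below).
* **Honesty.** Each tree draws a subsample without replacement
  (`sample_fraction`, default 0.5), splits it into a structure part
  (`honesty_fraction`) and an estimation part. Splits use only the structure
  part; leaves are populated with the estimation part. With
  `honesty_prune_leaves` (default on), a branch whose subtree holds no
  estimation rows is collapsed so every honest leaf is non-empty; with it
  off, a query routed into an empty leaf contributes nothing for that tree
  (the forest renormalises over contributing trees).
* **Pseudo-outcomes.** Within a parent node,
  ρ_i = A_P⁻¹ (Dc_i)[(Yc_i) − Dc_i β̂_P], where Dc, Yc are the
  weight-centred residuals, β̂_P is the within-node weighted least-squares
  slope of Yres on Dres, and A_P is the weighted mean of Dc² (weight-
  normalised, so the statistic is invariant to rescaling the weights). The
  weighted sum of ρ within a node is zero by least-squares orthogonality —
  a property the tests verify to 1e−10.
* **Split search.** Candidate thresholds are midpoints between consecutive
  distinct sorted values of the structure rows. The score
  Δ(L,R) = (Σ_L wρ)²/W_L + (Σ_R wρ)²/W_R − penalty·(1/W_L + 1/W_R) is
  maximised subject to (i) each child holding ≥ `alpha` share of the parent
  weight and (ii) ≥ `min_node_size` treated AND control structure rows per
  child. `min_node_size` is deliberately the minimum of *both* arms (the
  grf count semantics differ slightly). Ties are broken by lowest feature
  index, then lowest threshold. A unit-test oracle enumerates every split on
  small nodes and confirms the vectorised search agrees.
* **Prediction.** A query x receives, per tree, weight w_i/W_leaf on each
  estimation row sharing its leaf; averaging over trees gives forest weights
  w_i(x) summing to one, and
  τ̂(x) = Σ w_i(x)·Dres_i·Yres_i / Σ w_i(x)·Dres_i². Per-leaf sufficient
  statistics make this O(trees · depth) per query. A zero denominator raises
  an undefined-CATE error naming the row.
* **Variable importance.** Depth-weighted split frequencies: the share of
  splits at depth d involving each feature, weighted 2⁻ᵈ over the first four
  levels, normalised to sum to one (all-zero when no split exists).
* **Tuning.** `tune_params` draws candidate parameter vectors and picks the
  one minimising the out-of-bag debiased (R-) loss
  Σw(Yres − τ̂oob·Dres)² of small forests (`tune_trees`, default 200).
  The pipeline uses fixed defaults unless `forest: tune` is configured.

Defaults follow grf: `num_trees` 2000 (the pipeline's "desk" profile uses
200 so a full run finishes in minutes on one CPU; the full-scale "paper"
profile restores 2000), `mtry` = min(⌈√p⌉+20, p), `min_node_size` 5, `alpha` 0.05,
`imbalance_penalty` 0. Subsampling is without replacement; the honesty split
is a simple random partition of the subsample.

## Cross-fitting and doubly robust scores

Rows are split into three folds (optionally grouped by a household key to
prevent within-household leakage; the default is row-level assignment).
Three rotations give each fold one turn in each role:

1. the *nuisance* fold trains the super learners;
2. the *cate* fold trains the causal forest on residualised data;
3. the *score* fold receives out-of-sample τ̂(X_i) and the AIPTW score
   Γ̂_i = τ̂(X_i) + (D_i−ê_i)/(ê_i(1−ê_i))·(Y_i − m̂_i − (D_i−ê_i)τ̂(X_i)).

The assembled panel is fully out-of-sample — an audit verifies that no row's
own fold ever served as its nuisance or CATE fold — and the weighted mean of
Γ̂ is the AIPTW ATE, consistent if either the propensity or the outcome model
(m̂ together with τ̂) is correct. Standard errors use the weighted
influence-function form sd_w(Γ̂)/√n_eff with the Kish effective sample size
n_eff = (Σw)²/Σw²; weights are treated as frequency weights everywhere
(with integer weights every estimator equals its unweighted counterpart on
the row-replicated data, which the tests exploit as an oracle). Propensities
are clipped to [0.01, 0.99] with logging; the shipped scenarios never
trigger the clip.

## Heterogeneity summaries

* **Sorted GATEs.** Rows are ranked by τ̂ into weighted quintiles (stable
  original-order tie-breaking; each row is placed by the midpoint of its
  weight interval, so shares are equal up to tie mass and invariant to weight
  rescaling; identical τ̂ everywhere collapses to Q1 with a warning).
  Quintile GATEs are weighted means of Γ̂ and reaggregate exactly to the
  overall ATE.
* **Romano–Wolf tests.** Contrasts Qk − Q1 (k = 2..5) are studentised; the
  null distribution comes from a pairs bootstrap resampling rows with
  replacement within quintiles, re-centred at the observed contrasts
  (B = 1000 by default, ≥ 200 required, seeded). Both unadjusted and
  stepdown-adjusted p-values are bootstrap-based, so adjusted ≥ unadjusted
  holds by construction, the single-contrast case reduces to the unadjusted
  test, and family-wise error control under the global null is verified by
  simulation. A normal-approximation p-value is reported alongside.
* **Classification analysis.** Per covariate and quintile: weighted mean,
  SE, and the normalised distance |quintile mean − overall mean| / overall
  SD (the heatmap colour scale). Covariates are ranked by |SMD(Q1 vs Q5)|;
  zero-variance covariates are excluded from the ranking with a note. The
  top five become the data-driven effect modifiers.
* **Subgroup GATEs.** Weighted mean of Γ̂ within levels of each modifier;
  continuous modifiers are dichotomised at the weighted median by default,
  with age-band (<25, 25–49, 50–64, 65–74, 75+) and custom-cutpoint rules
  available; empty levels are skipped with a warning.
* **BLP.** Weighted OLS of Γ̂ on selected regressors (continuous ones
  dichotomised for interpretation). HC1 robust standard errors are the
  default display — DR scores are heteroskedastic by construction — with
  conventional OLS standard errors reported alongside. The intercept-only
  projection equals the AIPTW ATE exactly.

## Synthetic data and what it does (not) show

The generator emulates a national household survey evaluating subsidised
insurance: ~24 covariates in blocks (age, top-coded per-capita expenditure,
urban indicator, ten socioeconomic binaries at survey-like rates, a
7-category region one-hot, four healthcare-access indicators correlated with
urbanicity and region), a logistic propensity depending on age, expenditure,
education, region and access (empirical range ≈ 0.12–0.86, asserted inside
(0.01, 0.99)), and a hurdle outcome: Bernoulli participation (≈ 27%, i.e.
~73% zeros) times a zero-truncated Poisson count (a negative-binomial option
with fixed dispersion sits behind `consumption_family="ztnb"`). One master
seed fans out into named substreams (covariates / treatment / participation /
consumption / weights), and outcome uniforms are arm-independent, so flipping
D changes outcomes only through the effect terms — counterfactual coherence
the tests verify directly.

Ground truth is analytic: m1(d) by the logistic formula, m2(d) =
λ_d/(1−e^(−λ_d)) (truncated-Poisson mean), and τ(x) by composition. Effect
terms act on the participation logit and consumption log-mean; in addition a
*target-calibrated* consumption effect solves, row by row, for the treated
truncated mean that makes the two-part contrast equal a prescribed linear
function exactly. Shipped scenarios:

* `paper_like` — constant positive effects on both components; the
  participation ATE (~0.03) is an order of magnitude below the consumption
  ATE (~0.8), echoing the empirical pattern that insurance moves intensity
  more than uptake;
* `heterogeneous` — two-part effect exactly 0.5 + 1.0·urban +
  0.015·(age−30), driven by the supply-side urban/rural divide and age;
* `homogeneous` — constant two-part effect (GATE calibration);
* `null` — no effect anywhere, confounding retained.

Default scenario sizes are n = 2 000 (Monte-Carlo replicates) and n = 20 000
(single-run recovery); the test suite and acceptance script use 20–200-tree
forests and the lean two-member learner library at these sizes so everything
runs on one CPU in minutes. Passing tests demonstrate internal correctness
and recovery under the generator's assumptions — parametric hurdle outcomes,
exact unconfoundedness, independent rows. They do not certify performance
under real-survey features the generator omits: sampling design (strata,
PSUs), measurement error, within-household outcome correlation, covariate
missingness, or outcome families outside the (truncated) Poisson /
negative-binomial class.

## Numerical choices and degenerate inputs

* Binary-task predictions are clipped to [1e−12, 1−1e−12] inside the log
  loss; propensities to [0.01, 0.99] in all weighting/scoring (logged).
* Collinear metalearner or BLP designs fall back to minimum-norm
  (pseudoinverse) solutions with a warning.
* Consumption log-means are clipped at ±8 (logged) to guard overflow.
* A node with zero treatment-residual variance is unsplittable; a subsample
  lacking either arm yields a stump tree; a fold lacking either arm raises a
  hard error advising a larger sample.
* Zero pooled variance makes the SMD 0 when the group means agree and ∞
  otherwise.
* The truncated-Poisson mean inverse uses a safeguarded Newton iteration
  (monotone objective, derivative bounded away from 0; ~60 iterations,
  tolerance 1e−12).

## Known limitations

* No confidence intervals for individual τ̂(x) (inference runs through the
  DR scores, not forest-level variance estimates).
* Cross-fitting topology is fixed at three folds by default; the fold count
  is configurable but untested beyond small deviations.
* The classification heatmap's "normalised distance" uses the overall SD as
  the scale — one reasonable reading of the convention, stated here because
  alternatives (pooled within-quintile SD) exist.
* Survey-design variance (strata/PSU) is out of scope; weights are
  frequency weights only.
* At desk scale (n = 2 000, 50-tree forests) the null-scenario 95% CI covers
  zero in roughly 88–92% of 50-replicate batches: the influence-function SE
  ignores nuisance/CATE estimation noise, which is only asymptotically
  negligible. Coverage tightens with n and forest size.
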