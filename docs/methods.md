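# Methods

## The selection model

Each base method *i* assigns a raw importance `F_ij >= 0` to feature *j*.
Signed scores (Pearson correlations, lasso coefficients) enter as
magnitudes: min-max normalisation over signed values would push strongly
anticorrelated features to the bottom of a method's ranking, which is the
opposite of their predictive value. After per-method min-max normalisation
`F~_ij in [0, 1]`, the weighted total score is

    WTS_j = sum_i W_i * exp(F~_ij),   W_i >= 0,  sum_i W_i = 1,

so `WTS_j in [1, e]` with equality at 1 iff every positively-weighted
method gave feature *j* its row minimum, and at `e` iff every such method
gave it its row maximum. A constant importance row carries no ranking
information; it is normalised to all zeros (a uniform `W_i * 1`
contribution that cannot change the ordering) and a warning is emitted.
WTS ties are broken by original column order — a stable sort — so
selections are bitwise reproducible.

## Base scorers

- **Pearson** — `|r(x_j, y)|`. Affine-invariant up to sign.
- **Distance correlation** — the biased V-statistic estimator from
  double-centred pairwise distance matrices, O(n²) per feature. Detects
  arbitrary dependence; exactly zero only under independence (in the
  population).
- **Lasso** — `|coef|` at a penalty chosen by seeded 5-fold
  cross-validation over a 50-point alpha grid, on standardised features.
  One penalty, not a path aggregate: the cross-validated point is the
  penalty a practitioner would actually fit at, and it keeps the score a
  single well-defined magnitude per feature.
- **Random-forest permutation importance** — 100 trees, 10 permutation
  repeats on the full fit, fixed seed; negative importances (feature no
  better than shuffled noise) are clipped to 0 so the row minimum stays
  meaningful for normalisation.
- **Stability selection** — 100 half-subsamples; the score is the fraction
  of subsamples in which the feature's lasso coefficient is nonzero. The
  penalty is chosen once on the full data by cross-validation and reused
  across subsamples; re-running CV inside every subsample adds two orders
  of magnitude of fitting work for little change in the selection
  frequencies on data of this size. Frequencies are used directly as
  continuous scores — no hard selection threshold — so the method yields a
  row comparable to the other four.

## The weight / feature-count search

The simplex is discretised with step `delta` (`1/delta` must be an
integer), so every weight vector is an integer vector of delta units. For
each `k` in `k_range` the search starts at the lattice point closest to
equal weights (exactly equal when the method count divides `1/delta`;
otherwise remainder units go to the earliest methods) and repeatedly takes
the best strictly-improving move among all single-unit transfers between
two methods, stopping at a local optimum or after `max_iter` accepted
moves. Optional seeded random restarts (`n_restarts`) guard against local
optima on larger lattices. An exhaustive mode enumerates the entire
lattice and serves as the oracle in tests.

A candidate `(W, k)` is scored by the cross-validated performance of the
WTS-top-k subset: seeded `cv_folds`-fold CV of ordinary least squares on
min-max-scaled features and (by default) min-max-scaled target. Scaling is
global, before the folds, consistent with the global normalisation used
for the scores; a config switch disables target scaling. Out-of-fold
predictions give MSE, RMSE, MAE, R² and explained variance. Candidates are
ordered by (MSE ascending, R² descending, k ascending, lexicographically
smallest weights) — a total preorder, so the winner is unique and the
whole search is deterministic under a fixed seed. Because many weight
vectors induce the same top-k subset, evaluations are memoized under the
sorted-feature-name key; cached and uncached runs return identical
results.

Since the equal-weight point is the start of every climb, the returned
result is never worse than the equal-weight baseline at any `k` — the
dominance the comparison tables rely on is structural, not empirical.

Defaults: `delta = 0.1`, `max_iter = 1000`, `k_range = [1, p]`,
`cv_folds = 5`, `seed = 0`, `n_restarts = 0`.

## Multicollinearity screening

`VIF_j = 1 / (1 - R²_j)` with `R²_j` from OLS of feature *j* on the other
subset features plus intercept. Perfect collinearity reports `inf` rather
than raising, so the pruning loop can dispose of it. Pruning removes the
current maximum-VIF feature (ties to the earliest column) and recomputes
after every removal, stopping when all survivors are at or below the
threshold (default 10, the conventional rule of thumb) or one feature
remains. Automating the removal replaces a manual judgement call with a
reproducible rule. VIF is invariant to affine rescaling of columns, so it
is computed on the data as loaded.

## Causal stage

**Ordering.** Under a linear acyclic model `x = Bx + e` with non-Gaussian
independent noises, an exogenous variable is independent of the residuals
of every other variable regressed on it, while a downstream variable is
not. The ordering procedure standardises the variables, then repeatedly
extracts the candidate minimising the summed distance correlation between
itself and those residuals, replaces the remaining variables by their
residuals, and recurses (ties to the earlier column). Distance correlation
is used as the independence measure because it detects dependence of any
form and is already part of the scoring module. With Gaussian noise the
direction is unidentifiable and the ordering degenerates to a coin flip —
the non-Gaussianity assumption is essential.

**Edges.** Each variable is regressed by OLS on all its predecessors in
the order; edges with two-sided Wald p < alpha (default 0.05, the usual
significance convention) keep their coefficients. The result is strictly
triangular under the order, hence acyclic by construction.

**Path tests.** The DAG implies a recursive linear path model. For a
recursive model with independent residuals and a saturated covariance
block among the exogenous variables, the Gaussian ML point estimates
coincide with per-equation OLS, so estimation is analytic — no iterative
optimiser. Standard errors come from the expected Fisher information of
the implied covariance `Sigma(theta) = (I-B)^-1 Psi (I-B)^-T` evaluated at
the estimate (information scaled by n). This matters: the expected
information evaluates predictor covariances at their *model-implied*
values, so when an endogenous predictor's sample correlation with the
other predictors exceeds what the model implies, ML standard errors are
smaller than OLS ones, and the z-values differ accordingly. Reported per
path: estimate, SE, `z = estimate/SE`, and `p = 2(1 - Phi(|z|))`.
Variables are min-max scaled before fitting by default; z-values are
invariant to per-variable affine rescaling (tested), so the scaling
convention does not affect significance. A path whose residual variance is
numerically zero (e.g. `y` an exact copy of `x`) makes the model singular
and raises rather than returning an infinite z.

## Synthetic data

`gen_regression` draws equicorrelated standard-normal features (pairwise
correlation `feature_correlation`) and a linear target with the requested
effect sizes and Gaussian noise. `gen_lingam` simulates `x = Bx + e` in
topological order with uniform or Laplace noise (standardised to the
requested scales), optionally permuting columns so recovery studies cannot
lean on column order; it returns the ground-truth order and coefficient
matrix. `gen_wdlike` emulates the shape of a small wearable-device study:
150 samples, 16 daily indicators including a near-duplicate step pair
(r ≈ 0.95) and a composite sleep-duration structure, and a bounded 1–10
wellness-score target loading on wake-up counts, stress, steps, breathing
quality and sleep duration.

What the generators do not emulate: repeated measures within participants,
missing values, measurement drift, heavy-tailed targets, or any real
physiological coupling between indicators. Passing tests therefore
demonstrate correctness of the algorithms under their stated assumptions,
not performance on real wearable data.

All generators are bitwise deterministic under a fixed seed.

The diabetes loader returns the 442-patient open diabetes-progression
table (age, sex, BMI, ABP, TC, LDL, HDL, TCH, LTG, GLU, Target), either
from the copy bundled with scikit-learn or from the whitespace-delimited
archive file, with columns renamed to the clinical labels.

## Problem sizes used in the checks

The acceptance script and test suite use: 1000 randomized tables for the
WTS bound; ten synthetic datasets (n = 150, p = 8, five methods,
delta = 0.2) for the optimiser-vs-baseline comparison; six fixtures
(2–3 methods, delta in {0.5, 0.25}) for greedy-vs-exhaustive agreement; 50
replicates of a 3-variable uniform-noise chain at n = 2000 for ordering
recovery and five replicates at n = 5000 for edge-coefficient RMSE. These
sizes give stable Monte-Carlo estimates while keeping a full run to a few
minutes on one core.

## Numerical choices and edge cases

- Weight-simplex tolerance: `|sum W - 1| <= 1e-9`; lattice arithmetic is
  integer internally to avoid float drift.
- Constant columns: scorers and the Spearman/VIF routines raise with the
  column name; the normaliser warns and zeroes constant rows.
- Perfect fits: `evaluate_subset` returns MSE exactly 0; VIF returns
  `inf`; the path fitter raises `SingularModelError`.
- Tie-breaks everywhere default to original column order, for
  reproducibility.

## Limitations

- The evaluation model inside the weight search is linear; features whose
  value is purely interactive or nonlinear can score well on the forest
  row yet be discarded at evaluation time.
- Greedy search guarantees only a local optimum on the lattice for more
  than a handful of methods; the exhaustive mode is exact but exponential
  in the method count.
- The causal stage assumes linearity, acyclicity, no latent confounders
  and non-Gaussian noise; violations silently bias the order and the
  coefficients. Path-model standard errors are normal-theory.
- Stability selection's single shared penalty slightly smooths selection
  frequencies relative to per-subsample tuning.
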