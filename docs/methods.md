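# Methods

This note documents the models, the synthetic data design, the numerical
choices and the limitations of `aquadiag`.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The slime-mould optimizer

The optimizer minimizes a black-box objective over an axis-aligned box.
Its state is a population of `N` positions with fitness `f(X_i)`; the
incumbent best `X*` is tracked elitistically (ties broken by lowest
index) and never lost.

*Dynamic weights.*  Fitness is min–max normalized per iteration.  The
normalization direction matters: the weighting is meant to give *better*
solutions larger weights, and since the pipeline's fitness is an error
(RMSE, to be minimized), the default maps the lowest fitness to 1
(`(max − f)/(max − f_min)`); the literal ascending form is available via
`direction="maximize"`.  When all fitness values are equal the
normalization degenerates to all-ones, which keeps the weight
denominator positive.  Weights are `w_i = λ·f̃_i/Σf̃_j` with λ decaying
linearly from `λ_max` to `λ_min`; they sum to λ(t) exactly and this
invariant is asserted per iteration in the tests.  Candidates whose
objective call fails or returns a non-finite value are assigned `+inf`
fitness, receive normalized fitness 0 (hence the smallest weights), and
the run continues.

*Adaptive search.*  Step size α and shape parameters β, γ decay linearly
(defaults α: 1→0.1, β: 1→0.5, γ: 1→0.5 over `T = 100` iterations;
population 50).  The position update
`x' = x + α·sgn(d)·(|d|·β)^γ`, `d = X* − x`, is applied elementwise with
`sgn(0) := 0`, making a population collapsed onto the best a fixed
point; results are clipped to the box (clipping rather than reflection
preserves that fixed-point property).  λ's bounds are not part of the
reference parameter table; they mirror α's `[0.1, 1]` span.

*Role of the weights.*  The position update itself does not consume the
weights; they drive a diversity step instead: each iteration the
`ceil(0.1·N)` lowest-weight individuals are re-seeded uniformly in the
box.  Without this the update is purely contractive and the search
stalls on the first incumbent.

*Known limitation.*  Because the update is deterministic and, early in
the run (α≈β≈γ≈1), moves every individual essentially onto `X*`,
exploration is carried almost entirely by the uniform re-seeds.  On the
2-D/3-D sphere benchmarks the achievable accuracy is therefore roughly
that of a best-of-`restart_fraction·N·T` uniform search plus local
polish.  The convergence study (seeds 0–4) produced worst cases of
6.7e-2 (2-D) and 0.89 (3-D); the frozen test tolerances are 0.2 and 2.0
with a 2–3× margin.  The chaotic swarm, which retains velocity-driven
randomness, reaches ~1e-10 on the same benchmarks (tolerance frozen at
1e-6).

*Early stopping.*  Hard cap `T` plus an optional stall criterion
(improvement < 1e-6 for 20 consecutive iterations), disabled by setting
`patience=None`.

*Ablation toggles.*  `dynamic_weights=False` forces uniform weights
λ/N; `adaptive_search=False` pins α, β, γ at their maxima.  Both are
exposed through the pipeline's ablation arms.

## The chaotic particle swarm

Inertia weight e = 0.7 and learning factors c1 = c2 = 1.5 are
conventional PSO practice (the reference configuration does not specify
them); μ = 4 puts the logistic map in its fully chaotic regime.  Start
points are drawn uniformly from (0.01, 0.99) excluding a 1e-3
neighbourhood of 0.5, whose orbit collapses to 0.  Chaos enters both the
initialization (per-dimension orbits rescaled to the box) and, by
default, the r1/r2 coefficients (`chaos_mode="init_and_coefficients"`;
`init_only` falls back to uniform draws).  Velocities start at zero and
are clamped per dimension to 20% of the box width, which prevents
divergence without constriction factors.

## Gain importance from model dumps

LightGBM trains the ensembles (reference configuration: 100 trees,
learning rate 0.1, max depth 5, subsample and column subsample 0.8; the
reference table's depth 5 is used even though a depth of 4 is also
defensible).  The split-gain formula is implemented independently with
the standard ½ prefactor.  Per-node gradient/hessian sums are recovered
from the dump: the stored node value is the would-be leaf output
`−G/(H+ζ)·lr`, and the stored weight is `H`, so
`G = −value·(H+ζ)/lr`.  ζ is read from the booster's `lambda_l2` when
available (0 by default; when recomputing from a dump that does not
expose it, 1.0 is assumed); LightGBM has no per-leaf penalty, so η
defaults to 0.  Negative computed gains (possible with η > 0) are
floored at 0 so importances stay non-negative.

LightGBM's reported gain importance omits the ½ prefactor; the oracle
cross-check (`verify_library_importance`) therefore compares the
recomputed sums against half the reported values.  Agreement is ~1e-6
relative at ζ = 0; with ζ > 0 the dump's rounded node values limit
agreement to ~1e-2, and the corresponding test uses that looser
tolerance.

Selection uses the share-threshold rule (τ = 0.01 of total gain) by
default, with `top_k` available when an exact feature count is wanted.
Ties break by the table's feature order, and the tuning stage always
evaluates the reference boosting configuration alongside the swarm's
candidates, so the tuned model can never be worse than the default on
the validation set.

## The synthetic generator

The generator stands in for an undeposited year of lake monitoring
data.  What it emulates:

* **Marginals.**  Six parameters inside fixed measurement ranges: pH
  6.5–8.5 (unitless), DO 5–10, permanganate index 1–10, COD 10–50 mg/L.
  The TP range (0.05–0.4 mg/L) and NH₃-N range (0.5–2.0 mg/L) are this
  package's constructions bracketing typical reported lake values, since
  published ranges for these two were not available.
* **Cross-correlations.**  Five specified pairs (pH–DO −0.60,
  pH–permanganate 0.83, permanganate–NH₃N 0.76, permanganate–COD 0.76,
  NH₃N–COD 0.98).  Unspecified entries are completed by
  conditional-independence path products over the specification graph —
  the maximum-entropy completion, which keeps the specified values exact
  and is provably PSD for the default (chordal) graph; eigenvalue
  clipping is the fallback for user-supplied pair sets that remain
  non-PSD.  Zero-filling the unspecified entries and then projecting to
  the nearest correlation matrix was rejected because the projection
  drags the specified pairs far off their values (0.83 → 0.68).
* **Copula correction.**  The latent Gaussian correlations are pre-warped
  with the arcsine map `2·sin(πρ/6)` so that after the Gaussian-CDF →
  affine transform onto the physical ranges the *observed* Pearson
  correlations land on the targets rather than ~2% below them.
* **Temporal structure.**  A stationary AR(1) with common coefficient
  0.6 on a daily grid (a common coefficient preserves the innovation
  cross-correlation at lag 0), plus an annual sinusoid holding 12.5% of
  the latent variance (physical amplitude 0.2× the range, mapped through
  the copula slope at mid-range).  Per-parameter phases are fitted so the
  seasonal components' mutual correlations approximate the target
  matrix; parameters with no specified pair (TP) inherit the phase of
  the most-connected parameter.  The seasonal component is *not*
  compensated out of the latent covariance: it deliberately couples TP
  to the rest of the system through the shared annual cycle (empirical
  TP–permanganate correlation ≈ 0.12), so that all six lag-1 columns
  carry genuine signal for the forecast target.
* **Candidate features.**  Lag-1 values of the six parameters
  (labelled informative) plus 24 seeded standard-normal noise columns;
  target = next-day value of a configured parameter.  The default target
  is the permanganate index, the parameter with the richest correlation
  structure, so the informative labels are as honest as the design
  allows.
* **Corruption protocols.**  `inject_outliers` displaces a seeded random
  fraction of feature entries by ±k×IQR (entries chosen uniformly over
  the whole matrix, count = ⌈fraction × entries⌉, positions logged);
  `inject_noise` adds centred Gaussian noise scaled to a fraction of
  each column's SD.  Both act on the candidate-feature matrix, not the
  target, so the robustness ratios attribute degradation to input
  corruption.  The clean generator defaults to no corruption
  (`outlier_fraction = 0`, `noise_sd = 0`).

What it does **not** emulate: mixed sampling frequencies (everything
lives on one daily grid; `resample_daily` exists for aligning real
mixed-frequency tables by forward-fill), hydrological regime shifts,
station-to-station spatial structure, detection limits/censoring, and
heavy-tailed measurement error.  Tests passing on this generator
demonstrate the pipeline's mechanics and its statistical behaviour under
the stated design — not performance on real lake data.

## Pipeline and evaluation choices

* **Stage order.**  Split boundaries are fixed on the raw timeline
  first (7:2:1 chronological; sizes ⌊0.7n⌋/⌊0.2n⌋/rest, so 1080 →
  756/216/108); the imputer and scaler are fitted on the training block
  only and applied unchanged elsewhere; supervised rows are assigned to
  blocks by their target timestamp.  A mutation test asserts that
  perturbing test-period rows changes no train-fitted statistic.
* **Scaling.**  Median/IQR robust scaling is the default (quantiles via
  linear interpolation between order statistics); z-scoring
  (population SD) is selectable.  The target is scaled with the same
  train-block statistics, so reported RMSE/MAE are in scaled units.
* **Robustness ratios.**  Defined here (no standard formulas exist for
  them): outlier sensitivity = (RMSE_outlier − RMSE_clean)/RMSE_clean;
  noise resistance = 1 − (RMSE_noise − RMSE_clean)/RMSE_clean floored at
  0; overfitting tendency = (RMSE_test − RMSE_train)/RMSE_test floored
  at 0; each averaged over seeds.
* **Cross-validation.**  Blocked (time-contiguous) folds are the
  default, since shuffled folds leak future information in a time
  series; the shuffled mode exists for comparability with conventional
  k-fold protocols.
* **Final refit.**  After tuning, the SVR is refitted on
  train+validation by default (`refit_with_validation`), keeping the
  test block untouched.
* **Fitness caching.**  SVR fitness values are cached keyed on the
  parameter vector rounded to 6 decimals — a pure performance measure
  that cannot change results beyond that rounding.
* **Health thresholds.**  Shipped as an editable YAML
  (`aquadiag/data/default_thresholds.yaml`); illustrative values
  anchored to the measurement ranges.  They are configuration, not
  science.

## Problem sizes used by the test and acceptance suites

Unit tests run on 150–240-row datasets with small optimizer budgets.
The study-scale checks use the full 1080-row design over ten seeds with
reduced optimizer budgets chosen as this package's own evaluation
protocol: C_PSO swarm 6 × 8 iterations for the boosting stage, and ISMA
population 12 × 15 iterations for the SVR in the pipeline-ordering
comparison.  Library defaults remain at the reference configuration
(population 50, 100 iterations).

## Known limitation: share-threshold selection under the default design

With the default conditions (AR coefficient 0.6, daily one-step target)
the informative signal ceiling is roughly R² ≈ 0.45, so boosted trees
spend a large share of their training gain fitting residual noise.
Under the τ = 0.01 share rule this leaves more than six features above
threshold (typically 14–30 across seeds, even after validation-RMSE
tuning), and the gain shares of the weaker informative lags (DO, TP)
overlap those of the strongest noise columns.  The exact six-feature
reduction is therefore not reproduced by the share rule on this
generator; `select_features(..., rule="top_k", 6)` reproduces the count
exactly, and the corresponding statistical expectation is kept as a
deliberately failing test rather than weakened.
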