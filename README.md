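# aquadiag

Water-quality forecasting and aquatic-ecosystem health diagnosis for
river and lake monitoring programmes.  The package combines a
support vector regressor whose hyperparameters are tuned by an improved
slime-mould metaheuristic with a gradient-boosting feature-selection
stage tuned by a chaotic particle swarm, and wraps both in a
leakage-safe time-series pipeline with threshold-based health reporting.
Because real monitoring tables are rarely shareable, a first-class
synthetic generator reproduces the statistical structure of a year of
lake data (correlated parameters, seasonality, persistence) so every
stage can be exercised and tested end to end.

## The methods

**Improved slime-mould optimizer (ISMA).**  A population of candidate
parameter vectors `X_i` searches a bounded box, minimizing a fitness
`f` (here: validation RMSE of the SVR).  Each iteration the fitness
values are min–max normalized so the best solution maps to 1, and each
candidate receives a dynamic weight

    w_i = λ · f̃_i / Σ_j f̃_j ,      λ(t) = λ_max − (λ_max − λ_min)·t/T ,

so the weights always sum to the decaying budget λ.  Candidates move
toward the incumbent best with a sign-guided power-law step

    X_i ← clip( X_i + α·sgn(X* − X_i) · (|X* − X_i|·β)^γ ) ,

where α, β, γ all decay linearly from configured maxima to minima
(α: 1→0.1, β, γ: 1→0.5 by default), shifting the search from coarse
exploration to local refinement.  Since the update is contractive, the
lowest-weight tenth of the population is re-seeded uniformly each
iteration as a diversity mechanism.  The tuned SVR ("ISVR") searches
C ∈ [1e−2, 1e2] and the RBF kernel width r ∈ [1e−4, 10] in log space
and ε ∈ [1e−3, 1] linearly.

**Chaotic particle swarm (C_PSO).**  Standard inertia-weight PSO
(`v ← e·v + c1·r1·(p_i − x) + c2·r2·(g − x)`, `x ← x + v`) whose
randomness is driven by the logistic chaos map `x ← μx(1−x)` with μ = 4:
the initial swarm lies on per-dimension chaotic orbits and r1/r2 are
successive chaotic iterates.  It tunes the boosting stage (number of
trees, learning rate, depth, row/column subsampling).

**Gain-based feature selection.**  LightGBM trains the trees; the
importance accounting is recomputed here independently from the model
dump.  For a split with gradient/hessian sums `G_L, G_R, H_L, H_R`
(parent `G, H`), the gain is

    Gain = ½ ( G_L²/(H_L+ζ) + G_R²/(H_R+ζ) − G²/(H+ζ) ) − η ,

and a feature's importance `I(F)` is the sum of gains over all nodes in
all trees that split on it.  Features holding at least τ = 1% of the
total gain are kept (a `top_k` rule is also provided).  The same engine
doubles as an independent cross-check of the library's reported gain
importances.

**Pipeline.**  Mean imputation and median/IQR robust scaling are fitted
on the training block only; data are split chronologically 7:2:1
(train/validation/test) so no future information reaches the model;
lag-1 features feed a next-day forecast.  The test block yields RMSE,
MAE and R²; corruption protocols report outlier sensitivity
(relative RMSE increase), noise resistance and overfitting tendency;
predictions are screened against per-parameter health thresholds to
produce a warning report.

## Worked example

```python
from aquadiag import (PipelineConfig, ScheduleConfig, SyntheticConfig,
                      run_full_pipeline)

config = PipelineConfig(isma_pop_size=12, isma_schedule=ScheduleConfig(T=15))
bundle, report, health = run_full_pipeline(SyntheticConfig(seed=0), config, seed=0)
print(report.rmse, report.mae, report.r2)
```

prints (seed 0):

```
test RMSE 0.5114  MAE 0.3970  R^2 0.1320
selected 30 features; SVR params C=3.62, r=0.00298, eps=0.0559
health status: warning — 2 of 6 parameters beyond thresholds: TP, COD
```

Metrics are on the robust-scaled target, so an RMSE of 0.51 means the
next-day permanganate-index forecast errs by about half an interquartile
range — against a synthetic series whose one-step-ahead predictable
variance is deliberately limited (AR(1) coefficient 0.6 plus a seasonal
cycle).  The same run with feature selection and tuning disabled (a
plain default-parameter SVR) gives RMSE 0.5407; across ten seeds the
full pipeline averages 0.483 vs. 0.512 for the plain model.

The `examples/` directory has one short script per capability
(optimizers, generator, feature selection, full pipeline,
diagnosis/robustness); each prints its numbers with a line of
interpretation.  A thin CLI mirrors the pipeline:
`aquadiag simulate|train|evaluate|ablate|diagnose --help`.

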