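"""End-to-end water-quality diagnosis pipeline.

Wires the pieces together: robust preprocessing -> chaotic-PSO-tuned
gradient-boosting feature selection -> slime-mould-tuned support vector
regression -> test metrics, robustness ratios, cross-validation, and a
threshold-based ecosystem health report.
"""
from __future__ import annotations

import copy
import logging
import pickle
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from sklearn.svm import SVR

from . import featsel, metrics
from .cpso import SwarmConfig
from .isma import ScheduleConfig, run_isma
from .preprocess import MeanImputer, RobustScaler, SplitSpec, ZScoreScaler, chronological_split
from .searchspace import OptimizationResult, ParameterBox
from .simulate import SyntheticConfig, WaterQualityDataset, generate, inject_noise, inject_outliers

__all__ = [
    "SVRParams", "PipelineConfig", "EvaluationReport", "HealthAssessment",
    "ModelBundle", "DEFAULT_SVR_BOX", "DEFAULT_THRESHOLDS",
    "tune_svr", "run_full_pipeline", "robustness_suite", "kfold_cv",
    "diagnose", "ablation_harness", "load_thresholds",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SVRParams:
    """RBF support vector regression parameters: regularization ``C``,
    kernel width ``r`` (scikit-learn's ``gamma``) and tube width ``epsilon``."""

    C: float = 1.0
    r: float = 0.1
    epsilon: float = 0.1

    def __post_init__(self):
        if self.C <= 0 or self.r <= 0 or self.epsilon < 0:
            raise ValueError("require C > 0, r > 0, epsilon >= 0")

    def build(self) -> SVR:
        return SVR(kernel="rbf", C=self.C, gamma=self.r, epsilon=self.epsilon)


#: SVR tuning box; C and r are searched on a log10 scale.
DEFAULT_SVR_BOX = ParameterBox(
    ("log10_C", "log10_r", "epsilon"),
    [np.log10(0.01), np.log10(1e-4), 1e-3],
    [np.log10(100.0), np.log10(10.0), 1.0],
)

#: Illustrative health thresholds anchored to typical lake measurement
#: ranges; configuration, not science.  ``direction`` says which side of
#: the bound is harmful ("above", "below", or a two-sided "band").
DEFAULT_THRESHOLDS = {
    "pH": {"direction": "band", "bound": [6.5, 8.5]},
    "DO": {"direction": "below", "bound": 5.0},
    "permanganate": {"direction": "above", "bound": 10.0},
    "TP": {"direction": "above", "bound": 0.2},
    "NH3N": {"direction": "above", "bound": 1.5},
    "COD": {"direction": "above", "bound": 30.0},
}


def load_thresholds(path=None) -> dict:
    """Load health thresholds from YAML (package default when no path given)."""
    if path is None:
        from importlib import resources
        with resources.files("aquadiag").joinpath("data/default_thresholds.yaml").open() as fh:
            return yaml.safe_load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh)


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs besides the data and the seed."""

    scaler: str = "robust"                 # "robust" or "zscore"
    feature_selection: bool = True
    selection_rule: str = "share_threshold"
    selection_threshold_or_k: float = 0.01
    refit_with_validation: bool = True
    svr_tuning: bool = True
    dynamic_weights: bool = True
    adaptive_search: bool = True
    split: SplitSpec = field(default_factory=SplitSpec)
    isma_pop_size: int = 50
    isma_schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    isma_restart_fraction: float = 0.1
    swarm_config: SwarmConfig = field(default_factory=lambda: SwarmConfig(swarm_size=6, T=8))
    thresholds: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_THRESHOLDS))

    def snapshot(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class EvaluationReport:
    rmse: float
    mae: float
    r2: float
    rmse_train: float | None = None
    outlier_sensitivity: float | None = None
    noise_resistance: float | None = None
    overfitting_tendency: float | None = None
    folds: list[dict] = field(default_factory=list)
    selected_features: list[str] = field(default_factory=list)
    svr_params: dict = field(default_factory=dict)
    seed: int = 0
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rmse < 0 or self.mae < 0:
            raise ValueError("rmse and mae must be non-negative")
        if self.r2 > 1:
            raise ValueError("r2 cannot exceed 1")


@dataclass
class HealthAssessment:
    """Per-parameter predicted value vs. threshold, plus narrative fields."""

    parameters: dict[str, dict]
    overall_status: str
    current_status: str
    trends: str
    risks: str

    def to_json(self, path=None) -> str:
        import json
        payload = asdict(self)
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=2)
        return json.dumps(payload, indent=2)


def _position_to_svr(x) -> SVRParams:
    return SVRParams(C=10 ** x[0], r=10 ** x[1], epsilon=float(x[2]))


def tune_svr(train: tuple, validation: tuple, box: ParameterBox | None = None,
             pop_size: int = 50, schedule: ScheduleConfig | None = None,
             restart_fraction: float = 0.1, seed: int = 0,
             dynamic_weights: bool = True, adaptive_search: bool = True,
             ) -> tuple[SVRParams, OptimizationResult]:
    """Tune (C, r, epsilon) by slime-mould search on validation RMSE.

    ``train``/``validation`` are ``(X, y)`` pairs of preprocessed arrays.
    C and r are searched in log10 space.  A candidate whose SVR fit fails
    is assigned +inf fitness and the run continues.
    """
    box = box or DEFAULT_SVR_BOX
    X_tr, y_tr = train
    X_va, y_va = validation
    cache: dict[tuple, float] = {}

    def objective(x):
        key = tuple(np.round(x, 6))
        if key not in cache:
            params = _position_to_svr(x)
            model = params.build().fit(X_tr, y_tr)
            cache[key] = metrics.rmse(y_va, model.predict(X_va))
        return cache[key]

    result = run_isma(objective, box, schedule=schedule, pop_size=pop_size,
                      seed=seed, restart_fraction=restart_fraction,
                      dynamic_weights=dynamic_weights,
                      adaptive_search=adaptive_search)
    return _position_to_svr(result.best_position), result


@dataclass
class ModelBundle:
    """Fitted pipeline artefacts; reloadable with bit-identical predictions."""

    imputer: MeanImputer
    scaler: object
    target_scale: tuple[float, float]      # (center, spread) of the target
    selected_features: list[str]
    boosting_params: dict
    svr_params: SVRParams
    svr: SVR
    config: dict
    seed: int

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = self.scaler.transform(self.imputer.transform(features))
        return self.svr.predict(X[self.selected_features].to_numpy())

    def predict_physical(self, features: pd.DataFrame) -> np.ndarray:
        center, spread = self.target_scale
        return self.predict(features) * spread + center

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "ModelBundle":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _prepare(dataset: WaterQualityDataset, config: PipelineConfig):
    """Split on the raw timeline, then fit imputer/scaler on train only."""
    feats, target = dataset.features, dataset.target
    train_f, valid_f, test_f = chronological_split(feats, config.split)

    imputer = MeanImputer().fit(train_f)
    scaler_cls = {"robust": RobustScaler, "zscore": ZScoreScaler}[config.scaler]
    scaler = scaler_cls().fit(imputer.transform(train_f))

    y_train = target.loc[train_f.index]
    if config.scaler == "robust":
        center = float(y_train.median())
        spread = float(y_train.quantile(0.75) - y_train.quantile(0.25))
    else:
        center, spread = float(y_train.mean()), float(y_train.std(ddof=0))
    if not spread > 0:
        raise ValueError("degenerate target: zero spread on the training block")

    def prep(block_f):
        X = scaler.transform(imputer.transform(block_f))
        y = (target.loc[block_f.index] - center) / spread
        return X, y

    return (prep(train_f), prep(valid_f), prep(test_f), imputer, scaler,
            (center, spread))


def run_full_pipeline(data, config: PipelineConfig | None = None, seed: int = 0):
    """Run the whole diagnosis chain on a dataset (or generate one).

    Stages: impute -> scale (fit on train only) -> chronological 7:2:1
    split -> chaotic-PSO-tuned boosting feature selection -> slime-mould
    SVR tuning on the selected features -> final fit (train, plus
    validation when ``refit_with_validation``) -> test metrics ->
    threshold diagnosis.

    Returns ``(ModelBundle, EvaluationReport, HealthAssessment)``.
    """
    config = config or PipelineConfig()
    if isinstance(data, SyntheticConfig):
        dataset = generate(data)
    elif isinstance(data, WaterQualityDataset):
        dataset = data
    else:
        raise TypeError("data must be a WaterQualityDataset or SyntheticConfig")

    train, valid, test, imputer, scaler, target_scale = _prepare(dataset, config)
    (X_tr, y_tr), (X_va, y_va), (X_te, y_te) = train, valid, test

    if config.feature_selection:
        selected, boost_params, _table = featsel.tune_and_select(
            X_tr, y_tr, X_va, y_va, swarm_config=config.swarm_config,
            rule=config.selection_rule,
            threshold_or_k=config.selection_threshold_or_k, seed=seed)
        if not selected:
            logger.warning("selection kept no features; falling back to all")
            selected = list(X_tr.columns)
    else:
        selected, boost_params = list(X_tr.columns), {}

    sub = lambda X: X[selected].to_numpy()
    if config.svr_tuning:
        svr_params, _hist = tune_svr(
            (sub(X_tr), y_tr.to_numpy()), (sub(X_va), y_va.to_numpy()),
            pop_size=config.isma_pop_size, schedule=config.isma_schedule,
            restart_fraction=config.isma_restart_fraction, seed=seed,
            dynamic_weights=config.dynamic_weights,
            adaptive_search=config.adaptive_search)
    else:
        svr_params = SVRParams()

    if config.refit_with_validation:
        X_fit = np.vstack([sub(X_tr), sub(X_va)])
        y_fit = np.concatenate([y_tr.to_numpy(), y_va.to_numpy()])
    else:
        X_fit, y_fit = sub(X_tr), y_tr.to_numpy()
    svr = svr_params.build().fit(X_fit, y_fit)

    yhat_te = svr.predict(sub(X_te))
    yhat_tr = svr.predict(sub(X_tr))
    report = EvaluationReport(
        rmse=metrics.rmse(y_te, yhat_te), mae=metrics.mae(y_te, yhat_te),
        r2=metrics.r2(y_te, yhat_te),
        rmse_train=metrics.rmse(y_tr, yhat_tr),
        overfitting_tendency=metrics.overfitting_tendency(
            metrics.rmse(y_tr, yhat_tr), metrics.rmse(y_te, yhat_te))
        if metrics.rmse(y_te, yhat_te) > 0 else 0.0,
        selected_features=list(selected),
        svr_params=asdict(svr_params), seed=seed, config=config.snapshot())

    bundle = ModelBundle(imputer=imputer, scaler=scaler,
                         target_scale=target_scale,
                         selected_features=list(selected),
                         boosting_params=boost_params, svr_params=svr_params,
                         svr=svr, config=config.snapshot(), seed=seed)

    # diagnosis: forecast for the target parameter, latest observations
    # for the remaining parameters
    last_obs = dataset.core.iloc[-1].to_dict()
    pred_target = float(bundle.predict_physical(dataset.features.iloc[[-1]])[0])
    predictions = {p: (pred_target if p == dataset.config.target_parameter
                       else float(v)) for p, v in last_obs.items()}
    assessment = diagnose(predictions, config.thresholds)
    return bundle, report, assessment


def diagnose(predictions: dict, thresholds: dict) -> HealthAssessment:
    """Threshold screening of per-parameter values.

    A warning is raised when a value crosses its bound in the harmful
    direction: above the bound for oxygen-demand-type parameters, below
    for dissolved oxygen, outside a two-sided band for pH.
    """
    params = {}
    warned = []
    for name, value in predictions.items():
        if name not in thresholds:
            raise KeyError(f"no health threshold configured for {name!r}")
        spec = thresholds[name]
        direction, bound = spec["direction"], spec["bound"]
        if direction == "above":
            warning = value > bound
        elif direction == "below":
            warning = value < bound
        elif direction == "band":
            lo, hi = bound
            warning = not (lo <= value <= hi)
        else:
            raise ValueError(f"unknown threshold direction {direction!r}")
        params[name] = {"value": value, "bound": bound,
                        "direction": direction, "warning": bool(warning)}
        if warning:
            warned.append(name)

    overall = "warning" if warned else "healthy"
    current = (f"{len(warned)} of {len(params)} parameters beyond thresholds: "
               f"{', '.join(warned)}" if warned else
               "all monitored parameters within their healthy ranges")
    trends = "one-step forecast for the target parameter; remaining values are latest observations"
    risks = ("elevated ecological risk from: " + ", ".join(warned)) if warned \
        else "no immediate threshold exceedance detected"
    return HealthAssessment(parameters=params, overall_status=overall,
                            current_status=current, trends=trends, risks=risks)


def robustness_suite(synth_config: SyntheticConfig, config: PipelineConfig | None = None,
                     outlier_fraction: float = 0.05, outlier_magnitude: float = 3.0,
                     noise_sd_fraction: float = 0.1, seeds=(0, 1, 2)) -> dict:
    """Outlier/noise robustness ratios averaged over seeds.

    For each seed the pipeline is trained and tested three times — on the
    clean dataset, with outliers injected into the feature matrix, and
    with Gaussian noise injected — and the degradation ratios are
    computed from the test RMSEs.
    """
    config = config or PipelineConfig()
    sens, res, ovf = [], [], []
    for seed in seeds:
        base = generate(SyntheticConfig(**{**synth_config.__dict__,
                                           "seed": int(seed)}))
        _, clean, _ = run_full_pipeline(base, config, seed=int(seed))
        if clean.rmse <= 0:
            raise ValueError("clean RMSE is zero; robustness ratios undefined")
        with_out = inject_outliers(base, outlier_fraction, outlier_magnitude, int(seed))
        _, rep_out, _ = run_full_pipeline(with_out, config, seed=int(seed))
        with_noise = inject_noise(base, noise_sd_fraction, int(seed))
        _, rep_noise, _ = run_full_pipeline(with_noise, config, seed=int(seed))
        sens.append(metrics.outlier_sensitivity(clean.rmse, rep_out.rmse))
        res.append(metrics.noise_resistance(clean.rmse, rep_noise.rmse))
        ovf.append(clean.overfitting_tendency)
    return {"outlier_sensitivity": float(np.mean(sens)),
            "noise_resistance": float(np.mean(res)),
            "overfitting_tendency": float(np.mean(ovf)),
            "per_seed": {"outlier_sensitivity": sens, "noise_resistance": res,
                         "overfitting_tendency": ovf}}


def kfold_cv(X, y, k: int = 5, mode: str = "blocked", seed: int = 0,
             model_factory=None) -> list[EvaluationReport]:
    """k-fold cross-validation of a regressor (default: reference SVR).

    ``blocked`` folds are time-contiguous chunks preserving order (the
    leakage-safe choice for time series); ``shuffled`` is the classical
    seeded random partition.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    if mode == "blocked":
        folds = np.array_split(np.arange(n), k)
    elif mode == "shuffled":
        perm = np.random.default_rng(seed).permutation(n)
        folds = np.array_split(perm, k)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    factory = model_factory or (lambda: SVRParams().build())
    reports = []
    for i, test_idx in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        model = factory().fit(X[mask], y[mask])
        yhat = model.predict(X[test_idx])
        reports.append(EvaluationReport(
            rmse=metrics.rmse(y[test_idx], yhat),
            mae=metrics.mae(y[test_idx], yhat),
            r2=metrics.r2(y[test_idx], yhat),
            folds=[{"fold": i, "n_test": int(len(test_idx))}], seed=seed))
    return reports


ABLATION_ARMS = ("full", "no_featsel", "no_dynamic_weight",
                 "no_adaptive_search", "plain_svr")


def ablation_harness(arms, synth_config: SyntheticConfig,
                     config: PipelineConfig | None = None,
                     seeds=(0, 1, 2)) -> pd.DataFrame:
    """Component-removal comparison on identical data and seeds.

    Arms: ``full`` (everything on), ``no_featsel`` (all 30 features into
    the SVR), ``no_dynamic_weight`` (uniform slime-mould weights),
    ``no_adaptive_search`` (control parameters pinned at their maxima),
    ``plain_svr`` (reference SVR, no selection, no tuning).  Returns a
    tidy table of per-arm mean metrics.
    """
    base_cfg = config or PipelineConfig()
    for arm in arms:
        if arm not in ABLATION_ARMS:
            raise ValueError(f"unknown ablation arm {arm!r}")
    datasets = {int(s): generate(SyntheticConfig(**{**synth_config.__dict__,
                                                    "seed": int(s)}))
                for s in seeds}
    rows = []
    for arm in arms:
        cfg = copy.deepcopy(base_cfg)
        if arm == "no_featsel":
            cfg.feature_selection = False
        elif arm == "no_dynamic_weight":
            cfg.dynamic_weights = False
        elif arm == "no_adaptive_search":
            cfg.adaptive_search = False
        elif arm == "plain_svr":
            cfg.feature_selection = False
            cfg.svr_tuning = False
        for s, ds in datasets.items():
            _, rep, _ = run_full_pipeline(ds, cfg, seed=s)
            rows.append({"arm": arm, "seed": s, "rmse": rep.rmse,
                         "mae": rep.mae, "r2": rep.r2})
    table = pd.DataFrame(rows)
    return table.groupby("arm", sort=False)[["rmse", "mae", "r2"]].mean().reset_index()
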