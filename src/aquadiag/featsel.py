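"""Gain-based feature importance and selection over a boosted tree ensemble.

Tree *training* is delegated to LightGBM; the importance accounting is
implemented here, independently, from the library's model dump.  For a
split with left/right gradient sums ``G_L, G_R`` and hessian sums
``H_L, H_R`` (parent sums ``G, H``), the split gain is the second-order
improvement

    gain = 1/2 * ( G_L^2/(H_L + zeta) + G_R^2/(H_R + zeta)
                   - G^2/(H + zeta) ) - eta

with an L2 regularizer ``zeta`` and a per-leaf penalty ``eta``.  A
feature's importance is the sum of gains over every node (across all
trees) that splits on it; negative computed gains (possible with
``eta > 0``) are floored at zero so importances stay non-negative.

LightGBM's reported gain importance uses the same expression without the
1/2 prefactor, which makes the library a convenient independent
cross-check: :func:`verify_library_importance` compares this module's
recomputation against half the library's reported gains.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TreeSplit",
    "ImportanceTable",
    "split_gain",
    "feature_importance",
    "booster_splits",
    "importance_from_booster",
    "verify_library_importance",
    "select_features",
    "tune_and_select",
    "DEFAULT_BOOSTER_PARAMS",
    "DEFAULT_TUNING_BOX",
]

#: Reference boosting configuration (fixed point of the tuning stage).
DEFAULT_BOOSTER_PARAMS = {
    "n_estimators": 100,
    "learning_rate": 0.1,
    "max_depth": 5,
    "subsample": 0.8,
    "colsample_bytree": 0.8,
}


@dataclass(frozen=True)
class TreeSplit:
    """Gradient/hessian bookkeeping for one internal node."""

    feature: str
    G_L: float
    G_R: float
    H_L: float
    H_R: float
    zeta: float = 0.0
    eta: float = 0.0

    def __post_init__(self):
        if self.H_L < 0 or self.H_R < 0:
            raise ValueError("hessian sums must be non-negative")
        if self.zeta < 0 or self.eta < 0:
            raise ValueError("zeta and eta must be non-negative")


@dataclass
class ImportanceTable:
    """Per-feature summed split gains over an ensemble of Q trees."""

    scores: dict[str, float]
    Q: int

    @property
    def total_gain(self) -> float:
        return float(sum(self.scores.values()))

    def shares(self) -> dict[str, float]:
        tot = self.total_gain
        if tot <= 0:
            raise ValueError("total gain is zero; shares undefined")
        return {f: s / tot for f, s in self.scores.items()}

    def to_frame(self, selected=None):
        import pandas as pd
        tot = self.total_gain
        rows = sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame({
            "feature": [f for f, _ in rows],
            "gain": [g for _, g in rows],
            "share": [g / tot if tot > 0 else np.nan for _, g in rows],
            "selected": [f in set(selected or []) for f, _ in rows],
        })


def split_gain(split: TreeSplit) -> float:
    """Second-order gain of one split (see module docstring)."""
    G = split.G_L + split.G_R
    H = split.H_L + split.H_R
    if H + split.zeta == 0:
        raise ValueError("H + zeta must be positive")
    return 0.5 * (split.G_L ** 2 / (split.H_L + split.zeta)
                  + split.G_R ** 2 / (split.H_R + split.zeta)
                  - G ** 2 / (H + split.zeta)) - split.eta


def feature_importance(ensemble, features=None) -> ImportanceTable:
    """Sum per-node gains by feature over an ensemble.

    ``ensemble`` is an iterable of trees, each an iterable of
    :class:`TreeSplit`.  Features listed in ``features`` but never split
    on score 0.  Negative node gains are floored at 0.
    """
    scores: dict[str, float] = {f: 0.0 for f in (features or [])}
    Q = 0
    for tree in ensemble:
        Q += 1
        for node in tree:
            scores[node.feature] = scores.get(node.feature, 0.0) \
                + max(0.0, split_gain(node))
    return ImportanceTable(scores=scores, Q=Q)


def _node_gh(node: dict, zeta: float, learning_rate: float):
    """Recover (G, H) for a dump node.

    LightGBM stores the would-be leaf output ``-G/(H + zeta) * lr`` as
    ``leaf_value``/``internal_value`` and the hessian sum as
    ``leaf_weight``/``internal_weight``.
    """
    if "split_feature" in node:
        value, weight = node["internal_value"], node["internal_weight"]
    else:
        value, weight = node["leaf_value"], node["leaf_weight"]
    H = float(weight)
    G = -float(value) * (H + zeta) / learning_rate
    return G, H


def _as_booster(model):
    """Accept either a raw LightGBM Booster or the sklearn wrapper."""
    return getattr(model, "booster_", model)


def booster_splits(booster, eta: float = 0.0) -> list[list[TreeSplit]]:
    """Parse a LightGBM booster dump into per-tree :class:`TreeSplit` lists.

    ``zeta`` is taken from the booster's ``lambda_l2``/``reg_lambda``
    parameter when available, else 0.
    """
    booster = _as_booster(booster)
    try:
        dump = booster.dump_model()
    except Exception as exc:  # pragma: no cover - undumpable model
        raise ValueError(f"could not dump booster: {exc}") from exc
    params = getattr(booster, "params", {}) or {}
    zeta = float(params.get("lambda_l2", params.get("reg_lambda", 0.0)) or 0.0)
    lr = float(params.get("learning_rate", 0.1) or 0.1)
    names = dump["feature_names"]

    trees: list[list[TreeSplit]] = []
    for tree in dump["tree_info"]:
        nodes: list[TreeSplit] = []

        def walk(node):
            if "split_feature" not in node:
                return
            GL, HL = _node_gh(node["left_child"], zeta, lr)
            GR, HR = _node_gh(node["right_child"], zeta, lr)
            nodes.append(TreeSplit(feature=names[node["split_feature"]],
                                   G_L=GL, G_R=GR, H_L=HL, H_R=HR,
                                   zeta=zeta, eta=eta))
            walk(node["left_child"])
            walk(node["right_child"])

        walk(tree["tree_structure"])
        trees.append(nodes)
    return trees


def importance_from_booster(booster, eta: float = 0.0) -> ImportanceTable:
    """This package's gain-importance accounting applied to a trained booster."""
    booster = _as_booster(booster)
    dump_names = booster.dump_model()["feature_names"]
    return feature_importance(booster_splits(booster, eta=eta), features=dump_names)


def verify_library_importance(booster, tolerance: float = 5e-3) -> dict:
    """Cross-check the recomputed importances against the library's.

    Compares this module's per-feature sums (with the 1/2 prefactor)
    against half of LightGBM's reported gain importances.  Returns a
    report with per-feature relative deviations and a pass flag.
    """
    booster = _as_booster(booster)
    table = importance_from_booster(booster)
    reported = dict(zip(booster.dump_model()["feature_names"],
                        booster.feature_importance(importance_type="gain")))
    deviations = {}
    for f, lib_gain in reported.items():
        ours = table.scores.get(f, 0.0)
        ref = lib_gain / 2.0
        if ref == 0.0:
            deviations[f] = abs(ours)
        else:
            deviations[f] = abs(ours - ref) / ref
    max_dev = max(deviations.values()) if deviations else 0.0
    return {"deviations": deviations, "max_relative_deviation": max_dev,
            "passed": max_dev <= tolerance, "tolerance": tolerance}


def select_features(table: ImportanceTable, rule: str = "share_threshold",
                    threshold_or_k=0.01) -> list[str]:
    """Reduce the candidate set by importance.

    ``share_threshold`` keeps features whose share of the total gain is at
    least ``tau`` (default 0.01); ``top_k`` keeps the ``k`` highest.
    Output is ordered by descending importance with ties broken by
    feature name order in the table.
    """
    order = sorted(table.scores, key=lambda f: (-table.scores[f],
                                                list(table.scores).index(f)))
    if rule == "share_threshold":
        tot = table.total_gain
        if tot <= 0:
            raise ValueError("total gain is zero; share threshold undefined")
        return [f for f in order if table.scores[f] / tot >= threshold_or_k]
    if rule == "top_k":
        k = int(threshold_or_k)
        if k > len(order):
            raise ValueError(f"k={k} exceeds the {len(order)} available features")
        return order[:k]
    raise ValueError(f"unknown selection rule {rule!r}")


#: Hyperparameter search box for the boosting stage (integer dimensions
#: are rounded at evaluation time).
DEFAULT_TUNING_BOX = {
    "n_estimators": (50, 300),
    "learning_rate": (0.01, 0.3),
    "max_depth": (3, 6),
    "subsample": (0.5, 1.0),
    "colsample_bytree": (0.5, 1.0),
}


def _position_to_params(x, names):
    params = {}
    for name, val in zip(names, x):
        params[name] = int(round(val)) if name in ("n_estimators", "max_depth") \
            else float(val)
    return params


def _fit_booster(params: dict, X_train, y_train, seed: int):
    import lightgbm as lgb
    return lgb.LGBMRegressor(
        subsample_freq=1, random_state=seed, verbose=-1,
        deterministic=True, force_row_wise=True, n_jobs=1,
        **params,
    ).fit(X_train, y_train)


def tune_and_select(X_train, y_train, X_valid, y_valid,
                    swarm_config=None, rule: str = "share_threshold",
                    threshold_or_k=0.01, seed: int = 0,
                    box: dict | None = None):
    """Chaotic-PSO tuning of the boosting stage, then importance selection.

    The swarm minimizes validation RMSE of the boosted regressor over the
    hyperparameter box; the reference configuration
    (:data:`DEFAULT_BOOSTER_PARAMS`) is always evaluated as well and wins
    if the search does not improve on it.  The best model's recomputed
    :class:`ImportanceTable` drives :func:`select_features`.

    Returns ``(selected_features, tuned_params, importance_table)``.
    """
    from .cpso import SwarmConfig, run_cpso
    from .metrics import rmse
    from .searchspace import ParameterBox

    box = box or DEFAULT_TUNING_BOX
    names = list(box)
    pbox = ParameterBox(names, [box[n][0] for n in names],
                        [box[n][1] for n in names])
    cfg = swarm_config or SwarmConfig(swarm_size=6, T=8)

    def objective(x):
        params = _position_to_params(x, names)
        model = _fit_booster(params, X_train, y_train, seed)
        return rmse(y_valid, model.predict(X_valid))

    result = run_cpso(objective, pbox, cfg, seed=seed)
    tuned = _position_to_params(result.best_position, names)

    default = {k: v for k, v in DEFAULT_BOOSTER_PARAMS.items() if k in box}
    default_model = _fit_booster(default, X_train, y_train, seed)
    default_rmse = rmse(y_valid, default_model.predict(X_valid))
    if default_rmse <= result.best_fitness:
        tuned, model = default, default_model
    else:
        model = _fit_booster(tuned, X_train, y_train, seed)

    table = importance_from_booster(model.booster_)
    return select_features(table, rule, threshold_or_k), tuned, table
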