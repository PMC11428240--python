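"""Model families, split, cross-validation, metrics, and benchmarking.

Six regression families are exposed behind one uniform interface: elastic
net (EN), multilayer perceptron (ANN), random forest (RF), and three
gradient-boosting variants named XGBoost, LightGBM and CatBoost after the
libraries whose hyperparameter spaces they carry.  In this package the
three boosting families are backed by scikit-learn gradient-boosting
estimators (``GradientBoostingRegressor`` / ``HistGradientBoostingRegressor``)
so the pipeline has no compiled third-party dependencies; hyperparameters
are validated against the published ranges, and any dimension with no
scikit-learn counterpart is accepted but unmapped (documented per family).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (
    GradientBoostingRegressor,
    HistGradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .featuresets import FeatureSetSpec, materialize
from .gwo import Dim, SearchSpace

logger = logging.getLogger(__name__)

__all__ = [
    "FAMILIES",
    "SplitConfig",
    "EvalResult",
    "family_space",
    "default_params",
    "validate_params",
    "build_estimator",
    "split_train_test",
    "metrics",
    "cv_rmse",
    "train_model",
    "benchmark",
    "aggregate_by_set",
    "paired_t",
]

FAMILIES = ("EN", "ANN", "RF", "XGBoost", "LightGBM", "CatBoost")

_SPACES: dict[str, SearchSpace] = {
    "EN": SearchSpace((
        Dim("alpha", "log-continuous", (0.0001, 10.0)),
        Dim("l1_ratio", "continuous", (0.0001, 1.0)),
    )),
    "ANN": SearchSpace((
        Dim("max_iter", "integer", (200, 1000)),
        Dim("learning_rate_init", "log-continuous", (0.001, 0.1)),
        Dim("alpha", "log-continuous", (0.0001, 10.0)),
        Dim("activation", "categorical", options=("relu", "tanh")),
        Dim("hidden_layer_sizes", "categorical", options=((100,), (100, 50))),
    )),
    "RF": SearchSpace((
        Dim("n_estimators", "integer", (100, 1000)),
        Dim("max_depth", "integer", (3, 10)),
        Dim("min_samples_split", "continuous", (0.002, 0.2)),
        Dim("min_samples_leaf", "continuous", (0.001, 0.1)),
        Dim("max_features", "categorical", options=("sqrt", "log2")),
    )),
    "XGBoost": SearchSpace((
        Dim("n_estimators", "integer", (100, 1000)),
        Dim("learning_rate", "log-continuous", (0.01, 0.2)),
        Dim("subsample", "continuous", (0.1, 1.0)),
        Dim("reg_alpha", "log-continuous", (0.01, 10.0)),
        Dim("reg_lambda", "log-continuous", (0.01, 10.0)),
    )),
    "LightGBM": SearchSpace((
        Dim("num_iteration", "integer", (100, 1000)),
        Dim("learning_rate", "log-continuous", (0.01, 0.2)),
        Dim("bagging_fraction", "continuous", (0.1, 1.0)),
        Dim("lambda_l1", "log-continuous", (0.01, 10.0)),
        Dim("lambda_l2", "log-continuous", (0.01, 10.0)),
    )),
    "CatBoost": SearchSpace((
        Dim("iterations", "integer", (100, 1000)),
        Dim("learning_rate", "log-continuous", (0.01, 0.2)),
        Dim("l2_leaf_reg", "log-continuous", (0.01, 10.0)),
        Dim("subsample", "continuous", (0.1, 1.0)),
        Dim("depth", "integer", (3, 10)),
    )),
}


def family_space(family: str) -> SearchSpace:
    if family not in _SPACES:
        raise ValueError(f"unknown model family {family!r}; choose from {FAMILIES}")
    return _SPACES[family]


def default_params(family: str) -> dict:
    """Midpoint of each range (geometric midpoint for log dims); first
    option for categoricals."""
    space = family_space(family)
    out = {}
    for d in space.dims:
        if d.kind == "categorical":
            out[d.name] = d.options[0]
        else:
            out[d.name] = d.decode(0.5)
    return out


def validate_params(family: str, params: dict) -> None:
    family_space(family).validate(params)


def build_estimator(family: str, params: dict, seed: int = 0):
    """Instantiate a fitted-interface estimator for one family.

    Unmapped dimensions (validated but without a scikit-learn counterpart):
    XGBoost's reg_alpha/reg_lambda, LightGBM's bagging_fraction/lambda_l1,
    CatBoost's subsample.
    """
    validate_params(family, params)
    # the two scale-sensitive families get an input standardizer; tree
    # ensembles are scale-invariant and run on raw features
    if family == "EN":
        return make_pipeline(
            StandardScaler(),
            ElasticNet(
                alpha=params["alpha"], l1_ratio=params["l1_ratio"],
                max_iter=10000, random_state=seed,
            ),
        )
    if family == "ANN":
        return make_pipeline(
            StandardScaler(),
            MLPRegressor(
                max_iter=int(params["max_iter"]),
                learning_rate_init=params["learning_rate_init"],
                alpha=params["alpha"],
                activation=params["activation"],
                hidden_layer_sizes=tuple(params["hidden_layer_sizes"]),
                random_state=seed,
            ),
        )
    if family == "RF":
        return RandomForestRegressor(
            n_estimators=int(params["n_estimators"]),
            max_depth=int(params["max_depth"]),
            min_samples_split=params["min_samples_split"],
            min_samples_leaf=params["min_samples_leaf"],
            max_features=params["max_features"],
            random_state=seed,
            n_jobs=1,
        )
    if family == "XGBoost":
        return GradientBoostingRegressor(
            n_estimators=int(params["n_estimators"]),
            learning_rate=params["learning_rate"],
            subsample=params["subsample"],
            random_state=seed,
        )
    if family == "LightGBM":
        return HistGradientBoostingRegressor(
            max_iter=int(params["num_iteration"]),
            learning_rate=params["learning_rate"],
            l2_regularization=params["lambda_l2"],
            random_state=seed,
        )
    if family == "CatBoost":
        return HistGradientBoostingRegressor(
            max_iter=int(params["iterations"]),
            learning_rate=params["learning_rate"],
            l2_regularization=params["l2_leaf_reg"],
            max_depth=int(params["depth"]),
            random_state=seed,
        )
    raise ValueError(f"unknown model family {family!r}")


@dataclass
class SplitConfig:
    test_fraction: float = 0.2
    n_folds: int = 5
    shuffle: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class EvalResult:
    model_family: str
    feature_set: str
    split: str  # train | test | cv
    r2: float
    mae: float
    rmse: float

    def __post_init__(self) -> None:
        if self.split not in ("train", "test", "cv"):
            raise ValueError(f"unknown split {self.split!r}")


def split_train_test(X, y, config: SplitConfig):
    """Deterministic shuffled row split; test size = round(n * fraction)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if len(X) != n:
        raise ValueError("X and y must be row-aligned")
    if n < config.n_folds:
        raise ValueError(f"need at least n_folds={config.n_folds} rows, got {n}")
    n_test = int(round(n * config.test_fraction))
    if config.shuffle:
        perm = np.random.default_rng(config.seed).permutation(n)
    else:
        perm = np.arange(n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    if isinstance(X, pd.DataFrame):
        X_tr, X_te = X.iloc[train_idx], X.iloc[test_idx]
    else:
        X = np.asarray(X)
        X_tr, X_te = X[train_idx], X[test_idx]
    return X_tr, X_te, y[train_idx], y[test_idx]


def metrics(y_true, y_pred) -> tuple[float, float, float]:
    """(r2, mae, rmse).  r2 is NaN (with a warning) for zero-variance y_true."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must have equal non-zero length")
    resid = y_true - y_pred
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        logger.warning("zero variance in y_true; r2 undefined")
        return float("nan"), mae, rmse
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return r2, mae, rmse


def _fit(est, X, y):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence warnings at low max_iter
        est.fit(X, y)
    return est


def cv_rmse(family: str, params: dict, X, y, config: SplitConfig) -> float:
    """Mean RMSE over k held-out folds (the hyperparameter-search fitness)."""
    kf = KFold(n_splits=config.n_folds, shuffle=config.shuffle, random_state=config.seed)
    X_arr = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y, dtype=float)
    scores = []
    for tr, te in kf.split(X_arr):
        est = build_estimator(family, params, seed=config.seed)
        _fit(est, X_arr[tr], y[tr])
        _, _, rmse = metrics(y[te], est.predict(X_arr[te]))
        scores.append(rmse)
    return float(np.mean(scores))


def train_model(family: str, params: dict, X_train, y_train, config: SplitConfig):
    """Fit on the training data; return (fitted estimator, cv EvalResult).

    The cv result is the mean over folds of held-out r2/mae/rmse.
    """
    kf = KFold(n_splits=config.n_folds, shuffle=config.shuffle, random_state=config.seed)
    X_arr = X_train.to_numpy(float) if isinstance(X_train, pd.DataFrame) else np.asarray(X_train, float)
    y_train = np.asarray(y_train, dtype=float)
    fold_scores = []
    for tr, te in kf.split(X_arr):
        est = build_estimator(family, params, seed=config.seed)
        _fit(est, X_arr[tr], y_train[tr])
        fold_scores.append(metrics(y_train[te], est.predict(X_arr[te])))
    r2, mae, rmse = (float(np.mean([s[i] for s in fold_scores])) for i in range(3))
    model = _fit(build_estimator(family, params, seed=config.seed), X_arr, y_train)
    feature_set = getattr(X_train, "attrs", {}).get("feature_set", "")
    return model, EvalResult(family, feature_set, "cv", r2, mae, rmse)


def benchmark(
    registry: list[FeatureSetSpec],
    table: pd.DataFrame,
    families: tuple[str, ...] = FAMILIES,
    config: SplitConfig | None = None,
    params_by_family: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Fit every (feature set, family) pair and emit a tidy result table.

    Hyperparameters default to each family's midpoint values unless
    overridden via ``params_by_family``.  Returns one row per
    set x family x split (train/test) with r2/mae/rmse columns.
    """
    config = config or SplitConfig()
    rows = []
    for spec in registry:
        X, y = materialize(table, spec)
        X_tr, X_te, y_tr, y_te = split_train_test(X, y, config)
        for family in families:
            params = (params_by_family or {}).get(family) or default_params(family)
            est = build_estimator(family, params, seed=config.seed)
            _fit(est, X_tr.to_numpy(float), y_tr)
            for split, Xs, ys in (("train", X_tr, y_tr), ("test", X_te, y_te)):
                r2, mae, rmse = metrics(ys, est.predict(Xs.to_numpy(float)))
                rows.append({
                    "feature_set": spec.name, "group": spec.group,
                    "model_family": family, "split": split,
                    "r2": r2, "mae": mae, "rmse": rmse,
                })
    return pd.DataFrame(rows)


def aggregate_by_set(results: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of each metric across families, per feature set and split."""
    grouped = results.groupby(["feature_set", "split"], sort=False)
    agg = grouped.agg(
        n_families=("model_family", "nunique"),
        r2_mean=("r2", "mean"), r2_sd=("r2", "std"),
        mae_mean=("mae", "mean"), mae_sd=("mae", "std"),
        rmse_mean=("rmse", "mean"), rmse_sd=("rmse", "std"),
    ).reset_index()
    return agg.fillna({"r2_sd": 0.0, "mae_sd": 0.0, "rmse_sd": 0.0})


def paired_t(values_a, values_b) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t statistic, df, p value)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), a.size - 1, float(res.pvalue)
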