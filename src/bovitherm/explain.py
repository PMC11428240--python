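"""Tree-ensemble SHAP attributions and plot-ready data products.

Implements the polynomial-time, tree-path-dependent SHAP algorithm for
scikit-learn decision-tree ensembles (decision tree, random forest,
gradient boosting).  For a single tree the attribution of feature ``i`` is
the exact Shapley value of the cooperative game ``v(S) = E[f | x_S]``
where the expectation follows the tree: splits on features in ``S`` follow
the instance, other splits average the children by training cover.

``brute_force_shap`` evaluates the same game by explicit subset
enumeration (exponential; intended as a test oracle on tiny trees).

Local accuracy holds by construction: ``base_value + sum(attributions)``
equals the model prediction for every row.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "ShapMatrix",
    "explain",
    "summary_stats",
    "dependence_data",
    "waterfall_data",
    "brute_force_shap",
    "tree_expectation",
]


@dataclass
class ShapMatrix:
    """Per-row per-feature attributions on the scale of the target."""

    values: np.ndarray          # (n_rows, n_features)
    base_value: float           # expected model output over the training cover
    feature_values: pd.DataFrame
    feature_names: list[str]

    @property
    def predictions(self) -> np.ndarray:
        return self.base_value + self.values.sum(axis=1)


# ---------------------------------------------------------------------------
# core path-dependent algorithm
# ---------------------------------------------------------------------------
# The recursion of the reference algorithm is flattened to an explicit DFS
# stack so the whole batch loop can be JIT-compiled with numba when it is
# available; the same code runs (slower) in pure Python otherwise.  Path
# buffers are 2D: row = recursion level; a frame copies its parent's row
# (level - 1) before extending, so sibling subtrees never clobber each
# other.


def _tree_shap_batch(left, right, feature, threshold, value, cover, X, phi):
    # path length bound: tree depth + 2 (children always appear after their
    # parent in sklearn's node arrays, so one forward pass fills depths)
    n_nodes = left.shape[0]
    node_depth = np.zeros(n_nodes, dtype=np.int64)
    for i in range(n_nodes):
        if left[i] >= 0:
            node_depth[left[i]] = node_depth[i] + 1
            node_depth[right[i]] = node_depth[i] + 1
    maxlen = int(np.max(node_depth)) + 3

    feat_buf = np.empty((maxlen, maxlen), dtype=np.int64)
    pz_buf = np.empty((maxlen, maxlen))
    po_buf = np.empty((maxlen, maxlen))
    pw_buf = np.empty((maxlen, maxlen))
    cap = 2 * maxlen + 4
    st_node = np.empty(cap, dtype=np.int64)
    st_depth = np.empty(cap, dtype=np.int64)
    st_level = np.empty(cap, dtype=np.int64)
    st_pzf = np.empty(cap)
    st_pof = np.empty(cap)
    st_pfi = np.empty(cap, dtype=np.int64)

    for row in range(X.shape[0]):
        x = X[row]
        sp = 0
        st_node[0] = 0
        st_depth[0] = 0
        st_level[0] = 0
        st_pzf[0] = 1.0
        st_pof[0] = 1.0
        st_pfi[0] = -1
        sp = 1
        while sp > 0:
            sp -= 1
            node = st_node[sp]
            depth = st_depth[sp]
            level = st_level[sp]
            pzf = st_pzf[sp]
            pof = st_pof[sp]
            pfi = st_pfi[sp]

            feat = feat_buf[level]
            pz = pz_buf[level]
            po = po_buf[level]
            pw = pw_buf[level]
            if level > 0:
                for i in range(depth):
                    feat[i] = feat_buf[level - 1, i]
                    pz[i] = pz_buf[level - 1, i]
                    po[i] = po_buf[level - 1, i]
                    pw[i] = pw_buf[level - 1, i]
            # extend the path with the incoming split
            feat[depth] = pfi
            pz[depth] = pzf
            po[depth] = pof
            pw[depth] = 1.0 if depth == 0 else 0.0
            for i in range(depth - 1, -1, -1):
                pw[i + 1] += pof * pw[i] * (i + 1) / (depth + 1)
                pw[i] = pzf * pw[i] * (depth - i) / (depth + 1)

            if left[node] < 0:  # leaf: unwound-sum accumulation per path entry
                leaf_value = value[node]
                for idx in range(1, depth + 1):
                    one_fraction = po[idx]
                    zero_fraction = pz[idx]
                    next_one = pw[depth]
                    total = 0.0
                    if one_fraction != 0.0:
                        for i in range(depth - 1, -1, -1):
                            tmp = next_one * (depth + 1) / ((i + 1) * one_fraction)
                            total += tmp
                            next_one = pw[i] - tmp * zero_fraction * (depth - i) / (depth + 1)
                    else:
                        for i in range(depth - 1, -1, -1):
                            total += pw[i] * (depth + 1) / (zero_fraction * (depth - i))
                    phi[row, feat[idx]] += total * (one_fraction - zero_fraction) * leaf_value
                continue

            split_feature = feature[node]
            if x[split_feature] <= threshold[node]:
                hot, cold = left[node], right[node]
            else:
                hot, cold = right[node], left[node]
            hot_zf = cover[hot] / cover[node]
            cold_zf = cover[cold] / cover[node]
            incoming_zero = 1.0
            incoming_one = 1.0

            # undo a previous split on this same feature, if any
            path_index = depth + 1
            for i in range(depth + 1):
                if feat[i] == split_feature:
                    path_index = i
                    break
            if path_index <= depth:
                incoming_zero = pz[path_index]
                incoming_one = po[path_index]
                one_fraction = po[path_index]
                zero_fraction = pz[path_index]
                next_one = pw[depth]
                for i in range(depth - 1, -1, -1):
                    if one_fraction != 0.0:
                        tmp = pw[i]
                        pw[i] = next_one * (depth + 1) / ((i + 1) * one_fraction)
                        next_one = tmp - pw[i] * zero_fraction * (depth - i) / (depth + 1)
                    else:
                        pw[i] = pw[i] * (depth + 1) / (zero_fraction * (depth - i))
                for i in range(path_index, depth):
                    feat[i] = feat[i + 1]
                    pz[i] = pz[i + 1]
                    po[i] = po[i + 1]
                depth -= 1

            # push cold then hot (hot is processed first)
            st_node[sp] = cold
            st_depth[sp] = depth + 1
            st_level[sp] = level + 1
            st_pzf[sp] = cold_zf * incoming_zero
            st_pof[sp] = 0.0
            st_pfi[sp] = split_feature
            sp += 1
            st_node[sp] = hot
            st_depth[sp] = depth + 1
            st_level[sp] = level + 1
            st_pzf[sp] = hot_zf * incoming_zero
            st_pof[sp] = incoming_one
            st_pfi[sp] = split_feature
            sp += 1


try:  # JIT-compile the batch kernel when numba is present
    from numba import njit as _njit

    _tree_shap_batch = _njit(cache=False)(_tree_shap_batch)
except ImportError:  # pragma: no cover - exercised only without numba
    pass


def _single_tree_shap(tree, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Attributions (n, F) and expectation for one fitted sklearn tree."""
    t = tree.tree_
    left = t.children_left.astype(np.int64)
    right = t.children_right.astype(np.int64)
    feature = t.feature.astype(np.int64)
    threshold = t.threshold.astype(np.float64)
    value = t.value[:, 0, 0].astype(np.float64)
    cover = t.weighted_n_node_samples.astype(np.float64)

    leaves = left < 0
    expectation = float(np.sum(value[leaves] * cover[leaves]) / cover[0])

    n, n_features = X.shape
    phi = np.zeros((n, n_features))
    _tree_shap_batch(left, right, feature, threshold, value, cover,
                     np.ascontiguousarray(X, dtype=np.float64), phi)
    return phi, expectation


# ---------------------------------------------------------------------------
# model adapters
# ---------------------------------------------------------------------------


def _decompose(model) -> tuple[list, np.ndarray, float]:
    """Return (trees, per-tree scales, additive offset) for a tree model."""
    if isinstance(model, DecisionTreeRegressor):
        return [model], np.ones(1), 0.0
    if isinstance(model, (RandomForestRegressor, ExtraTreesRegressor)):
        n = len(model.estimators_)
        return list(model.estimators_), np.full(n, 1.0 / n), 0.0
    if isinstance(model, GradientBoostingRegressor):
        trees = [stage[0] for stage in model.estimators_]
        scales = np.full(len(trees), model.learning_rate)
        init = model.init_
        if init == "zero":
            offset = 0.0
        else:
            offset = float(np.asarray(init.predict(np.zeros((1, model.n_features_in_)))).ravel()[0])
        return trees, scales, offset
    raise ValueError(
        f"unsupported model type {type(model).__name__}: explain() requires a "
        "decision-tree ensemble (DecisionTreeRegressor, RandomForestRegressor, "
        "ExtraTreesRegressor, or GradientBoostingRegressor)"
    )


def explain(model, X) -> ShapMatrix:
    """Path-dependent SHAP attributions for every row of ``X``."""
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        X_arr = X.to_numpy(float)
        frame = X.reset_index(drop=True)
    else:
        X_arr = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(X_arr.shape[1])]
        frame = pd.DataFrame(X_arr, columns=names)
    if np.isnan(X_arr).any():
        raise ValueError("X must be fully numeric with no missing cells")

    trees, scales, offset = _decompose(model)
    values = np.zeros((X_arr.shape[0], X_arr.shape[1]))
    base = offset
    for tree, scale in zip(trees, scales):
        phi, expectation = _single_tree_shap(tree, X_arr)
        values += scale * phi
        base += scale * expectation
    return ShapMatrix(values=values, base_value=float(base),
                      feature_values=frame, feature_names=names)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def tree_expectation(tree, x: np.ndarray, subset: frozenset | set) -> float:
    """Path-dependent conditional expectation E[f | x_S] for one tree."""
    t = tree.tree_
    def rec(node: int) -> float:
        if t.children_left[node] < 0:
            return float(t.value[node, 0, 0])
        f = t.feature[node]
        if f in subset:
            child = t.children_left[node] if x[f] <= t.threshold[node] else t.children_right[node]
            return rec(child)
        wl = t.weighted_n_node_samples[t.children_left[node]]
        wr = t.weighted_n_node_samples[t.children_right[node]]
        return (wl * rec(t.children_left[node]) + wr * rec(t.children_right[node])) / (wl + wr)
    return rec(0)


def brute_force_shap(model, x) -> tuple[np.ndarray, float]:
    """Exact Shapley values by subset enumeration (exponential cost).

    Returns (phi, base_value) for a single instance ``x``; intended for
    tiny trees/stumps in tests.
    """
    x = np.asarray(x, dtype=float)
    trees, scales, offset = _decompose(model)
    n_features = len(x)
    if n_features > 12:
        raise ValueError("brute force limited to <= 12 features")
    all_features = list(range(n_features))
    phi = np.zeros(n_features)
    base = offset
    for tree, scale in zip(trees, scales):
        base += scale * tree_expectation(tree, x, frozenset())
        for i in all_features:
            others = [f for f in all_features if f != i]
            for size in range(len(others) + 1):
                for S in itertools.combinations(others, size):
                    weight = (
                        math.factorial(size)
                        * math.factorial(n_features - size - 1)
                        / math.factorial(n_features)
                    )
                    gain = tree_expectation(tree, x, frozenset(S) | {i}) - tree_expectation(
                        tree, x, frozenset(S)
                    )
                    phi[i] += scale * weight * gain
    return phi, float(base)


# ---------------------------------------------------------------------------
# plot-ready data products
# ---------------------------------------------------------------------------


def summary_stats(shap: ShapMatrix) -> pd.DataFrame:
    """Mean |attribution| per feature, descending; ties broken lexicographically."""
    mean_abs = np.abs(shap.values).mean(axis=0)
    df = pd.DataFrame({"feature": shap.feature_names, "mean_abs_shap": mean_abs})
    return df.sort_values(
        ["mean_abs_shap", "feature"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def dependence_data(
    shap: ShapMatrix, feature: str, interaction_feature: str | None = None
) -> pd.DataFrame:
    """Per-row (x, attribution, color) triples for a dependence plot."""
    if feature not in shap.feature_names:
        raise ValueError(f"unknown feature {feature!r}")
    interaction = interaction_feature or feature
    if interaction not in shap.feature_names:
        raise ValueError(f"unknown interaction feature {interaction!r}")
    j = shap.feature_names.index(feature)
    return pd.DataFrame({
        "x": shap.feature_values[feature].to_numpy(float),
        "shap_value": shap.values[:, j],
        "color": shap.feature_values[interaction].to_numpy(float),
    })


def waterfall_data(shap: ShapMatrix, row_index: int) -> pd.DataFrame:
    """Ordered contributions for one row: |attribution| descending, with a
    cumulative sum running from base_value to the prediction."""
    row = shap.values[row_index]
    order = sorted(
        range(len(row)), key=lambda j: (-abs(row[j]), shap.feature_names[j])
    )
    df = pd.DataFrame({
        "feature": [shap.feature_names[j] for j in order],
        "feature_value": [shap.feature_values.iloc[row_index, j] for j in order],
        "contribution": [row[j] for j in order],
    })
    df["cumulative"] = shap.base_value + df["contribution"].cumsum()
    df.attrs["base_value"] = shap.base_value
    df.attrs["prediction"] = float(shap.base_value + row.sum())
    return df
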