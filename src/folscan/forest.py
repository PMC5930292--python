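"""Bootstrap regression forest (CART) with per-diameter importance factors.

Implemented from first principles so that the importance bookkeeping is
exact and auditable:

* trees are grown by recursive binary splitting on the 18 per-diameter
  count features, choosing at each node the (feature, threshold) pair
  that maximises the sum-of-squares decrease
  SSE(parent) − SSE(left) − SSE(right), over ``mtry`` features sampled
  without replacement; thresholds sit at midpoints of consecutive
  distinct values;
* each tree trains on an n-sized bootstrap resample; per-tree RNG
  streams are spawned deterministically from the forest seed, so a seed
  fully determines the forest;
* the "model importance factor" of a diameter is the total SSE decrease
  attributed to splits on it, summed over all trees and divided by the
  number of trees (impurity importance).  Out-of-bag permutation
  importance is available as an independent cross-check.

Prediction is the mean of per-tree predictions; the 95% prediction
limits are the empirical quantiles of the per-tree predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cohort import (
    Cohort,
    DIAMETERS,
    N_BINS,
    SizeHistogram,
    ValidationError,
)

__all__ = [
    "TreeNode",
    "ForestModel",
    "ImportanceProfile",
    "fit_tree",
    "fit_forest",
    "fit_forest_cohort",
    "predict",
    "predict_matrix",
    "predict_interval",
    "importance",
    "forest_to_json",
    "forest_from_json",
    "save_forest",
    "load_forest",
]

_SPLIT_TOL = 1e-12
SCHEMA_VERSION = 1


@dataclass
class TreeNode:
    """Node of a regression tree.

    Leaves carry only ``leaf_value`` (mean training outcome in the
    node); internal nodes additionally carry the split and its SSE
    decrease.
    """

    leaf_value: float
    n: int
    split_feature: Optional[int] = None  # feature index 0..17, None for leaves
    split_threshold: float = float("nan")
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    node_sse_decrease: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.split_feature is None


def _build_tree(
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    mtry: int,
    min_leaf: int,
    rng: np.random.Generator,
) -> TreeNode:
    n = idx.size
    yv = y[idx]
    s = float(yv.sum())
    node_mean = s / n
    node = TreeNode(leaf_value=node_mean, n=n)
    if n < 2 * min_leaf:
        return node

    n_features = X.shape[1]
    feats = rng.choice(n_features, size=min(mtry, n_features), replace=False)
    best_dec = _SPLIT_TOL
    best_feat = -1
    best_thr = 0.0
    parent_term = s * s / n
    for f in feats:
        xs = X[idx, f]
        order = np.argsort(xs, kind="stable")
        xsrt = xs[order]
        csum = np.cumsum(yv[order])
        nl = np.arange(1, n)
        valid = (xsrt[1:] != xsrt[:-1]) & (nl >= min_leaf) & (n - nl >= min_leaf)
        if not valid.any():
            continue
        sl = csum[:-1]
        dec = sl * sl / nl + (s - sl) ** 2 / (n - nl) - parent_term
        dec[~valid] = -np.inf
        j = int(np.argmax(dec))
        if dec[j] > best_dec:
            best_dec = float(dec[j])
            best_feat = int(f)
            best_thr = float(0.5 * (xsrt[j] + xsrt[j + 1]))
    if best_feat < 0:
        return node

    mask = X[idx, best_feat] <= best_thr
    node.split_feature = best_feat
    node.split_threshold = best_thr
    node.node_sse_decrease = best_dec
    node.left = _build_tree(X, y, idx[mask], mtry, min_leaf, rng)
    node.right = _build_tree(X, y, idx[~mask], mtry, min_leaf, rng)
    return node


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    mtry: int,
    min_leaf: int,
    rng: np.random.Generator,
) -> TreeNode:
    """Grow a single CART regression tree on (X, y).

    Splitting stops when a node has fewer than ``2·min_leaf`` rows or no
    candidate split yields a positive SSE decrease.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValidationError("X must be n x p and y length n")
    if y.size == 0:
        raise ValidationError("cannot fit a tree on empty data")
    if not 1 <= mtry:
        raise ValidationError("mtry must be >= 1")
    if min_leaf < 1:
        raise ValidationError("min_leaf must be >= 1")
    return _build_tree(X, y, np.arange(y.size), mtry, min_leaf, rng)


def _predict_tree(node: TreeNode, X: np.ndarray, out: np.ndarray, idx: np.ndarray) -> None:
    if node.is_leaf:
        out[idx] = node.leaf_value
        return
    m = X[idx, node.split_feature] <= node.split_threshold
    _predict_tree(node.left, X, out, idx[m])
    _predict_tree(node.right, X, out, idx[~m])


def predict_tree(node: TreeNode, X: np.ndarray) -> np.ndarray:
    """Predictions of one tree for each row of X."""
    X = np.asarray(X, dtype=float)
    out = np.empty(X.shape[0])
    _predict_tree(node, X, out, np.arange(X.shape[0]))
    return out


@dataclass
class ForestModel:
    """A fitted bootstrap regression forest over the 18 diameter bins."""

    trees: list[TreeNode]
    n_trees: int
    mtry: int
    min_leaf: int
    seed: int
    feature_names: tuple[int, ...] = tuple(DIAMETERS)
    outcome: str = ""
    #: per-tree out-of-bag row indices (empty when bootstrap disabled)
    oob_indices: list[np.ndarray] = field(default_factory=list, repr=False)
    #: training data, kept for permutation importance
    X_train: Optional[np.ndarray] = field(default=None, repr=False)
    y_train: Optional[np.ndarray] = field(default=None, repr=False)
    #: per-feature training ranges, for the coverage diagnostic
    feature_min: Optional[np.ndarray] = field(default=None, repr=False)
    feature_max: Optional[np.ndarray] = field(default=None, repr=False)


@dataclass
class ImportanceProfile:
    """Per-diameter importance factors from a fitted forest."""

    importance: dict[int, float]
    method: str

    def ranked(self) -> list[tuple[int, float]]:
        return sorted(self.importance.items(), key=lambda kv: -kv[1])


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 5000,
    mtry: int = 6,
    min_leaf: int = 5,
    seed: int = 0,
    bootstrap: bool = True,
    outcome: str = "",
) -> ForestModel:
    """Fit ``n_trees`` regression trees, each on a bootstrap resample.

    ``bootstrap=False`` trains every tree on the full sample (used by
    tests to reduce the forest to a single deterministic tree).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValidationError("X must be n x p and y length n")
    n = y.size
    if n < 10:
        raise ValidationError("need at least 10 rows to fit a forest")
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    if not 1 <= mtry <= X.shape[1]:
        raise ValidationError(f"mtry must be in 1..{X.shape[1]}")

    streams = np.random.SeedSequence(seed).spawn(n_trees)
    trees: list[TreeNode] = []
    oob: list[np.ndarray] = []
    all_idx = np.arange(n)
    for ss in streams:
        rng = np.random.default_rng(ss)
        if bootstrap:
            sample = rng.integers(0, n, size=n)
            oob.append(np.setdiff1d(all_idx, sample))
        else:
            sample = all_idx
            oob.append(np.empty(0, dtype=int))
        trees.append(_build_tree(X, y, sample, mtry, min_leaf, rng))
    return ForestModel(
        trees=trees,
        n_trees=n_trees,
        mtry=mtry,
        min_leaf=min_leaf,
        seed=seed,
        outcome=outcome,
        oob_indices=oob,
        X_train=X,
        y_train=y,
        feature_min=X.min(axis=0),
        feature_max=X.max(axis=0),
    )


def fit_forest_cohort(
    cohort: Cohort,
    outcome: str,
    n_trees: int = 5000,
    mtry: int = 6,
    min_leaf: int = 5,
    seed: int = 0,
) -> ForestModel:
    """Convenience wrapper: fit on a cohort's count matrix and outcome."""
    return fit_forest(
        cohort.design_matrix(),
        cohort.outcome_vector(outcome),
        n_trees=n_trees,
        mtry=mtry,
        min_leaf=min_leaf,
        seed=seed,
        outcome=outcome,
    )


def predict_matrix(forest: ForestModel, X: np.ndarray, per_tree: bool = False) -> np.ndarray:
    """Forest predictions for each row of X.

    With ``per_tree=True`` returns the (n_trees, n_rows) matrix of
    per-tree predictions instead of their mean.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(forest.feature_names):
        raise ValidationError(
            f"feature mismatch: expected {len(forest.feature_names)} columns"
        )
    preds = np.stack([predict_tree(t, X) for t in forest.trees])
    return preds if per_tree else preds.mean(axis=0)


def predict(forest: ForestModel, h: SizeHistogram) -> float:
    """Point prediction for one histogram (mean over trees)."""
    return float(predict_matrix(forest, h.as_array()[None, :])[0])


def predict_interval(
    forest: ForestModel, h: SizeHistogram, level: float = 0.95
) -> tuple[float, float]:
    """Per-tree quantile interval around the point prediction."""
    if not 0 < level < 1:
        raise ValidationError("level must be in (0, 1)")
    per_tree = predict_matrix(forest, h.as_array()[None, :], per_tree=True)[:, 0]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(per_tree, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _accumulate_decrease(node: TreeNode, acc: np.ndarray) -> None:
    if node.is_leaf:
        return
    acc[node.split_feature] += node.node_sse_decrease
    _accumulate_decrease(node.left, acc)
    _accumulate_decrease(node.right, acc)


def importance(forest: ForestModel, method: str = "impurity") -> ImportanceProfile:
    """Per-diameter importance factors.

    ``impurity``: total SSE decrease from splits on each diameter,
    summed over trees and divided by the number of trees.  A diameter
    never split on scores exactly 0.

    ``permutation``: mean increase in out-of-bag MSE after permuting
    the diameter's column, averaged over trees with non-empty OOB sets.
    """
    p = len(forest.feature_names)
    if method == "impurity":
        acc = np.zeros(p)
        for t in forest.trees:
            _accumulate_decrease(t, acc)
        acc /= forest.n_trees
        vals = acc
    elif method == "permutation":
        if forest.X_train is None or not forest.oob_indices:
            raise ValidationError(
                "permutation importance requires out-of-bag data retained at fit time"
            )
        X, y = forest.X_train, forest.y_train
        rng = np.random.default_rng(np.random.SeedSequence([forest.seed, 2**16 + 1]))
        acc = np.zeros(p)
        used = 0
        for t, oob in zip(forest.trees, forest.oob_indices):
            if oob.size == 0:
                continue
            used += 1
            Xo = X[oob]
            base = float(np.mean((predict_tree(t, Xo) - y[oob]) ** 2))
            for f in range(p):
                Xp = Xo.copy()
                Xp[:, f] = Xp[rng.permutation(oob.size), f]
                acc[f] += float(np.mean((predict_tree(t, Xp) - y[oob]) ** 2)) - base
        if used == 0:
            raise ValidationError("no tree has out-of-bag rows; cannot permute")
        vals = acc / used
    else:
        raise ValidationError(f"unknown importance method {method!r}")
    return ImportanceProfile(
        importance={d: float(v) for d, v in zip(forest.feature_names, vals)},
        method=method,
    )


# ---------------------------------------------------------------------------
# serialization (versioned JSON; structure and parameters only)

def _node_to_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {"value": node.leaf_value, "n": node.n}
    return {
        "value": node.leaf_value,
        "n": node.n,
        "feature": node.split_feature,
        "threshold": node.split_threshold,
        "decrease": node.node_sse_decrease,
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(d: dict) -> TreeNode:
    node = TreeNode(leaf_value=float(d["value"]), n=int(d["n"]))
    if "feature" in d:
        node.split_feature = int(d["feature"])
        node.split_threshold = float(d["threshold"])
        node.node_sse_decrease = float(d["decrease"])
        node.left = _node_from_dict(d["left"])
        node.right = _node_from_dict(d["right"])
    return node


def forest_to_json(forest: ForestModel) -> str:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "n_trees": forest.n_trees,
        "mtry": forest.mtry,
        "min_leaf": forest.min_leaf,
        "seed": forest.seed,
        "outcome": forest.outcome,
        "feature_names": list(forest.feature_names),
        "feature_min": None if forest.feature_min is None else forest.feature_min.tolist(),
        "feature_max": None if forest.feature_max is None else forest.feature_max.tolist(),
        "trees": [_node_to_dict(t) for t in forest.trees],
    }
    return json.dumps(payload, sort_keys=True, separators=(",", ":"))


def forest_from_json(text: str) -> ForestModel:
    d = json.loads(text)
    if d.get("schema_version") != SCHEMA_VERSION:
        raise ValidationError(f"unsupported forest schema {d.get('schema_version')!r}")
    return ForestModel(
        trees=[_node_from_dict(t) for t in d["trees"]],
        n_trees=int(d["n_trees"]),
        mtry=int(d["mtry"]),
        min_leaf=int(d["min_leaf"]),
        seed=int(d["seed"]),
        outcome=d.get("outcome", ""),
        feature_names=tuple(d["feature_names"]),
        feature_min=None if d["feature_min"] is None else np.asarray(d["feature_min"]),
        feature_max=None if d["feature_max"] is None else np.asarray(d["feature_max"]),
    )


def save_forest(forest: ForestModel, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(forest_to_json(forest))


def load_forest(path: str) -> ForestModel:
    with open(path, encoding="utf-8") as fh:
        return forest_from_json(fh.read())
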