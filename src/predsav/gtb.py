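"""Gradient tree boosting with the logistic loss.

The classifier is an additive ensemble Θ_M(χ) = Θ₀ + Σ_m ν·γ_m(χ) built by
functional gradient descent on L(y, Θ) = log(1 + exp(−yΘ)) with labels
y ∈ {−1, +1}:

1. Θ₀ = argmin_c Σ L(y_i, c) = log(n₊/n₋), the training log-odds;
2. at each iteration the negative gradient r_i = y_i·σ(−y_i Θ(χ_i)) is
   fitted by a least-squares regression tree of bounded depth;
3. each leaf's value is replaced by a single Newton step on the logistic
   loss over the training points in that leaf (the standard estimator of
   the per-leaf line search), then applied with shrinkage ν.

The class probability is σ(Θ) and the predicted label is +1 iff Θ ≥ 0
(probability ≥ 0.5; ties predict +1).  Tree fitting is delegated to
scikit-learn's regression trees; the boosting loop, initialization, gradient
and Newton leaf updates are implemented here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

FORMAT_VERSION = 1

DEFAULT_N_TREES = 2000
DEFAULT_DEPTH = 3
DEFAULT_LEARNING_RATE = 0.1


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


def logistic_loss(y, theta) -> float:
    """Σ log(1 + exp(−yΘ))."""
    return float(np.logaddexp(0.0, -np.asarray(y) * np.asarray(theta)).sum())


@dataclass
class _Tree:
    """One regression tree in flat array form (scikit-learn node layout)."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    leaf_value: np.ndarray  # Newton leaf values, 0 at internal nodes

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf index of every row (vectorized level-by-level routing)."""
        node = np.zeros(len(X), dtype=np.int64)
        while True:
            internal = self.children_left[node] >= 0
            if not internal.any():
                return node
            idx = np.nonzero(internal)[0]
            cur = node[idx]
            go_left = X[idx, self.feature[cur]] <= self.threshold[cur]
            node[idx] = np.where(go_left, self.children_left[cur], self.children_right[cur])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.leaf_value[self.apply(X)]

    def to_jsonable(self) -> dict:
        return dict(
            children_left=self.children_left.tolist(),
            children_right=self.children_right.tolist(),
            feature=self.feature.tolist(),
            threshold=self.threshold.tolist(),
            leaf_value=self.leaf_value.tolist(),
        )

    @classmethod
    def from_jsonable(cls, d: dict) -> "_Tree":
        return cls(
            children_left=np.asarray(d["children_left"], dtype=np.int64),
            children_right=np.asarray(d["children_right"], dtype=np.int64),
            feature=np.asarray(d["feature"], dtype=np.int64),
            threshold=np.asarray(d["threshold"], dtype=float),
            leaf_value=np.asarray(d["leaf_value"], dtype=float),
        )


@dataclass
class PredictionSet:
    """Decision values, probabilities and ±1 labels for a batch of variants."""

    decision: np.ndarray
    probability: np.ndarray
    labels: np.ndarray


class GradientTreeBoosting:
    """Gradient tree boosting model for ±1-labeled feature matrices.

    Parameters
    ----------
    X : (n, p) array
    y : (n,) array of ±1 labels
    feature_names : sequence of str, optional
        Enables name-based column alignment at prediction time.
    n_trees : int
        Boosting iterations M (default 2000).
    depth : int
        Maximum tree depth (default 3).
    learning_rate : float
        Shrinkage ν applied to every leaf update (default 0.1).
    seed : int
        Seeds the (tie-breaking) randomness of tree fitting.
    """

    def __init__(
        self,
        X,
        y,
        feature_names=None,
        n_trees: int = DEFAULT_N_TREES,
        depth: int = DEFAULT_DEPTH,
        learning_rate: float = DEFAULT_LEARNING_RATE,
        seed: int = 0,
        diagnostics: bool = True,
    ):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if not set(np.unique(y)) <= {-1, 1}:
            raise ValueError("labels must be in {-1, +1}")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        if depth < 1 or n_trees < 0:
            raise ValueError("depth must be >= 1 and n_trees >= 0")
        if feature_names is not None and len(feature_names) != X.shape[1]:
            raise ValueError("feature_names length must match the number of columns")
        self.X = X
        self.y = y.astype(float)
        self.feature_names = list(feature_names) if feature_names is not None else None
        self.n_trees = int(n_trees)
        self.depth = int(depth)
        self.learning_rate = float(learning_rate)
        self.seed = int(seed)
        self.diagnostics = bool(diagnostics)

    def fit(self) -> "GTBResults":
        n = len(self.y)
        n_pos = float(np.sum(self.y == 1))
        n_neg = float(np.sum(self.y == -1))
        init_score = float(np.log(n_pos / n_neg))  # argmin_c Σ log(1+e^{-yc})

        theta = np.full(n, init_score)
        trees: list = []
        loss_trace = [logistic_loss(self.y, theta)] if self.diagnostics else None
        importances = np.zeros(self.X.shape[1])
        # sklearn trees operate on float32 internally; convert once
        X32 = np.ascontiguousarray(self.X, dtype=np.float32)

        for m in range(self.n_trees):
            # negative gradient of the logistic loss (working response)
            resid = self.y * _sigmoid(-self.y * theta)
            reg = DecisionTreeRegressor(
                max_depth=self.depth, random_state=(self.seed + m) % (2**31)
            )
            reg.fit(X32, resid, check_input=False)
            tree, leaf_of = self._newton_leaves(reg, resid, X32)
            theta = theta + self.learning_rate * tree.leaf_value[leaf_of]
            trees.append(tree)
            if self.diagnostics:
                loss_trace.append(logistic_loss(self.y, theta))
                importances += reg.tree_.compute_feature_importances(normalize=False)

        total = importances.sum()
        if total > 0:
            importances = importances / total
        return GTBResults(
            init_score=init_score,
            trees=trees,
            learning_rate=self.learning_rate,
            depth=self.depth,
            seed=self.seed,
            feature_names=self.feature_names,
            loss_trace_=np.asarray(loss_trace) if self.diagnostics else None,
            feature_importances_=importances if self.diagnostics else None,
        )

    def _newton_leaves(self, reg: DecisionTreeRegressor, resid: np.ndarray, X32):
        """Replace each leaf's least-squares mean with one Newton step on the
        logistic loss: γ = Σ r_i / Σ |r_i|(1−|r_i|) over the leaf's points."""
        t = reg.tree_
        leaf_of = t.apply(X32)
        hess = np.abs(resid) * (1.0 - np.abs(resid))
        num = np.bincount(leaf_of, weights=resid, minlength=t.node_count)
        den = np.bincount(leaf_of, weights=hess, minlength=t.node_count)
        with np.errstate(invalid="ignore", divide="ignore"):
            leaf_value = np.where(den > 1e-150, num / np.maximum(den, 1e-150), 0.0)
        tree = _Tree(
            children_left=t.children_left.copy().astype(np.int64),
            children_right=t.children_right.copy().astype(np.int64),
            feature=t.feature.copy().astype(np.int64),
            threshold=t.threshold.copy().astype(float),
            leaf_value=leaf_value,
        )
        return tree, leaf_of


@dataclass
class GTBResults:
    """A fitted boosting ensemble: Θ(χ) = init_score + Σ ν·tree_m(χ)."""

    init_score: float
    trees: list
    learning_rate: float
    depth: int
    seed: int
    feature_names: list | None = None
    loss_trace_: np.ndarray | None = None
    feature_importances_: np.ndarray | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def _align(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if self.feature_names is None:
                return X.to_numpy(dtype=float)
            missing = [c for c in self.feature_names if c not in X.columns]
            extra = [c for c in X.columns if c not in self.feature_names]
            if missing or extra:
                raise ValueError(
                    f"feature columns do not match training: missing={missing}, extra={extra}"
                )
            return X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if self.feature_names is not None and X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} feature columns, got {X.shape[1]}"
            )
        return X

    def decision_function(self, X) -> np.ndarray:
        X = self._align(X)
        theta = np.full(len(X), self.init_score)
        for tree in self.trees:
            theta += self.learning_rate * tree.predict(X)
        return theta

    def predict_proba(self, X) -> np.ndarray:
        """P(disease-associated) = σ(Θ)."""
        return _sigmoid(self.decision_function(X))

    def predict(self, X) -> PredictionSet:
        theta = self.decision_function(X)
        prob = _sigmoid(theta)
        return PredictionSet(
            decision=theta, probability=prob, labels=np.where(prob >= 0.5, 1, -1)
        )

    def summary(self) -> str:
        lines = [
            "Gradient Tree Boosting",
            "======================",
            f"trees           : {self.n_trees}",
            f"max depth       : {self.depth}",
            f"learning rate   : {self.learning_rate}",
            f"init score Θ₀   : {self.init_score:.6f}",
        ]
        if self.loss_trace_ is not None and len(self.loss_trace_):
            lines.append(f"training loss   : {self.loss_trace_[0]:.4f} -> {self.loss_trace_[-1]:.4f}")
        if self.feature_importances_ is not None and self.feature_names is not None:
            order = np.argsort(self.feature_importances_)[::-1][:10]
            lines.append("top features    :")
            for i in order:
                if self.feature_importances_[i] <= 0:
                    break
                lines.append(f"  {self.feature_names[i]:<30s} {self.feature_importances_[i]:.4f}")
        return "\n".join(lines)


def train_gtb(
    fm,
    n_trees: int = DEFAULT_N_TREES,
    depth: int = DEFAULT_DEPTH,
    learning_rate: float = DEFAULT_LEARNING_RATE,
    seed: int = 0,
) -> GTBResults:
    """Fit the boosting classifier to a :class:`~predsav.selection.FeatureMatrix`."""
    return GradientTreeBoosting(
        fm.X, fm.y, feature_names=fm.names,
        n_trees=n_trees, depth=depth, learning_rate=learning_rate, seed=seed,
    ).fit()


def save_model(results: GTBResults, path) -> None:
    """Write the fitted ensemble to versioned JSON (metadata + tree arrays)."""
    payload = dict(
        format_version=FORMAT_VERSION,
        init_score=results.init_score,
        learning_rate=results.learning_rate,
        depth=results.depth,
        seed=results.seed,
        n_trees=results.n_trees,
        feature_names=results.feature_names,
        trees=[t.to_jsonable() for t in results.trees],
    )
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> GTBResults:
    """Load a model written by :func:`save_model`; round-trips predictions
    bit-identically."""
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValueError(f"corrupt or truncated model file {path}") from e
    version = payload.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"model format version {version!r} unsupported (expected {FORMAT_VERSION})"
        )
    if payload["n_trees"] != len(payload["trees"]):
        raise ValueError(f"corrupt model file {path}: tree count mismatch")
    return GTBResults(
        init_score=payload["init_score"],
        trees=[_Tree.from_jsonable(t) for t in payload["trees"]],
        learning_rate=payload["learning_rate"],
        depth=payload["depth"],
        seed=payload["seed"],
        feature_names=payload["feature_names"],
    )
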