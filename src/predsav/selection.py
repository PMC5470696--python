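"""Two-step feature selection: stability selection, then sequential forward
selection (SFS) scored by cross-validated AUC under the boosting learner.

Stability selection repeatedly (i) subsamples half of the variants,
(ii) rescales every standardized feature column by an independent random
factor drawn from [weakness, 1], and (iii) fits an L1-regularized linear
selector along a short penalty path, recording which features ever receive
nonzero weight.  A feature's score is the fraction of resamples in which it
was selected; informative features score close to 1.  Features scoring
above the cutoff (0.2 by default, strict inequality) enter the SFS stage,
which greedily adds the candidate whose addition most increases the 5-fold
cross-validated AUC of the boosting classifier and stops as soon as the AUC
no longer increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

DEFAULT_CUTOFF = 0.2
#: tree count used by the SFS learner (the final model uses 2000)
SELECTION_TREES = 200


@dataclass
class FeatureMatrix:
    """Variants × features with ±1 labels (+1 disease-associated, −1 neutral)."""

    names: list
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.y):
            raise ValueError("X must be 2-D with one row per label")
        if self.X.shape[1] != len(self.names):
            raise ValueError("names length must equal the number of columns")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("labels must be in {-1, +1}")
        if len(np.unique(self.y)) < 2:
            raise ValueError("both classes must be present")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, names) -> "FeatureMatrix":
        idx = [self.names.index(n) for n in names]
        return FeatureMatrix(names=list(names), X=self.X[:, idx], y=self.y)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.names)
        df.insert(0, "label", self.y)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_col: str = "label") -> "FeatureMatrix":
        y = df[label_col].to_numpy()
        data = df.drop(columns=[label_col])
        return cls(names=list(data.columns), X=data.to_numpy(dtype=float), y=y)

    @classmethod
    def read_tsv(cls, path, label_col: str = "label") -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t"), label_col=label_col)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class StabilityScores:
    """Per-feature selection fractions in [0, 1] with the run parameters."""

    names: list
    scores: np.ndarray
    n_resamples: int
    subsample_frac: float
    weakness: float
    seed: int

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scores) != len(self.names):
            raise ValueError("one score per feature required")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("stability scores must lie in [0, 1]")

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.names, name="stability_score")

    def score_of(self, name: str) -> float:
        return float(self.scores[self.names.index(name)])


@dataclass
class SelectionTrace:
    """Ordered SFS picks with the CV-AUC after each addition."""

    selected: list
    auc_trace: list
    stop_reason: str
    params: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return dict(
            selected=list(self.selected),
            auc_trace=[float(a) for a in self.auc_trace],
            stop_reason=self.stop_reason,
            params=self.params,
        )


def stability_selection(
    fm: FeatureMatrix,
    n_resamples: int = 200,
    subsample_frac: float = 0.5,
    weakness: float = 0.5,
    seed: int = 0,
    n_alphas: int = 10,
    alpha_min_ratio: float = 0.1,
    max_retries: int = 100,
) -> StabilityScores:
    """Randomized-lasso stability selection.

    Each of ``n_resamples`` rounds draws ⌈subsample_frac·n⌉ variants without
    replacement (redrawn, boundedly, if single-class), multiplies each
    standardized feature column by an independent factor ~ U[weakness, 1],
    and fits a lasso along ``n_alphas`` log-spaced penalties from the
    subsample's critical penalty α_max down to ``alpha_min_ratio``·α_max.
    A feature counts as selected in a round if its coefficient is nonzero
    anywhere on the path; scores are selection fractions over rounds.
    Deterministic given ``seed``.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if not 0 < subsample_frac <= 1:
        raise ValueError("subsample_frac must be in (0, 1]")
    if not 0 < weakness <= 1:
        raise ValueError("weakness must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n, p = fm.X.shape
    m = int(np.ceil(subsample_frac * n))

    mu = fm.X.mean(axis=0)
    sd = fm.X.std(axis=0)
    keep = sd > 0
    Z = np.zeros_like(fm.X)
    Z[:, keep] = (fm.X[:, keep] - mu[keep]) / sd[keep]
    y = fm.y.astype(float)

    counts = np.zeros(p)
    for _ in range(n_resamples):
        for attempt in range(max_retries):
            idx = rng.choice(n, size=m, replace=False)
            if len(np.unique(fm.y[idx])) == 2:
                break
        else:
            raise RuntimeError(
                f"could not draw a two-class subsample in {max_retries} attempts"
            )
        scale = rng.uniform(weakness, 1.0, size=p)
        Xb = Z[idx] * scale
        yb = y[idx] - y[idx].mean()
        Xb = Xb - Xb.mean(axis=0)
        alpha_max = np.max(np.abs(Xb.T @ yb)) / m
        if alpha_max == 0:
            continue  # degenerate subsample: nothing correlates with the label
        alphas = np.geomspace(alpha_max, alpha_max * alpha_min_ratio, n_alphas)
        _, coefs, _ = lasso_path(Xb, yb, alphas=alphas)
        counts += (np.abs(coefs) > 1e-12).any(axis=1)

    return StabilityScores(
        names=list(fm.names),
        scores=counts / n_resamples,
        n_resamples=n_resamples,
        subsample_frac=subsample_frac,
        weakness=weakness,
        seed=seed,
    )


def threshold_select(ss: StabilityScores, cutoff: float = DEFAULT_CUTOFF) -> list:
    """Features with stability score strictly greater than ``cutoff``,
    ordered by descending score then name.  Warns (and returns []) when no
    feature passes."""
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must lie in [0, 1]")
    picked = [
        (name, score)
        for name, score in zip(ss.names, ss.scores)
        if score > cutoff
    ]
    picked.sort(key=lambda t: (-t[1], t[0]))
    if not picked:
        import warnings

        warnings.warn(f"no feature has stability score > {cutoff}")
    return [name for name, _ in picked]


def _cv_auc(fm: FeatureMatrix, names, splits, learner_config: dict, seed: int) -> float:
    """Pooled out-of-fold AUC of the boosting learner on a feature subset,
    with a fixed fold partition (paired comparisons across candidates)."""
    from predsav.gtb import GradientTreeBoosting
    from predsav.metrics import roc_auc

    sub = fm.subset(names)
    pooled = np.zeros(sub.n_samples)
    for tr, te in splits:
        model = GradientTreeBoosting(
            sub.X[tr], sub.y[tr], feature_names=sub.names, seed=seed,
            diagnostics=False, **learner_config
        ).fit()
        pooled[te] = model.decision_function(sub.X[te])
    return roc_auc(sub.y, pooled)


def sequential_forward_selection(
    fm: FeatureMatrix,
    candidates,
    folds: int = 5,
    seed: int = 0,
    min_gain: float = 0.0,
    stability: StabilityScores | None = None,
    learner_config: dict | None = None,
    max_features: int | None = None,
) -> SelectionTrace:
    """Greedy forward selection scored by stratified k-fold CV AUC.

    At each step every remaining candidate is evaluated jointly with the
    current set (same fold partition and learner seed throughout).  The
    first pick is the unconditional argmax (any single feature beats the
    empty, chance-level model); every later argmax is added only if its AUC
    beats the incumbent by more than ``min_gain``, otherwise selection
    stops.  Ties break toward the higher stability score, then the
    lexicographically smaller name.
    """
    from predsav.metrics import stratified_folds

    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate set is empty")
    if len(set(candidates)) != len(candidates):
        raise ValueError("duplicate candidate names")
    unknown = [c for c in candidates if c not in fm.names]
    if unknown:
        raise ValueError(f"candidates not in feature matrix: {unknown}")

    cfg = dict(n_trees=SELECTION_TREES, depth=3, learning_rate=0.1)
    cfg.update(learner_config or {})
    splits = stratified_folds(fm.y, folds=folds, seed=seed)

    def tie_key(name):
        stab = stability.score_of(name) if stability is not None else 0.0
        return (-stab, name)

    selected: list = []
    auc_trace: list = []
    incumbent = 0.5  # AUC of the empty (uninformative) model
    remaining = sorted(candidates, key=tie_key)
    stop_reason = "auc_no_longer_increased"
    while remaining:
        best_name, best_auc = None, -np.inf
        for name in remaining:  # tie-break order is the iteration order
            auc = _cv_auc(fm, selected + [name], splits, cfg, seed)
            if auc > best_auc:
                best_name, best_auc = name, auc
        # the first pick is the unconditional argmax (it always beats the
        # empty-set chance baseline); later picks must improve by > min_gain
        if not selected or best_auc > incumbent + min_gain:
            selected.append(best_name)
            remaining.remove(best_name)
            auc_trace.append(float(best_auc))
            incumbent = best_auc
        else:
            break
        if max_features is not None and len(selected) >= max_features:
            stop_reason = "max_features_reached"
            break
    else:
        stop_reason = "candidates_exhausted"

    return SelectionTrace(
        selected=selected,
        auc_trace=auc_trace,
        stop_reason=stop_reason,
        params=dict(
            folds=folds,
            seed=seed,
            min_gain=min_gain,
            learner=cfg,
            n_candidates=len(candidates),
        ),
    )
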