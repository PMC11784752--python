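"""Random k conditional nearest neighbor (RkCNN) ensemble.

The algorithm: draw h random feature subsets of size m (uniform, without
replacement within a subset; independent across subsets), score each by the
separation score S = BV/WV, keep the r highest-scoring subsets, weight them
proportionally to score, and classify a query by the weighted average of the
component kCNN probability vectors:

    P(Y=c | x) = sum_{j=1}^{r} w_(j) * P_(j)(Y=c | x),
    w_(j) = S_(j) / sum_{l<=r} S_(l).

Filtering happens before any kCNN model is evaluated, so h controls only the
size of the candidate pool, not prediction cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataset import Dataset
from .kcnn import _proba_from_class_distances, kth_class_distances
from .separation import (
    FeatureSubset,
    SubsetScore,
    compute_precompute,
    separation_score_fast,
)

__all__ = [
    "RkCNNConfig",
    "FittedRkCNN",
    "sample_subsets",
    "select_top_r",
    "compute_weights",
    "rkcnn_fit",
    "rkcnn_predict_proba",
    "rkcnn_predict",
    "RkCNN",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RkCNNConfig:
    """Ensemble tuning parameters.

    k    neighbor rank inside each class (small k recommended);
    m    subset size, 1 <= m <= q (ceil(sqrt(q)) is a common default);
    r    number of contributing subsets;
    h    number of sampled candidate subsets, h >= r;
    seed integer master seed controlling subset sampling.
    """

    k: int
    m: int
    r: int
    h: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.r < 1:
            raise ValueError(f"r must be >= 1, got {self.r}")
        if self.h < self.r:
            raise ValueError(f"h ({self.h}) must be >= r ({self.r})")


@dataclass(frozen=True)
class FittedRkCNN:
    """A fitted ensemble: training data, retained subsets, and weights."""

    train: Dataset
    selected: list  # r SubsetScore, descending S, ties by draw order
    weights: np.ndarray  # nonnegative, sums to 1
    config: RkCNNConfig

    @property
    def classes(self) -> np.ndarray:
        return self.train.classes


def sample_subsets(q: int, m: int, h: int, seed: int) -> list[FeatureSubset]:
    """Draw h feature subsets of size m, uniformly without replacement.

    Each subset consumes its own child of the master seed stream, so growing
    h re-draws nothing: the first subsets of a longer run coincide with a
    shorter run at the same seed.  Duplicate subsets across draws are allowed
    (draws are independent).
    """
    if m > q:
        raise ValueError(f"subset size m={m} exceeds feature count q={q}")
    if h < 1:
        raise ValueError(f"h must be >= 1, got {h}")
    children = np.random.SeedSequence(seed).spawn(h)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        out.append(FeatureSubset(rng.choice(q, size=m, replace=False), q))
    return out


def select_top_r(scores: list[SubsetScore], r: int) -> list[SubsetScore]:
    """The r largest-S entries, descending; ties keep sampling order."""
    if r > len(scores):
        raise ValueError(f"r={r} exceeds number of scored subsets {len(scores)}")
    order = sorted(range(len(scores)), key=lambda j: (-scores[j].s, j))
    return [scores[j] for j in order[:r]]


def compute_weights(top: list[SubsetScore]) -> np.ndarray:
    """Score-proportional weights w_(j) = S_(j) / sum_l S_(l).

    Degenerate limits: infinite scores take uniform mass among themselves
    (everything else gets 0); if every score is 0 the weights are uniform.
    """
    if len(top) == 0:
        raise ValueError("cannot weight an empty subset list")
    s = np.array([t.s for t in top], dtype=np.float64)
    inf = np.isinf(s)
    if inf.any():
        return inf / inf.sum()
    total = s.sum()
    if total == 0.0:
        logger.warning(
            "all %d retained subsets have separation score 0; "
            "falling back to uniform weights", len(top)
        )
        return np.full(s.size, 1.0 / s.size)
    return s / total


def rkcnn_fit(train: Dataset, config: RkCNNConfig) -> FittedRkCNN:
    """Sample, score and select subsets; kCNN evaluation stays lazy."""
    if config.m > train.q:
        raise ValueError(
            f"subset size m={config.m} exceeds feature count q={train.q}"
        )
    pre = compute_precompute(train)
    subsets = sample_subsets(train.q, config.m, config.h, config.seed)
    scores = [separation_score_fast(pre, s) for s in subsets]
    top = select_top_r(scores, config.r)
    weights = compute_weights(top)
    return FittedRkCNN(train=train, selected=top, weights=weights, config=config)


def rkcnn_predict_proba(model: FittedRkCNN, queries: np.ndarray) -> np.ndarray:
    """Weighted average of the component kCNN probability vectors.

    Returns a ``(t, L)`` matrix; every row sums to 1.
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    train = model.train
    if queries.shape[1] != train.q:
        raise ValueError(
            f"queries have {queries.shape[1]} features, train has {train.q}"
        )
    agg = np.zeros((queries.shape[0], train.n_classes))
    for score, w in zip(model.selected, model.weights):
        if w == 0.0:
            continue
        if score.subset.m == train.q:  # full feature set: no copy
            sub_train, sub_queries = train.features, queries
        else:
            idx = score.subset.indices
            sub_train, sub_queries = train.features[:, idx], queries[:, idx]
        d = kth_class_distances(
            sub_train,
            train.codes,
            train.n_classes,
            sub_queries,
            model.config.k,
        )
        agg += w * _proba_from_class_distances(d)
    return agg


def rkcnn_predict(model: FittedRkCNN, queries: np.ndarray) -> np.ndarray:
    """Argmax classes of the aggregated probabilities (ties: lowest ordinal)."""
    probs = rkcnn_predict_proba(model, queries)
    return model.classes[np.argmax(probs, axis=1)]


class RkCNN:
    """Estimator-style wrapper around the functional interface.

    >>> clf = RkCNN(k=1, m=15, r=200, h=600, seed=0)
    >>> clf.fit(train)            # train: Dataset
    >>> clf.predict(X_new)        # array of class labels
    """

    def __init__(self, k: int = 1, m: int | None = None, r: int = 200,
                 h: int | None = None, seed: int = 0):
        self.k = k
        self.m = m
        self.r = r
        self.h = h
        self.seed = seed
        self.model_: FittedRkCNN | None = None

    def _config(self, q: int) -> RkCNNConfig:
        m = self.m if self.m is not None else int(np.ceil(np.sqrt(q)))
        h = self.h if self.h is not None else 3 * self.r
        return RkCNNConfig(k=self.k, m=m, r=self.r, h=h, seed=self.seed)

    def fit(self, train: Dataset) -> "RkCNN":
        self.model_ = rkcnn_fit(train, self._config(train.q))
        return self

    def _check_fitted(self) -> FittedRkCNN:
        if self.model_ is None:
            raise RuntimeError("call fit() before predicting")
        return self.model_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return rkcnn_predict_proba(self._check_fitted(), X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return rkcnn_predict(self._check_fitted(), X)

    @property
    def classes_(self) -> np.ndarray:
        return self._check_fitted().classes
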