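"""k conditional nearest neighbor (kCNN) classification.

Unlike plain kNN, which pools the k nearest training points regardless of
class, kCNN looks up the k-th nearest training point *within each class* and
converts the reciprocals of those per-class distances into a class-probability
vector:

    P(Y = c | x)  =  d_c^{-1} / sum_l d_l^{-1},

where ``d_c`` is the Euclidean distance from the query to the k-th nearest
member of class c.  If a class has fewer than k members, its farthest
available member is used instead (k is clamped per class).  If one or more
classes sit at distance exactly zero, the unit probability mass is split
uniformly over those classes, which is the limit of the formula as the
distance goes to zero.
"""

from __future__ import annotations

import numpy as np

from .dataset import Dataset

__all__ = [
    "kth_class_distance",
    "kcnn_predict_proba",
    "kcnn_predict",
]


def _pairwise_sq_dists(queries: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, (t x n), via the Gram-matrix expansion."""
    q2 = np.einsum("ij,ij->i", queries, queries)
    x2 = np.einsum("ij,ij->i", X, X)
    d2 = q2[:, None] + x2[None, :] - 2.0 * (queries @ X.T)
    np.maximum(d2, 0.0, out=d2)
    return d2


def kth_class_distances(
    X: np.ndarray,
    codes: np.ndarray,
    n_classes: int,
    queries: np.ndarray,
    k: int,
) -> np.ndarray:
    """Per-class k-th nearest neighbor distances for a batch of queries.

    Returns a ``(t, L)`` matrix ``D`` with ``D[t, c]`` the Euclidean distance
    from query ``t`` to the k-th closest training row of class ``c`` (clamped
    to the class size when the class has fewer than k members).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    queries = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    if queries.shape[1] != X.shape[1]:
        raise ValueError(
            f"query has {queries.shape[1]} features, train has {X.shape[1]}"
        )
    d2 = _pairwise_sq_dists(queries, X)
    out = np.empty((queries.shape[0], n_classes))
    for c in range(n_classes):
        members = np.flatnonzero(codes == c)
        if members.size == 0:
            raise ValueError(f"class ordinal {c} has no members")
        kk = min(k, members.size)  # clamp: farthest available member
        dc = d2[:, members]
        out[:, c] = np.partition(dc, kk - 1, axis=1)[:, kk - 1]
    return np.sqrt(out)


def _proba_from_class_distances(dists: np.ndarray) -> np.ndarray:
    """Inverse-distance normalization with the exact-zero mass rule."""
    probs = np.empty_like(dists)
    zero = dists == 0.0
    any_zero = zero.any(axis=1)
    if any_zero.any():
        z = zero[any_zero]
        probs[any_zero] = z / z.sum(axis=1, keepdims=True)
    regular = ~any_zero
    if regular.any():
        inv = 1.0 / dists[regular]
        probs[regular] = inv / inv.sum(axis=1, keepdims=True)
    return probs


def kth_class_distance(train: Dataset, query, k: int, c) -> float:
    """Distance from ``query`` to the k-th nearest training point of class ``c``."""
    code = train.code_of(c)
    d = kth_class_distances(
        train.features, train.codes, train.n_classes, query, k
    )
    return float(d[0, code])


def kcnn_predict_proba(train: Dataset, query, k: int) -> np.ndarray:
    """Class-probability vector for one query (class-ordinal order).

    Entries are nonnegative and sum to 1.
    """
    d = kth_class_distances(
        train.features, train.codes, train.n_classes, query, k
    )
    return _proba_from_class_distances(d)[0]


def kcnn_predict_proba_batch(train: Dataset, queries: np.ndarray, k: int) -> np.ndarray:
    """Row-wise class probabilities for a ``(t, q)`` query matrix."""
    d = kth_class_distances(
        train.features, train.codes, train.n_classes, queries, k
    )
    return _proba_from_class_distances(d)


def kcnn_predict(train: Dataset, query, k: int):
    """Most probable class; exact ties go to the smallest class ordinal."""
    probs = kcnn_predict_proba(train, query, k)
    return train.classes[int(np.argmax(probs))]


def kcnn_predict_batch(train: Dataset, queries: np.ndarray, k: int) -> np.ndarray:
    probs = kcnn_predict_proba_batch(train, queries, k)
    return train.classes[np.argmax(probs, axis=1)]
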