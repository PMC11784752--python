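"""Separation score: class separability of a feature subset.

For a feature subset the between-group dispersion BV measures how far the
class mean vectors sit from the overall mean, and the within-group dispersion
WV measures how tightly each class clusters around its own mean:

    BV = sum_c ||xbar_c' - xbar'||_2 / (L - 1)
    WV = sum_c sum_{i in c} ||x_i' - xbar_c'||_2 / (sqrt(N_c - 1) * L)

(primes denote restriction to the subset's columns).  The separation score
S = BV / WV is large when classes are well separated in that subspace, so it
ranks random feature subsets by how useful they are to a nearest-neighbor
component classifier.

Two implementations are provided.  The fast path precomputes two matrices
once per training set —

    B (q x L):  column c = (xbar_c - xbar) ** 2                (elementwise)
    W (q x n):  column i = (x_i - xbar_{c(i)}) ** 2 / (N_{c(i)} - 1)

— after which the score of any subset with indicator vector z costs only

    BV = sum_c sqrt(b_c^T z) / (L - 1),   WV = sum_i sqrt(w_i^T z) / L.

The direct path restricts the data to the subset's columns and evaluates the
norm formulas; it exists as an independently coded oracle for the fast path.
Degenerate subsets are scored by the limits of the ratio: S = +inf when
WV = 0 with BV > 0 (perfect separation), and S = 0 whenever BV = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import Dataset

__all__ = [
    "FeatureSubset",
    "SeparationPrecompute",
    "SubsetScore",
    "compute_precompute",
    "separation_score_fast",
    "separation_score_direct",
]


@dataclass(frozen=True)
class FeatureSubset:
    """An m-element subset of feature indices out of q features."""

    indices: np.ndarray
    q: int

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=np.intp))
        if idx.size == 0:
            raise ValueError("feature subset may not be empty")
        if idx[0] < 0 or idx[-1] >= self.q:
            raise ValueError(f"feature indices out of range [0, {self.q})")
        object.__setattr__(self, "indices", idx)

    @property
    def m(self) -> int:
        return self.indices.size

    @property
    def z(self) -> np.ndarray:
        """0/1 indicator vector of length q with exactly m ones."""
        z = np.zeros(self.q, dtype=np.float64)
        z[self.indices] = 1.0
        return z


@dataclass(frozen=True)
class SubsetScore:
    subset: FeatureSubset
    bv: float
    wv: float
    s: float  # bv/wv, +inf when wv == 0 < bv, 0 when bv == 0


def _score_from_bv_wv(subset: FeatureSubset, bv: float, wv: float) -> SubsetScore:
    if bv == 0.0:
        s = 0.0
    elif wv == 0.0:
        s = np.inf
    else:
        s = bv / wv
    return SubsetScore(subset=subset, bv=float(bv), wv=float(wv), s=float(s))


@dataclass(frozen=True)
class SeparationPrecompute:
    """Per-training-set matrices from which any subset score is cheap."""

    B: np.ndarray  # (q, L) squared class-mean deviations from overall mean
    W: np.ndarray  # (q, n) squared within-class deviations / (N_c - 1)
    class_sizes: np.ndarray
    class_means: np.ndarray  # (L, q)
    overall_mean: np.ndarray  # (q,)

    @property
    def q(self) -> int:
        return self.B.shape[0]

    @property
    def n_classes(self) -> int:
        return self.B.shape[1]


def compute_precompute(train: Dataset) -> SeparationPrecompute:
    """Build the B and W matrices for a training set.

    Every class needs at least two members for the (N_c - 1) divisor;
    a smaller class raises ``ValueError`` naming the class.
    """
    X = train.features
    L = train.n_classes
    sizes = train.class_sizes()
    for c, nc in enumerate(sizes):
        if nc < 2:
            raise ValueError(
                f"class {train.classes[c]!r} has {nc} member(s); "
                "separation scoring needs at least 2 per class"
            )
    overall = X.mean(axis=0)  # grand mean over all n rows
    means = np.empty((L, train.q))
    W = np.empty((train.q, train.n))
    for c in range(L):
        rows = train.codes == c
        means[c] = X[rows].mean(axis=0)
        dev = X[rows] - means[c]
        W[:, rows] = (dev * dev).T / (sizes[c] - 1)
    B = ((means - overall) ** 2).T
    return SeparationPrecompute(
        B=B, W=W, class_sizes=sizes, class_means=means, overall_mean=overall
    )


def separation_score_fast(
    pre: SeparationPrecompute, subset: FeatureSubset
) -> SubsetScore:
    """Score a subset from the precomputed B and W matrices."""
    if subset.q != pre.q:
        raise ValueError(
            f"subset is over {subset.q} features, precompute over {pre.q}"
        )
    idx = subset.indices
    L = pre.n_classes
    bv = np.sqrt(pre.B[idx, :].sum(axis=0)).sum() / (L - 1)
    wv = np.sqrt(pre.W[idx, :].sum(axis=0)).sum() / L
    return _score_from_bv_wv(subset, bv, wv)


def separation_score_direct(train: Dataset, subset: FeatureSubset) -> SubsetScore:
    """Definitional score: restrict columns, evaluate the norm formulas.

    Independent of :func:`separation_score_fast`; used as its testing oracle.
    """
    if subset.q != train.q:
        raise ValueError(
            f"subset is over {subset.q} features, dataset has {train.q}"
        )
    sizes = train.class_sizes()
    for c, nc in enumerate(sizes):
        if nc < 2:
            raise ValueError(
                f"class {train.classes[c]!r} has {nc} member(s); "
                "separation scoring needs at least 2 per class"
            )
    Xs = train.features[:, subset.indices]
    L = train.n_classes
    overall = Xs.mean(axis=0)
    bv = 0.0
    wv = 0.0
    for c in range(L):
        rows = Xs[train.codes == c]
        mean_c = rows.mean(axis=0)
        bv += np.linalg.norm(mean_c - overall)
        wv += np.linalg.norm(rows - mean_c, axis=1).sum() / np.sqrt(
            sizes[c] - 1
        )
    return _score_from_bv_wv(subset, bv / (L - 1), wv / L)


def score_subsets_fast(
    pre: SeparationPrecompute, subsets: list[FeatureSubset]
) -> list[SubsetScore]:
    """Score many subsets against one precompute (convenience loop)."""
    return [separation_score_fast(pre, s) for s in subsets]
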