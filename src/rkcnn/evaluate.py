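"""Metrics, leave-one-out cross-validation, and method-comparison driver.

Metrics are the misclassification rate and the generalized (multiclass)
Matthews correlation coefficient computed from the full L x L confusion
matrix.  The experiment driver regenerates misclassification-rate comparisons
between RkCNN and the thin in-repo baselines (plain kNN, plain kCNN, and an
unweighted random-subset kNN ensemble, "RkNN") on the synthetic data designs
from :mod:`rkcnn.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier

from .dataset import Dataset
from .ensemble import RkCNNConfig, rkcnn_fit, rkcnn_predict, sample_subsets
from .kcnn import kcnn_predict_batch
from .simulate import SimulationConfig, simulate_train_test

__all__ = [
    "EvaluationResult",
    "misclassification_rate",
    "matthews_corrcoef",
    "confusion_matrix",
    "loocv",
    "run_comparison_experiment",
    "BaselineConfig",
    "METHODS",
]


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def _as_arrays(predicted, truth) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted)
    t = np.asarray(truth)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError(
            f"predicted and truth must be equal-length vectors, "
            f"got shapes {p.shape} and {t.shape}"
        )
    if p.size == 0:
        raise ValueError("empty label vectors")
    return p, t


def misclassification_rate(predicted, truth) -> float:
    """Fraction of mismatching labels."""
    p, t = _as_arrays(predicted, truth)
    return float(np.mean(p != t))


def confusion_matrix(predicted, truth, classes=None) -> np.ndarray:
    """L x L count matrix; rows = true class, columns = predicted class."""
    p, t = _as_arrays(predicted, truth)
    if classes is None:
        classes = np.unique(np.concatenate([t, p]))
    classes = np.asarray(classes)
    lut = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((classes.size, classes.size), dtype=np.int64)
    for ti, pi in zip(t, p):
        cm[lut[ti], lut[pi]] += 1
    return cm


def matthews_corrcoef(predicted, truth) -> float:
    """Generalized (Gorodkin) Matthews correlation coefficient.

    Computed from the full confusion matrix C:

        MCC = (n * tr(C) - sum_k t_k p_k)
              / sqrt((n^2 - sum_k p_k^2) * (n^2 - sum_k t_k^2))

    with t_k, p_k the true/predicted marginals.  Ranges over [-1, 1]; 1 is
    perfect agreement, 0 chance-level, -1 complete disagreement.  Returns 0
    when a marginal term degenerates (e.g. all predictions in one class).
    """
    p, t = _as_arrays(predicted, truth)
    if np.unique(t).size < 2:
        raise ValueError("truth must contain at least 2 classes")
    cm = confusion_matrix(p, t).astype(np.float64)
    n = cm.sum()
    t_marg = cm.sum(axis=1)
    p_marg = cm.sum(axis=0)
    cov_tp = n * np.trace(cm) - t_marg @ p_marg
    cov_pp = n * n - p_marg @ p_marg
    cov_tt = n * n - t_marg @ t_marg
    denom = np.sqrt(cov_pp * cov_tt)
    if denom == 0.0:
        return 0.0
    return float(cov_tp / denom)


@dataclass(frozen=True)
class EvaluationResult:
    accuracy: float
    misclassification: float
    mcc: float
    confusion: np.ndarray
    per_fold_predictions: np.ndarray


# --------------------------------------------------------------------------
# baselines
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BaselineConfig:
    """Specification of a non-RkCNN method for LOOCV / experiments.

    method: "kNN" (all features), "kCNN" (all features) or "RkNN"
    (unweighted majority vote of kNN over r random size-m subsets — a thin
    reference reimplementation, not a reproduction of any published RkNN).
    """

    method: str
    k: int = 3
    m: int | None = None  # RkNN only; default ceil(sqrt(q))
    r: int = 200          # RkNN only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("kNN", "kCNN", "RkNN"):
            raise ValueError(f"unknown method {self.method!r}")


def _knn_predict(train: Dataset, X_test: np.ndarray, k: int) -> np.ndarray:
    clf = KNeighborsClassifier(n_neighbors=min(k, train.n))
    clf.fit(train.features, train.labels)
    return np.asarray(clf.predict(X_test))


def _rknn_predict(
    train: Dataset, X_test: np.ndarray, k: int, m: int, r: int, seed: int
) -> np.ndarray:
    """Majority vote of r subset-restricted kNN classifiers; ties go to the
    smallest class ordinal."""
    subsets = sample_subsets(train.q, m, r, seed)
    votes = np.zeros((X_test.shape[0], train.n_classes), dtype=np.int64)
    for sub in subsets:
        idx = sub.indices
        sub_train = train.features[:, idx]
        clf = KNeighborsClassifier(n_neighbors=min(k, train.n))
        clf.fit(sub_train, train.codes)
        pred = clf.predict(X_test[:, idx])
        votes[np.arange(X_test.shape[0]), pred] += 1
    return train.classes[np.argmax(votes, axis=1)]


def _predict_with_spec(spec, train: Dataset, X_test: np.ndarray) -> np.ndarray:
    """Dispatch on RkCNNConfig vs BaselineConfig."""
    if isinstance(spec, RkCNNConfig):
        model = rkcnn_fit(train, spec)
        return rkcnn_predict(model, X_test)
    if isinstance(spec, BaselineConfig):
        if spec.method == "kNN":
            return _knn_predict(train, X_test, spec.k)
        if spec.method == "kCNN":
            return kcnn_predict_batch(train, X_test, spec.k)
        m = spec.m if spec.m is not None else int(np.ceil(np.sqrt(train.q)))
        return _rknn_predict(train, X_test, spec.k, m, spec.r, spec.seed)
    raise TypeError(f"unsupported model spec {type(spec).__name__}")


def _child_seed(seed: int, *key: int) -> int:
    """Deterministic child seed below 2**31 from a master seed and a key."""
    return int(
        np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31)
    )


def _reseed(spec, seed: int):
    if isinstance(spec, RkCNNConfig):
        return RkCNNConfig(k=spec.k, m=spec.m, r=spec.r, h=spec.h, seed=seed)
    return BaselineConfig(
        method=spec.method, k=spec.k, m=spec.m, r=spec.r, seed=seed
    )


# --------------------------------------------------------------------------
# leave-one-out cross-validation
# --------------------------------------------------------------------------

def loocv(data: Dataset, model_spec) -> EvaluationResult:
    """Leave-one-out CV of an RkCNN or baseline specification.

    Each fold refits the full pipeline on n-1 rows with a fold-specific child
    seed derived from the spec's master seed, then predicts the held-out row.
    Requires every class to have at least 3 members so the training classes
    keep the >= 2 members the separation precompute needs.
    """
    if data.n < 3:
        raise ValueError("LOOCV needs at least 3 observations")
    sizes = data.class_sizes()
    for c, nc in enumerate(sizes):
        if nc < 3:
            raise ValueError(
                f"class {data.classes[c]!r} has {nc} member(s); LOOCV needs "
                "at least 3 per class"
            )
    master = getattr(model_spec, "seed", 0)
    preds = np.empty(data.n, dtype=data.labels.dtype)
    for i in range(data.n):
        fold_spec = _reseed(model_spec, _child_seed(master, i))
        fold_train = data.drop_row(i)
        preds[i] = _predict_with_spec(
            fold_spec, fold_train, data.features[i : i + 1]
        )[0]
    mis = misclassification_rate(preds, data.labels)
    return EvaluationResult(
        accuracy=1.0 - mis,
        misclassification=mis,
        mcc=matthews_corrcoef(preds, data.labels),
        confusion=confusion_matrix(preds, data.labels, classes=data.classes),
        per_fold_predictions=preds,
    )


# --------------------------------------------------------------------------
# comparison experiment driver
# --------------------------------------------------------------------------

METHODS = ("kNN", "kCNN", "RkNN", "RkCNN")


@dataclass(frozen=True)
class ComparisonResult:
    """Raw per-replicate metrics plus a mean-misclassification summary."""

    raw: pd.DataFrame = field(repr=False)

    def summary(self) -> pd.DataFrame:
        return (
            self.raw.groupby("method", sort=False)[["misclassification", "mcc"]]
            .mean()
            .reset_index()
        )


def run_comparison_experiment(
    sim: SimulationConfig,
    methods: list[str],
    replicates: int,
    seed: int,
    k: int = 3,
    r: int = 200,
    m: int | None = None,
    h: int | None = None,
) -> ComparisonResult:
    """Mean test-set misclassification per method over fresh train/test draws.

    Per replicate, an independent training and test set of ``sim.n_per_class``
    observations per class are drawn; every requested method is fit on the
    same training set and scored on the same test set.  Defaults follow the
    common comparison settings: k = 3, r = 200, m = ceil(sqrt(q)), h = 3 r.
    """
    for name in methods:
        if name not in METHODS:
            raise ValueError(f"unknown method {name!r}; choose from {METHODS}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    q = sim.q
    m_eff = m if m is not None else int(np.ceil(np.sqrt(q)))
    h_eff = h if h is not None else 3 * r
    rows = []
    for rep in range(replicates):
        rep_seed = _child_seed(seed, rep)
        rep_sim = SimulationConfig(
            d=sim.d, q_noise=sim.q_noise, n_per_class=sim.n_per_class,
            omega=sim.omega, omega_c=sim.omega_c,
            num_classes=sim.num_classes, seed=rep_seed,
            permute_columns=sim.permute_columns,
        )
        train, test = simulate_train_test(rep_sim)
        for name in sorted(methods, key=METHODS.index):
            method_seed = _child_seed(seed, rep, METHODS.index(name))
            if name == "RkCNN":
                spec = RkCNNConfig(k=k, m=m_eff, r=r, h=h_eff, seed=method_seed)
            elif name == "RkNN":
                spec = BaselineConfig(
                    method="RkNN", k=k, m=m_eff, r=r, seed=method_seed
                )
            else:
                spec = BaselineConfig(method=name, k=k, seed=method_seed)
            pred = _predict_with_spec(spec, train, test.features)
            rows.append(
                {
                    "method": name,
                    "replicate": rep,
                    "misclassification": misclassification_rate(
                        pred, test.labels
                    ),
                    "mcc": matthews_corrcoef(pred, test.labels),
                }
            )
    raw = pd.DataFrame(rows)
    # present methods in their requested order
    raw["method"] = pd.Categorical(
        raw["method"], categories=[m_ for m_ in METHODS if m_ in methods]
    )
    raw = raw.sort_values(["replicate", "method"]).reset_index(drop=True)
    raw["method"] = raw["method"].astype(str)
    return ComparisonResult(raw=raw)
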