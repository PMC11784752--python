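"""Labeled feature-matrix container used throughout the package.

A :class:`Dataset` couples an ``n x q`` continuous feature matrix with one
categorical label per row.  Class labels are mapped to stable ordinal codes
(0..L-1) by sorted label order; every algorithm in this package reports class
probabilities in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Dataset"]


@dataclass(frozen=True)
class Dataset:
    """An ``n x q`` feature matrix plus a length-``n`` categorical label vector.

    Parameters
    ----------
    features
        Real-valued matrix, one row per observation.  Must be finite.
    labels
        One categorical label per row.  At least two distinct classes and at
        least one member per class are required.

    Attributes
    ----------
    classes : ndarray
        Distinct labels in sorted order; position defines the class ordinal.
    codes : ndarray of int
        Per-row class ordinals (``codes[i] == class_index[labels[i]]``).
    """

    features: np.ndarray
    labels: np.ndarray
    classes: np.ndarray = field(init=False)
    codes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError(f"features must be 2-D, got shape {X.shape}")
        n, q = X.shape
        if n < 2:
            raise ValueError(f"need at least 2 observations, got {n}")
        if q < 1:
            raise ValueError("need at least 1 feature")
        if not np.isfinite(X).all():
            bad = np.argwhere(~np.isfinite(X))[0]
            raise ValueError(
                f"non-finite feature value at row {bad[0]}, column {bad[1]}"
            )
        y = np.asarray(self.labels)
        if y.ndim != 1 or y.shape[0] != n:
            raise ValueError(
                f"labels length {y.shape} does not match feature rows {n}"
            )
        classes, codes = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("need at least 2 distinct classes")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)
        object.__setattr__(self, "classes", classes)
        object.__setattr__(self, "codes", codes.astype(np.intp))

    # -- basic shape accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def q(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return self.classes.size

    @property
    def class_index(self) -> dict:
        """Mapping label -> ordinal 0..L-1 (sorted by label)."""
        return {c: i for i, c in enumerate(self.classes)}

    def class_sizes(self) -> np.ndarray:
        """Number of members per class, in class-ordinal order."""
        return np.bincount(self.codes, minlength=self.n_classes)

    def code_of(self, label) -> int:
        """Ordinal of ``label``; raises ``KeyError`` for unknown classes."""
        idx = np.searchsorted(self.classes, label)
        if idx >= self.classes.size or self.classes[idx] != label:
            raise KeyError(f"unknown class {label!r}")
        return int(idx)

    # -- construction helpers --------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str) -> "Dataset":
        """Build a Dataset from a DataFrame with one label column.

        All non-label columns must be numeric and finite; offending cells are
        reported with row/column coordinates.
        """
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found")
        feats = df.drop(columns=[label_column])
        for col in feats.columns:
            numeric = pd.to_numeric(feats[col], errors="coerce")
            bad = numeric.index[numeric.isna()]
            if len(bad) > 0:
                raise ValueError(
                    f"missing or non-numeric value at row {bad[0]}, "
                    f"column {col!r}"
                )
            feats[col] = numeric
        return cls(feats.to_numpy(dtype=np.float64),
                   df[label_column].to_numpy())

    def to_dataframe(self, label_column: str = "label") -> pd.DataFrame:
        cols = [f"f{i + 1}" for i in range(self.q)]
        df = pd.DataFrame(self.features, columns=cols)
        df[label_column] = self.labels
        return df

    def drop_row(self, i: int) -> "Dataset":
        """Dataset with row ``i`` removed (used by leave-one-out CV)."""
        keep = np.ones(self.n, dtype=bool)
        keep[i] = False
        return Dataset(self.features[keep], self.labels[keep])
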