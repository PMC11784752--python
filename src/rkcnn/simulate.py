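"""Synthetic high-dimensional classification data.

The generator produces balanced Gaussian classes on d informative features
plus pure-noise columns, the standard benchmark design for studying
nearest-neighbor methods under irrelevant features:

  class A  ~  N(2 * 1_d, omega * Psi),  Psi_ij = (1/2)^|i-j|  (AR(1)-like),
  class B  ~  N(1 * 1_d, I_d),
  class C  ~  N(3 * 1_d, omega_C * I_d)          (three-class settings only),

and every class appends q_noise i.i.d. standard-normal columns.  omega scales
the spread of class A (hence the overlap with B); omega_C plays the same role
for class C.  Informative columns come first by convention (a permutation
option exists; every algorithm in this package is column-order invariant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import Dataset

__all__ = ["SimulationConfig", "ar1_covariance", "simulate_dataset"]

_CLASS_LABELS = ("A", "B", "C")
_CLASS_MEANS = {"A": 2.0, "B": 1.0, "C": 3.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset draw.

    d            informative features (>= 1);
    q_noise      standard-normal noise features (>= 0);
    n_per_class  observations per class (>= 2; classes are balanced);
    omega        variance scale of class A (> 0);
    omega_c      variance scale of class C (> 0; ignored for 2 classes);
    num_classes  2 (A, B) or 3 (A, B, C);
    seed         integer seed; equal seeds give byte-identical datasets.
    """

    d: int
    q_noise: int = 0
    n_per_class: int = 1000
    omega: float = 1.0
    omega_c: float = 1.0
    num_classes: int = 2
    seed: int = 0
    permute_columns: bool = False

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError(f"d must be >= 1, got {self.d}")
        if self.q_noise < 0:
            raise ValueError(f"q_noise must be >= 0, got {self.q_noise}")
        if self.n_per_class < 2:
            raise ValueError(
                f"n_per_class must be >= 2, got {self.n_per_class}"
            )
        if self.num_classes not in (2, 3):
            raise ValueError(f"num_classes must be 2 or 3, got {self.num_classes}")
        if self.omega <= 0 or self.omega_c <= 0:
            raise ValueError("omega and omega_c must be positive")

    @property
    def q(self) -> int:
        return self.d + self.q_noise

    def informative_indices(self) -> np.ndarray:
        """Column positions of the informative features (before permutation)."""
        return np.arange(self.d)


def ar1_covariance(d: int) -> np.ndarray:
    """The d x d matrix with entries (1/2)^|i-j|.

    Symmetric positive definite with unit diagonal; feature correlation
    decays geometrically with index distance.
    """
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    idx = np.arange(d)
    return 0.5 ** np.abs(idx[:, None] - idx[None, :])


def simulate_dataset(config: SimulationConfig) -> Dataset:
    """Draw one dataset; rows are shuffled deterministically by the seed."""
    rng = np.random.default_rng(config.seed)
    d, noise = config.d, config.q_noise
    npc = config.n_per_class
    labels_used = _CLASS_LABELS[: config.num_classes]

    psi = ar1_covariance(d)
    chol_a = np.linalg.cholesky(config.omega * psi)

    blocks, labels = [], []
    for lab in labels_used:
        mean = np.full(d, _CLASS_MEANS[lab])
        z = rng.standard_normal((npc, d))
        if lab == "A":
            informative = mean + z @ chol_a.T
        elif lab == "B":
            informative = mean + z
        else:  # class C: spherical with its own scale
            informative = mean + np.sqrt(config.omega_c) * z
        noise_block = rng.standard_normal((npc, noise))
        blocks.append(np.hstack([informative, noise_block]))
        labels.extend([lab] * npc)

    X = np.vstack(blocks)
    y = np.array(labels)
    perm = rng.permutation(X.shape[0])
    X, y = X[perm], y[perm]
    if config.permute_columns:
        X = X[:, rng.permutation(X.shape[1])]
    return Dataset(X, y)


def simulate_train_test(
    config: SimulationConfig, test_seed: int | None = None
) -> tuple[Dataset, Dataset]:
    """A training draw plus an independent test draw from the same design."""
    if test_seed is None:
        # distinct, deterministic companion stream
        test_seed = int(
            np.random.SeedSequence([config.seed, 0x7E57]).generate_state(1)[0]
            % (2**31)
        )
    base = SimulationConfig(
        d=config.d,
        q_noise=config.q_noise,
        n_per_class=config.n_per_class,
        omega=config.omega,
        omega_c=config.omega_c,
        num_classes=config.num_classes,
        seed=config.seed,
        permute_columns=False,
    )
    train = simulate_dataset(base)
    test = simulate_dataset(
        SimulationConfig(
            d=config.d,
            q_noise=config.q_noise,
            n_per_class=config.n_per_class,
            omega=config.omega,
            omega_c=config.omega_c,
            num_classes=config.num_classes,
            seed=test_seed,
            permute_columns=False,
        )
    )
    if config.permute_columns:
        # one shared permutation so train and test stay column-aligned
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0xC015])
        )
        perm = rng.permutation(config.q)
        train = Dataset(train.features[:, perm], train.labels)
        test = Dataset(test.features[:, perm], test.labels)
    return train, test
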