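# rkcnn — random k conditional nearest neighbor classification

Nearest-neighbor classifiers degrade badly on high-dimensional data —
gene-expression microarrays being the canonical case — because the many
irrelevant features swamp the Euclidean distances that the method relies on.
`rkcnn` implements **RkCNN**, an ensemble remedy built on the
*k conditional nearest neighbor* (kCNN) classifier.

## The method

For a query **x** and training data restricted to a feature subset, kCNN
finds the k-th nearest training point *within each class* c and turns the
inverse distances into class probabilities:

    P(Y = c | x) = d_c^{-1} / Σ_l d_l^{-1},    d_c = ||x' − x'_{k|c}||₂

RkCNN draws **h** random feature subsets of size **m** (uniform, without
replacement), scores each subset's class separability with the ratio
**S = BV / WV** of between-group to within-group dispersion,

    BV = Σ_c ||x̄'_c − x̄'||₂ / (L − 1),
    WV = Σ_c Σ_{i∈c} ||x'_i − x̄'_c||₂ / (√(N_c − 1) · L),

keeps the **r** highest-scoring subsets, and averages their kCNN probability
vectors with score-proportional weights w₍ⱼ₎ = S₍ⱼ₎ / Σ_l S₍l₎.  The query is
assigned to the class with the largest aggregated probability.  Scores are
computed from two precomputed matrices (squared class-mean deviations and
squared within-class deviations), so scoring any subset costs only an index
sum — subset filtering is cheap and happens before any distance computation.

The package also ships the synthetic benchmark generator used to study the
method (two or three multivariate-normal classes on d informative features —
class A with AR(1)-like covariance (1/2)^|i−j| scaled by ω — plus
standard-normal noise features), plain kNN / kCNN / RkNN baselines,
misclassification and multiclass Matthews-correlation metrics, leave-one-out
cross-validation, and a small CLI.

## Worked example

```python
import numpy as np
from rkcnn import RkCNN, SimulationConfig
from rkcnn.simulate import simulate_train_test
from rkcnn.evaluate import misclassification_rate

sim = SimulationConfig(d=20, q_noise=500, n_per_class=1000, seed=11)
train, test = simulate_train_test(sim)           # 2000 x 520 each

clf = RkCNN(k=3, r=200, h=600, seed=5).fit(train)  # m defaults to ceil(sqrt(q))=23
pred = clf.predict(test.features)
print(misclassification_rate(pred, test.labels))
```

This prints `0.055`: with 500 noise features drowning 20 informative ones,
the weighted subset ensemble misclassifies ~5% of the 2,000 test points,
whereas plain 3-NN on all 520 features misclassifies ~20% of them on the
same draw.  The separation score of any subset is available directly:

```
$ rkcnn simulate --d 20 --noise 500 --n-per-class 1000 --seed 11 --out train.csv
$ rkcnn score --data train.csv --subset 0,3,7
BV      1.765037
WV      50.396998
S       0.035023
```

(features 0, 3 and 7 are informative in this draw, so the subset scores well
above the noise-only baseline — compare `--subset 100,101,102`, which gives
S ≈ 0.001).

The CLI also exposes `simulate`, `fit-predict` and `benchmark` subcommands;
every output file gets a `.meta.json` sidecar recording version, seed and
parameters so runs are reproducible byte-for-byte.

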