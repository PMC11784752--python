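# Methods

## Model

`rkcnn` classifies a query vector by aggregating many k-conditional-nearest-
neighbor (kCNN) component classifiers, each restricted to a random feature
subset.  kCNN estimates P(Y=c|x) as the normalized reciprocal of the
Euclidean distance from the query to the k-th nearest training point *of
class c*; unlike plain kNN it therefore always produces a full probability
vector and never lets a locally dominant class mask the others.  The
ensemble (RkCNN) draws h subsets of m features by simple random sampling
without replacement (duplicates across draws allowed — draws are
independent), ranks them by the separation score S = BV/WV, retains the top
r, and weights the retained components proportionally to their scores.  The
aggregated probability is the convex combination Σⱼ w₍ⱼ₎ P₍ⱼ₎(Y=c|x); the
predicted class is its argmax, with exact ties resolved toward the smallest
class ordinal (classes are ordered by sorted label).

The assumptions are those of any nearest-neighbor method — a metric feature
space in which locality is informative — plus the ensemble's premise that
*some* random subsets of features separate the classes much better than
others, which is what makes score-based filtering and weighting worthwhile.
No feature scaling is applied internally; features are taken as given (an
optional z-score flag exists at the CLI layer, default off).

## Separation score

For a subset with indicator vector z over the q features,

    BV = Σ_c ||x̄'_c − x̄'||₂ / (L−1)          (between-group dispersion)
    WV = Σ_c Σ_{i∈c} ||x'_i − x̄'_c||₂ / (√(N_c−1)·L)   (within-group)

where primes denote restriction to the subset, x̄ is the unweighted grand
mean over all n training rows, and N_c the class sizes.  Both are norm-based
dispersion measures (square roots of summed squares), not variances proper.
The fast path precomputes B (q×L, squared class-mean deviations) and
W (q×n, squared within-class deviations over N_c−1) once per training set,
after which BV = Σ_c √(b_cᵀz)/(L−1) and WV = Σ_i √(w_iᵀz)/L for any subset —
an O(m·n) index sum with no further per-vector work.  A definitional
implementation (`separation_score_direct`) restricts the columns and
evaluates the norms; the test suite holds the two paths equal to 1e−9
relative tolerance over a thousand random dataset/subset pairs.

A note on the √(N_c−1): placing the 1/(N_c−1) *inside* the square (in the W
matrix) and taking square roots per observation is what makes the fast path
an identity rather than an approximation, and it is the convention used
throughout this package, in both paths.  An alternative reading divides each
class's summed norms by N_c−1 outside; for balanced classes the two differ
by one global constant, leaving subset rankings, weights and hence all
predictions identical.

Degenerate subsets are scored by the limits of the ratio: S = +∞ when
WV = 0 with BV > 0 (a perfectly separating subset should rank first) and
S = 0 whenever BV = 0.  Weighting inherits the same limits: +∞ scores split
the unit mass uniformly among themselves; if every retained score is 0 the
weights fall back to uniform with a logged warning.

## Tuning parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| k | neighbor rank within each class | 1 (CLI); 3 in the comparison driver | averaging across subsets already reduces variance, so low-bias small k works best; k is clamped per class to N_c when a class is smaller than k |
| m | subset size | ⌈√q⌉ | balances feature-interaction coverage against dilution by noise features |
| r | retained subsets | 200 | large enough to stabilize the weighted average |
| h | sampled candidate subsets | 3r | more candidates enrich the retained pool at scoring-only cost; h = r disables filtering |
| seed | master seed | — | one integer; each subset draw consumes its own child stream, so increasing h only appends draws |

## Synthetic data generator

The generator emulates the standard "few informative, many noise features"
benchmark: balanced classes, d informative features with class A ~
N(2·1, ωΨ) where Ψᵢⱼ = (1/2)^|i−j| (AR(1)-like correlation), class B ~
N(1·1, I), optionally class C ~ N(3·1, ω_C·I), plus q_noise i.i.d. standard-
normal columns appended identically for every class.  ω widens class A and
therefore the A/B overlap.  Sampling uses a Cholesky factor of ωΨ; rows are
shuffled deterministically by the seed; informative columns come first (a
column-permutation option exists, and a shared permutation is applied to
train/test pairs so they stay aligned — all algorithms are column-order
invariant regardless).

What it does *not* emulate: heavy tails, feature-dependent scales, class
imbalance, or the correlation structure of real expression data.  Passing
the simulation benchmarks therefore demonstrates the noise-robustness
mechanism (subset scoring + weighting), not performance on any particular
real dataset; real tabular data enters through the CSV loader and LOOCV
machinery instead.

Test sets are independent fresh draws from the same configuration.  For the
scaled benchmark reproductions, training and test sizes default to 1,000
instances per class and mean rates are taken over 5 independent replicates —
sizes chosen to keep each scenario at a couple of minutes on one CPU while
holding the binomial standard error of each rate near 0.005.

## Evaluation machinery

Misclassification rate is the plain mismatch fraction.  The Matthews
correlation coefficient uses the generalized (Gorodkin) multiclass form from
the full confusion matrix, defined as 0 when a marginal degenerates.
Leave-one-out CV refits the *entire* pipeline (precompute, subset sampling,
scoring, selection, weighting) on every fold, with a per-fold child seed
derived from the master seed so folds are reproducible and independent; it
requires every class to have ≥3 members so that each fold's training classes
keep the ≥2 the precompute needs.  The comparison driver pits RkCNN against
thin in-repo baselines: plain kNN (scikit-learn), plain kCNN, and "RkNN" —
an unweighted majority vote of kNN over r random subsets, a reference
reimplementation for context rather than a faithful reproduction of any
published variant.  Per-replicate raw metrics are retained alongside the
mean summary so dispersion can be inspected or exported for external
significance testing.

## Numerical choices

- Distances use the Gram-matrix expansion ||a−b||² = ||a||²+||b||²−2aᵀb with
  clipping at 0; exact duplicates still yield exactly 0, which triggers the
  zero-distance probability rule (mass split uniformly over zero-distance
  classes — the limit of the inverse-distance formula).
- Distance ties at rank k use the k-th order statistic of the distance
  multiset: deterministic and permutation-invariant.
- Subset selection sorts by score descending with ties kept in sampling
  order (stable); +∞ sorts first.
- When one retained subset spans all q features the original (uncopied)
  arrays are used, making the m=q, h=r=1 configuration bit-identical to
  plain kCNN.

## Known limitations

- Prediction cost is O(r · t · n · m) per test batch; no approximate-NN
  index is used (one would have to preserve exact results per subset).
- The score-based weighting assumes at least one sampled subset carries
  signal; in pure-noise data all scores are small and weights approach
  uniform, reducing RkCNN to an unweighted subset ensemble.
- The weight denominator runs over the retained r scores only (as the
  algorithm specifies), not over all h — weights are relative within the
  retained pool.
- Class-probability calibration is not studied; probabilities are ensemble
  averages of inverse-distance ratios, not calibrated posteriors.
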