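# Methods

This note documents the models, the numerical choices, and the design
decisions behind `ppnet`, in the order the pipeline executes them.

## Individual networks

An individual network (IN) assigns a per-sample weight to each edge of a
shared edge set over a fixed node (feature) list.

*Node Product.* Features are min-max scaled per column on the training
data, `i' = (i − min i)/(max i − min i)`; a test sample is scaled with the
**training** minima/maxima and clipped to [0, 1], which prevents
information leakage and keeps products bounded. The edge weight is the
product of its endpoints' scaled values, hence in [0, 1] and zero whenever
either endpoint is at its training minimum.

*LIONESS.* The aggregate co-expression model (Pearson correlation between
feature columns; any symmetric edge function can be plugged in) is fitted
on all N training samples and on every leave-one-out panel; the IN of
sample x is `N(e^α − e^(α−x)) + e^(α−x)`. The construction is exact for
mean-type aggregates — `N(S/N − (S − m_x)/(N − 1)) + (S − m_x)/(N − 1) =
m_x` — which the tests use as a machine-precision oracle. Leave-one-out
requires N ≥ 4 so every aggregate still sees ≥ 3 samples.

*Test protocol.* A new sample's IN depends on the reference panel. Each
test sample is therefore appended **alone** to the training panel, all
N+1 INs are recomputed in that temporary panel, and the test sample's
similarities to the *refreshed* training INs are taken from it. Processing
one sample at a time keeps the training panel's internal relations intact.

*Scaling.* Train IN weights are mapped to [0, 1] by a single affine map
using the global minimum and maximum across **all** training INs, so the
ordering of weights is preserved between individuals. Test INs reuse the
training bounds and are clipped; clipping keeps the scaled-weight
invariant at the cost of saturating weights outside the training range,
which is the standard trade-off for out-of-range test data.

## Feature selection

Nodes: largest training standard deviation, ties broken lexicographically
(determinism). Edges: per-class *condition networks* are built on each
class's training samples — by default the class mean of Node Product
networks (the cheap construction also used for selection), optionally the
within-class Pearson correlation — and an edge is kept when the absolute
between-class difference strictly exceeds the `t_edge` quantile of all
candidate differences. "Keep above the quantile" makes `t_edge = 0.25`
the loosest threshold (≈ 75 % of edges kept) and nests the selected sets
across thresholds. Both knobs are tuned together by stratified 5-fold CV
on the training set, scoring macro F1 of the fast Node Product edge
pipeline (C fixed to 100 inside the inner loop to keep tuning cheap); ties
prefer smaller node counts, then smaller thresholds.

Selection uses training data only; the pipeline tests assert that test
matrices never enter any selection computation.

## Person-to-Person networks

Node level (raw feature values):

- **affinity** — scaled exponential similarity `exp(−d²/(2(σ·ε)²))` with
  the local bandwidth `ε_xy = (knn̄_x + knn̄_y + d_xy)/3`, `knn̄` the mean
  distance to the K nearest neighbours. Defaults K = 20, σ = 0.05.
- **gaussian** — `exp(−d²/σ²)`, default σ = 1000.
- **spearman** — rank correlation between the two samples' feature
  vectors (average ranks on ties); entries may be negative and are kept.

Edge level: the edge-difference distance between two INs is the Frobenius
norm of the difference of their full symmetric adjacencies,
`sqrt(2 Σ_e (w_a − w_b)²)` (each undirected edge contributes twice). It is
a true metric on the shared edge set, which the tests verify on random
triples.

**Distance-to-similarity conversion and bandwidths.** The fixed bandwidths
σ = 0.05 and σ = 1000 are tied to the measurement scales of the cohorts
they were originally tuned on. On data whose pairwise distances
concentrate — which is the norm for high-dimensional vectors, including
this package's Gaussian simulations, where d/ε ≈ 1 for essentially all
pairs — `exp(−d²/(2(0.05·ε)²)) ≈ e^{−200}` and the affinity matrix
collapses numerically to the identity; likewise `exp(−d²/1000²) ≈ 1`
collapses to the all-ones matrix. A kernel SVM fed either matrix predicts
a constant class. The package therefore:

- keeps the printed values as the *function-level* defaults of
  `affinity_ppn` and `gaussian_ppn`;
- converts edge distances to similarities with an **adaptive Gaussian**
  kernel `exp(−d²/s²)`, `s²` = mean squared training distance (computed
  on train, reused on test); the affinity and negative-distance
  conversions remain available via `edge_ppn(similarity=...)`;
- defaults `run_pipeline` to `sigma_affinity = 0.5` (the mid-range the
  affinity kernel's origin recommends) and `sigma_gaussian = "auto"`
  (root-mean-square pairwise train distance). Both accept explicit
  values, so the printed constants can be restored for data on the scales
  they came from.

Normalization divides by the square root of the two self-similarities,
giving unit diagonal on square PPNs; rectangular test-by-train PPNs use
each test sample's own self-similarity (exactly 1 for all exponential
kernels and for Spearman). Node- and edge-level PPNs are combined by
elementwise averaging **after** normalization so both live on comparable
scales.

## Fusion and classification

- *Early*: per-modality node selection, then column concatenation with
  modality-tagged feature IDs (`rna:GENE1`), so downstream edge selection
  can pair features across modalities.
- *Intermediate*: elementwise average of the per-modality normalized
  PPNs, or similarity network fusion — per view a row-stochastic full
  kernel (off-diagonal mass 1/2, diagonal 1/2) and a row-normalized
  K-nearest-neighbour kernel S; update `P_v ← S_v · mean(P_w≠v) · S_vᵀ`
  with renormalization and symmetrization each step, 20 iterations with
  early stop below 1e-8 max-norm change, output the symmetrized mean of
  the final views. SNF is defined on square matrices; the rectangular
  test-by-train side of an SNF run is fused by averaging the per-view
  normalized test PPNs, a deliberate simplification recorded here because
  cross-diffusion has no canonical out-of-sample extension.
- *Late*: per-sample majority vote over the four outcomes
  {node, edge} × {modality a, modality b}; exact ties are resolved
  uniformly at random from the run's seeded stream. The per-modality
  *contribution* is the frequency with which its prediction matches the
  final one, tied samples excluded. Late fusion of a single modality, or
  of a pure node or edge level, adds no information and is rejected as an
  undefined combination.

Classification is an SVM on the precomputed similarity matrix. Spearman,
combined and fused PPNs can be indefinite, and kernel-solver behaviour on
indefinite matrices is implementation-dependent, so the training kernel is
repaired by clipping negative eigenvalues at zero; the associated spectral
filter `U diag(λ⁺/λ) Uᵀ` is applied to test rows so train and test live in
the same repaired space. The repair is the identity on PSD inputs
(tested). C is selected from {10ᵏ, k = 1…5} by stratified 5-fold CV macro
F1 on the training kernel (an inner CV rather than training-set
performance, the defensible reading when tuning and evaluation would
otherwise share data); ties go to the smallest C. libsvm iterations are
capped at 10⁵ to bound worst-case fits; well-posed problems converge far
below the cap. Multiclass would be one-vs-one on the kernel, but the
tested path is binary, matching the use cases the workflow targets.

Macro F1 is the unweighted mean of per-class F1 with F1 = 0 for a class
with no true and no predicted positives.

## Differential co-expression and enrichment

The edges × samples weight matrix is analysed edge-wise: a two-group
linear model gives the coefficient β (second minus first group mean,
groups in lexicographic order), residual variance s² on d = n₁+n₂−2
degrees of freedom. The empirical-Bayes squeeze uses the scaled-F
hierarchy: log s² has digamma/trigamma moments, so matching its observed
mean and variance yields the prior (d₀, s₀²) (trigamma inverted by Newton
iteration; d₀ = ∞ when the observed spread does not exceed the
equal-variance expectation). Posterior variance
`s̃² = (d₀s₀² + d s²)/(d₀ + d)`, moderated t = β/(s̃·√(1/n₁+1/n₂)) on
d₀+d degrees of freedom, two-sided p, Benjamini–Hochberg adjustment
(labelled as such in the output; other corrections could be slotted in).
`prior_df=0` recovers the ordinary two-sample t exactly. The same
function applied to a genes × samples expression matrix gives the
node-level statistics. The implementation is cross-checked in the test
suite against the reference empirical-Bayes implementation in R.

The top-50 edges (by |moderated t|) define a graph whose edge colour key
is the sign of β, edge width |β|, and node colour the node-level moderated
t masked to neutral below |t| = 1.5. The largest connected component
(ties broken toward the lexicographically smallest member) supplies the
ranked gene list for enrichment.

Preranked enrichment walks the ranking in decreasing order of the signed
statistic; hits accumulate |t|¹/Σ|t| (weighting exponent 1, configurable)
and misses subtract 1/(N−N_h); the enrichment score is the signed extremum
of the running sum. The null permutes gene labels (equivalently, draws
random hit-position sets of the same size; extrema occur only at hit
positions, which the permutation code exploits). p-values and NES are
sign-stratified; the FDR q is the ratio of permutation to observed NES
tail frequencies, clipped to [0, 1]. Sets smaller than `min_size` after
intersection with the ranking are dropped.

## The synthetic data generator

`simulate_dataset` draws class-conditional multivariate Gaussians with
three orthogonal levers: a mean shift on `n_shift` designated features of
the first class (node signal), a class-specific equicorrelated block of
`block_size` features (edge signal; equicorrelation keeps the covariance
positive definite for ρ > −1/(b−1), checked by factorization), and an
optional latent factor shared between modalities that adds cross-modality
block correlation of the same strength. Defaults: 30 features per
modality, block 10, shift on 10 disjoint features, unit noise. The
fixture suite pins the study conditions used by the tests:
`node_signal_only` (shift 2.0), `edge_signal_only` (ρ 0.8 vs 0.0, zero
shift), `both_signals` (both, shared factor), `null` (neither), with
150/50 train/test samples per class (60/40 for `null`).

With two balanced classes a symmetric mean shift leaves the per-sample
correlation contributions identical in both classes, and a correlation
difference leaves the means identical — so node-level pipelines are blind
to `edge_signal_only` and LIONESS edge-level pipelines blind to
`node_signal_only`, which is exactly the contrast the acceptance tests
measure.

What the generator does **not** emulate: count-distribution noise of
RNA-Seq, batch effects, heavy-tailed or skewed features, the geometry of
real histology embeddings, or label noise. Passing tests show that the
pipeline recovers the kind of signal each level is designed for and stays
at chance under the null; they do not certify performance on real
cohorts.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: ≤ 300 training
samples, ≤ 60 features per modality, 435 candidate edges, 500
permutations for enrichment checks — sizes chosen so the signal/noise
regimes of interest are clearly expressed while the whole suite completes
in minutes on one CPU. All randomness flows from explicit integer seeds
(dataset generation, CV splits, tie-breaking, permutation nulls);
identical configuration and seed reproduce byte-identical prediction and
metrics files, which is asserted in the tests.

## Known limitations

- Edge selection is defined for exactly two classes (the difference of
  two condition networks); multiclass edge selection needs new rules.
- The SNF out-of-sample side uses view-averaged test PPNs (see above).
- Moderated-t models edge weights as conditionally Gaussian; Node Product
  weights live in [0, 1] and are only approximately so. Under the null
  the p-values are uniform in practice (KS-tested), but heavy selection
  upstream of the test (edges chosen by between-class difference) biases
  them by construction — interpretation runs should use a class-blind
  edge set or treat the ranking, not the p-values, as primary.
- The enrichment FDR follows the sign-stratified NES procedure, which is
  approximate for few sets; with very few gene sets the permutation p
  with BH adjustment is the safer quantity.
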