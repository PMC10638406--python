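# ppnet

Graph-based integration of multi-modal patient data for subtype
classification. `ppnet` builds **individual networks** (INs) — per-sample
weighted graphs whose nodes are molecular or image-derived features — turns
them into **Person-to-Person Networks** (PPNs, sample-by-sample similarity
matrices), fuses data modalities early, intermediate or late, classifies
samples with a similarity-matrix SVM scored by macro F1, and interprets the
result through edge-level differential co-expression and gene-set
enrichment.

The package is aimed at computational biologists who want to ask whether
*interactions between features* (co-expression edges) carry class
information beyond the feature values themselves — e.g. for cancer subtype
or severity prediction from RNA-Seq plus histopathology embeddings.

## The model in brief

**Individual networks.** For sample *x* with min-max-scaled feature values
*i′ˣ*, the *Node Product* network sets the weight of edge (i, j) to

    e_ij^x = i'^x · j'^x

The *LIONESS* network linearly interpolates an aggregate co-expression
model (Pearson correlation by default) fitted on all N samples (`e^α`) and
on all samples but x (`e^(α−x)`):

    e_ij^x = N (e_ij^α − e_ij^(α−x)) + e_ij^(α−x)

For any aggregate that is a per-sample mean, this identity returns the
sample's own contribution exactly — the module's primary correctness
oracle. Unseen samples are handled by appending one test sample at a time
to the training panel and recomputing all N+1 networks in that temporary
panel.

**Person-to-Person networks.** At the node level, sample similarity is a
scaled-exponential affinity kernel (K = 20, σ = 0.05), a Gaussian kernel
(σ = 1000), or the Spearman correlation between feature vectors. At the
edge level, individual networks are compared with the *edge-difference
distance* — the Frobenius norm of the difference of their adjacency
matrices, `sqrt(2 Σ (w_a − w_b)²)` — and distances are converted to
similarities (adaptive Gaussian kernel by default). Every PPN is
normalized as

    PPN(x, y) / sqrt(PPN(x, x) · PPN(y, y))

**Selection.** Nodes are ranked by training standard deviation (grid
100…1400); edges by the absolute difference between condition-specific
(per-class) networks, thresholded at the 0.25 / 0.5 / 0.75 quantile; both
are tuned by stratified 5-fold CV of the fast Node Product path on macro
F1.

**Fusion and classification.** Early fusion concatenates per-modality
selected features (edges may then link features of different modalities);
intermediate fusion averages per-modality PPNs or merges them by
similarity network fusion (iterative cross-diffusion); late fusion takes a
seeded majority vote over the node/edge × modality prediction quartet. An
SVM operates directly on the (PSD-repaired) similarity matrix; the cost C
is chosen from {10¹…10⁵} by stratified CV, and performance is the macro F1
score `(1/L) Σ_l F1_l`.

**Interpretation.** Edge weights across samples form an edges × samples
matrix; per-edge two-group linear models with empirical-Bayes variance
moderation yield moderated t-statistics (BH-adjusted). The top-50
differential edges define an annotated network; genes of its largest
connected component are ranked by node-level moderated t and tested for
gene-set enrichment with a weighted running-sum statistic (min size 10,
5000 permutations, permutation p, sign-stratified NES and FDR).

Because real cohorts are not bundled, `ppnet.simulate` generates
two-modality Gaussian datasets in which class signal lives in feature
means (node level), in a correlated block (edge level), in both, or in
neither — which makes the central claim (edges carry information nodes do
not) directly testable.

## Worked example

```python
from ppnet import fixture_suite, run_pipeline, SelectionParams

train, test, y_train, y_test = fixture_suite(1)["edge_signal_only"]
sel = SelectionParams(n_nodes=30, t_edge=0.5)
edges = run_pipeline({"rna": train["a"]}, {"rna": test["a"]}, y_train, y_test,
                     level="edges", edge_method="lioness", selection=sel, seed=1)
nodes = run_pipeline({"rna": train["a"]}, {"rna": test["a"]}, y_train, y_test,
                     level="nodes", node_similarity="spearman", seed=1)
print(f"edge-level macro F1: {edges.metrics.macro_f1:.3f}")
print(f"node-level macro F1: {nodes.metrics.macro_f1:.3f}")
```

prints

```
edge-level macro F1: 0.849
node-level macro F1: 0.520
```

The fixture has **zero mean shift** between classes; the only signal is a
correlation block present in one class (ρ = 0.8 vs 0.0). Node-level
similarity cannot see it (macro F1 ≈ chance), while the LIONESS
edge-level pipeline recovers it (macro F1 0.85, per-class F1 0.86 / 0.84).
On the complementary `node_signal_only` fixture the ordering reverses.

The same workflow is available from the shell:

```sh
ppnet --seed 1 simulate --preset edge_signal_only --out data/
ppnet classify --config run.yaml
```

with `simulate`, `select`, `networks`, `ppn`, `fuse`, `classify` and
`interpret` subcommands (see `ppnet --help`).

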