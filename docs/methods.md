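# Methods

This note documents the models, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Curation and molecule handling

A molecule enters the pipeline through `parse_and_canonicalize`: the
largest fragment (by heavy-atom count, ties broken by molecular weight and
then lexicographic canonical SMILES, so curation is deterministic) is kept,
stereochemistry is preserved through canonicalization, and a descriptor
snapshot is computed on that fragment. Library curation keeps molecules
with molecular weight ≤ 600 Da, ≤ 5 hydrogen-bond donors, ≤ 10 acceptors
and ≤ 10 rotatable bonds (all inclusive). For per-target activity tables
the weight filter is applied first and tables left with fewer than 50 rows
are then rejected — in that order, so a table can fail because the filter
shrank it. Duplicate detection happens post-canonicalization.

## The three views

**Graph.** Hydrogens are implicit; the heavy-atom graph is stored with each
bond once. Nodes and edges are tokens: five categorical features each,
embedded per feature (width = token width / 4, i.e. 128 at the default
512-D token width), concatenated and projected to the token width. Nodes
and edges share the transformer and are distinguished by a learned type
embedding. Spectral positional encoding uses the k (default 8) smallest
eigenpairs of the combinatorial Laplacian `L = D − A`: eigenvalues in
stable ascending order, each eigenvector's sign fixed by making its first
component of magnitude > 1e-10 positive, zero-padding when `|V| < k`. A
node token takes its own eigenvector row; an edge token takes the mean of
its two endpoints' rows, which is invariant to endpoint order.

**Image.** Depictions are rendered at 256×256 on a white background with
standard 2D coordinates, then cropped to 224×224 — centrally in eval mode,
randomly (plus a 50% horizontal flip) under a seed in train mode — and
normalized per channel with fixed constants (mean 0.95, sd 0.15 on the
[0, 1] scale; depictions are mostly white background, hence the means near
one). The same (molecule, mode, seed) always yields bit-identical pixels.

**Text.** The regex tokenizer splits SMILES into bracket atoms, two-letter
elements, aromatic atoms, bonds, ring/branch symbols and `%nn` ring
closures; the concatenation of tokens always equals the input, and
unrecognized characters become single-character unknown tokens with a
warning rather than a failure. The documented pattern is
`views.SMILES_TOKEN_PATTERN`; it is tested by round-trip on every generated
molecule but no claim is made that it is identical to any other published
tokenizer. Vocabularies are a frozen seed list of common organic-chemistry
tokens plus corpus-derived tokens appended in discovery order, with
reserved pad/mask/unknown/begin/end entries.

## Self-supervision targets

Token masking (default 15%), graph-feature masking (default 85%, drawn
jointly over node and edge tokens) and edge corruption (default 15%, one
endpoint rewired to a uniformly chosen different node, edge features
unchanged) are all deterministic given their seed. Counts use
nearest-integer rounding of `rate × n` with exact ties rounded **down**:
with drug-like molecules averaging ~12 edges, rounding ties up would pin
every 10-edge molecule at 2 corrupted edges (20%) and bias the pooled rate
to ~16%; ties-down keeps pooled rates within a percentage point of nominal
while leaving all half-integer-free cases untouched. Masked graph features
are replaced by a per-feature sentinel embedding index (not randomized).

Betti targets: for each atom, the induced subgraph on nodes within k hops
(default k = 2 — local enough to keep targets node-specific, wide enough to
see ring closure at k ≥ 3 for six-rings) gives `β0` by component counting
and `β1 = |E| − |V| + β0`. When used as classification labels the values
are clipped at a configurable maximum class (default 8); raw values are
always retained. Whether the prediction head treats them as regression or
classification is left to the consumer; both labelings are emitted.

## Encoders

All encoders are pure functions of (input, parameters); identical seeds
give identical parameters and repeated calls are bit-identical. Desk-scale
defaults are depth 2, 4 heads, output width 256; the full-scale token
widths (512 graph / 768 text) are the config defaults for embedding width,
and `EncoderConfig` documents how to scale any of this up or down. Pooling
is masked mean pooling (a CLS-style pooling token would work equally; mean
was chosen for permutation symmetry of the graph token sequence). The image
encoder applies a fixed 8× average-pool stem (224 → 28) before two strided
convolutions around a residual block — at desk scale the depiction's
information content survives the pooling, and it keeps cached features and
compute small.

Attention extraction: for transformers, last-layer attention probabilities
averaged over heads and over the (real-token) queries that feed the mean
pool, renormalized over real tokens; for the CNN, the channel-mean
activation magnitude of the final feature map normalized over spatial
cells. Both give nonnegative weights summing to one.

## Gated late fusion

The aggregator computes per-view gate scores
`w_m = (1/B) Σ_i qᵀ tanh(W z_im/‖z_im‖₂ + b)`, `α = softmax(w)` (no
temperature), and `z_mv = MLP(Σ_m α_m z_im)` with a two-layer MLP (hidden
width = embedding width, tanh). The L2 normalization makes α invariant to
per-sample embedding scale; the batch mean makes it invariant to batch
order; softmax shift invariance means only score differences matter. A
zero-norm embedding is an explicit error, not a silent epsilon.

Because `w` is a batch statistic, single-molecule inference would depend on
batch composition. Trained models therefore freeze `w` at the running mean
recorded over the final training epoch (restored alongside the best early-
stopping state), making inference deterministic and batch-independent.

Aggregator reconstruction pre-training attaches one linear head per view
mapping `z_mv` back to that view's input embedding under summed per-view
mean squared error. At full scale this ordering of reconstruction
difficulty produced reference gate weights of 0.6/0.3/0.1
(image/graph/text); those constants are recorded in
`fusion.ALPHA_PRETRAIN_REFERENCE` for comparison only — reproducing them
requires corpus-scale pre-training and is out of scope. The desk-scale
default is thousands of triples, where the qualitative behavior (an
uninformative view receives the smallest α) is reproduced and tested.

## Splits, fine-tuning and metrics

Scaffold clustering keys molecules by Bemis–Murcko framework; acyclic
molecules form one singleton cluster per unique molecule, so scaffold-free
chemotypes are representable and the leakage guarantee (no cluster spans
two partitions) is meaningful for them too. Size-ordered splitting assigns
clusters in descending size, filling train to capacity, then validation,
then test (ties on equal size broken by the cluster key, so assignment is
deterministic). Balanced splitting forces clusters larger than the
test-partition target into train and shuffles the remaining clusters into
test, then validation, then train under the seed. A single-scaffold dataset
yields a valid assignment with an explicit warning that test may be empty.

Fine-tuning trains encoders, aggregator and head jointly with Adam and up
to four parameter groups (one learning rate per encoder plus one for
aggregator + head), early stopping on the validation metric (ROC-AUC for
classification, RMSE for regression) with patience 10 and a 100-epoch cap
by default, and reports held-out metrics over n seeds (default 5) as mean
with a 1.96·SEM 95% confidence interval; the reported model instance is the
highest validation performer across seeds. Losses are binary cross-entropy
and mean squared error.

Regression metrics can be rescaled for cross-dataset comparison by
`m′ = 1 − (m − m0)/s` with the registry pairs ESOL (0.7, 1.0), FreeSolv
(1.5, 5.0), Lipophilicity (0.50, 1.0), QM7 (55.0, 100.0) and
ComputationalADME (0.30, 1.0); the transform is affine and invertible.
Model agreement uses the asymmetric F1 of one model's 0.5-binarized
positives predicting the other's for classification, and Pearson r with a
χ²-based p-value (statistic `n·r²`, 1 dof) for regression.

## Drug–target interaction head

Ligand and protein embeddings are projected to 64-D each (tanh),
concatenated to 128-D and passed through a 2-layer regression head. Protein
embeddings are consumed as input tables (id → vector); computing them is
out of scope and tests use synthetic Gaussian (optionally exact low-rank)
matrices. Cross-validation is sixfold: pairs are shuffled once into six
near-equal folds; round k tests fold k, validates on fold k+1 (mod 6) and
trains on the rest, so every pair is tested exactly once. "Gradual
unfreezing" is implemented as staged training — head-only for the first
epochs (default 10), then all parameters — with the best validation state
restored per fold. Reported statistics are arithmetic means over folds.

## Synthetic data: what it emulates and what it does not

The generator decorates 12 drug-like ring-system templates with 19 common
organic substituents at two sites, canonicalizing and deduplicating, with
stratified sampling so every scaffold is represented. For the
substructure-classification rule, positives carry an aromatic nitro group
attached directly or through short linkers (methyl, ethyl, phenyl) so both
classes exist on every scaffold and class prevalence is controlled exactly.
Descriptor-regression labels are a fixed linear map of (MW/100, donors,
acceptors, rotatable bonds, heavy atoms/10) plus Gaussian noise — exactly
recoverable at zero noise. Latent-affinity labels are pKI-like values in
[4, 9] driven by fragment content. Drug-likeness filtering retains ≥ 95% of
generated molecules by construction.

These libraries emulate the *structure* of small assay datasets — scaffold
clustering, substructure-determined activity, descriptor-linear trends —
but not the property distributions, assay noise, activity cliffs or label
imbalance of real screening data. Passing the end-to-end tests shows the
pipeline can extract a recoverable structural signal through each view and
through fusion; it does not certify benchmark-level accuracy on real
datasets, which additionally requires corpus-scale pre-training.

## Problem sizes and numerical conventions

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which each claim is statistically
meaningful: 2,000-molecule libraries (5 seeds) for the substructure task
with 16-D encoders of depth 1; 10,000 generated molecules for pooled
masking rates; 500 random graphs (≤ 20 nodes) for the topology oracles; 100
seeded datasets for split integrity; 600 ligand–protein pairs for the DTI
recovery. Tolerances: exact integer agreement for topology; 1e-10 for the
fusion arithmetic against hand evaluation; 1e-8 for zero-eigenvalue
multiplicity; one percentage point for pooled masking rates. Degenerate
inputs are handled explicitly: empty molecules and empty batches are
errors, single-atom molecules and single-view fusion are valid, all-one-
class agreement inputs are flagged, and training divergence (non-finite
loss) raises rather than clipping silently.

## Known limitations

* No 3D conformer view; all views derive from 1D/2D structure.
* The NumPy engine is single-threaded float64; it is sized for desk-scale
  experiments, not corpus-scale pre-training.
* The image augmentation pipeline covers crop/flip only; the broader family
  of image pretext tasks is intentionally out of scope.
* Betti targets use induced k-hop subgraphs; other neighbourhood
  definitions (edge-ball, non-induced) would give different `β1` profiles.
* The regex tokenizer covers standard organic SMILES; exotic inorganic
  strings fall back to unknown tokens.
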