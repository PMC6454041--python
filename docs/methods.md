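# Methods

## Problem setting

Given an undirected PPI network over gene identifiers and a set of genes
known to be associated with a disease, rank every other gene in the network
by how likely it is to be associated with the same disease. The working
hypothesis is guilt by association: disease genes aggregate in network
neighborhoods, so network proximity — captured either directly (diffusion,
path lengths) or through a learned embedding — is the predictive signal.

## Pipeline model

### Biased second-order walks

The walker's next step from node *v*, having arrived from *t*, weights each
neighbor *x* of *v* by `α_pq(t,x) · w_vx`, where α is 1/p when x = t
(backtrack), 1 when x is also adjacent to t, and 1/q otherwise (outward
move). Because x is a neighbor of v, the t–x shortest distance can only be
0, 1 or 2, so α is computed locally from the previous node's neighbor set —
no per-step BFS. The very first step of a walk has no previous node; it
uses the plain first-order distribution `w_vx / Σ w`. Walks start
`walks_per_node` times (default 10) from every node in sorted order, run
for `walk_length` nodes (default 80), and share one seeded random stream,
so a (graph, parameters, seed) triple determines the corpus byte for byte.
Isolated nodes yield single-node walks. Default bias parameters are p = 2,
q = 0.1 (a DFS-leaning regime that samples community-scale structure);
both are exposed in configuration and swept by `n2asvm evaluate --sweep`.

Categorical sampling uses Vose's alias method (O(1) per draw after O(deg)
setup); transition distributions are built on the fly rather than
precomputed per edge pair, which is the right trade at the network sizes
this package targets.

### Skip-gram embedding

(center, context) pairs are all positions at distance ≤ `window` (default
10) within a walk. The objective per pair is the standard negative-sampling
one, `log σ(u_c·v_o) + Σ_k log σ(−u_c·v_nk)`, with `negatives` = 5 noise
draws from the unigram distribution raised to 0.75. Input vectors start
uniform in ±0.5/dim, context vectors at zero; SGD with a linear
learning-rate decay from 0.025 to 0.00025 over the full pair stream;
training is single-threaded and JIT-compiled, with its own deterministic
xorshift generator, so fixed seeds give identical matrices. No
frequent-token subsampling is applied: walk corpora visit nodes far more
uniformly than natural text, and dropping it keeps training exactly
reproducible. The input (center) vectors are the exported representation.
The per-epoch mean loss is recorded; it must not increase from first to
final epoch, which the tests assert.

### Autoencoder

Encoder widths are given as a strictly decreasing list from the input
dimension n to the code m (defaults 512 → 200); the decoder mirrors them.
Hidden and code layers use a sigmoid by default (identity/relu/tanh
available); the output layer is identity so reconstructions live on the
input scale. The loss is the mean over rows of ‖x − z‖², minimized by plain
mini-batch gradient descent (batch 32, learning rate 1e-3, 200 epochs,
Glorot-uniform initialization from the seeded stream). Plain SGD was chosen
over adaptive optimizers deliberately: it is deterministic, dependency-free
and easy to reason about, and the code layer — not the loss value — is the
product. A per-column standardization flag exists but is off by default.

In the identity-activation regime the global optimum of this objective is
rank-m principal-component truncation, which gives an external correctness
oracle: on noise-free rank-4 data in 32 dimensions the trained linear
autoencoder reaches reconstruction MSE ~1e-29 — at the PCA floor — and the
acceptance suite asserts it lands within 10% of the eigendecomposition
truncation error. Non-finite loss aborts training with the epoch reported.

### Classification, evaluation, ranking

Positives are the known disease genes present in the network; negatives are
a uniform, seeded, equal-size sample of the remaining genes (a fresh draw
per repetition in the evaluation runner, 10 repetitions by default, since a
single draw is high-variance). The classifier is an SVM (RBF kernel, C = 1,
gamma by the variance-scaling rule; all configurable). Evaluation is
stratified ten-fold cross-validation — stratification avoids single-class
folds at these sample sizes — and the metric is the Mann–Whitney AUROC with
ties counted 1/2, implemented by midranks and verified against brute-force
pair counting. For ranking, the SVM is refit on all labeled genes inside a
cross-validated sigmoid (Platt) calibration wrapper, and unlabeled genes
are sorted by calibrated probability with lexicographic id tie-breaking.

### Baselines

* **RWR** — the diffusion state π of a seed gene is the fixed point of
  π = r·e_s + (1−r)·Wᵀπ with W the row-normalized adjacency, solved by
  power iteration to an L1 tolerance of 1e-10 and checked against a direct
  linear solve. Restart probability defaults to r = 0.5. A candidate's
  score is the mean, over seed genes other than itself, of the seed's
  diffusion state at the candidate. The full diffusion-state matrix (one
  row per gene) is also the feature input of the `rwa-svm` variant.
* **SPL** — negated mean breadth-first shortest-path length from the
  candidate to the positives (candidate excluded when itself positive);
  positives outside the candidate's component contribute the component
  diameter + 1, keeping scores finite and rank-meaningful.
* **ED** — negated mean Euclidean distance between binary adjacency rows
  (an embedding matrix may be substituted via the API).

All scores are oriented so larger = more disease-like, making every method
directly comparable under the same AUROC.

## Synthetic fixture

`synthetic.planted_partition` samples a stochastic block model: blocks of
60/120/120 genes, within-block edge probability 0.15, between-block 0.01.
Block 1 acts as the disease module; 30 of its genes are revealed as
positives and the remaining 30 are held out as ground truth for ranking
experiments. These sizes keep a full pipeline run in tens of seconds while
leaving enough positives for stratified ten-fold splits. The generator's
block structure demonstrably carries community signal (its modularity beats
degree-preserving rewired controls), and walk embeddings separate the
blocks linearly.

For this 300-node fixture the evaluation and acceptance runs use
embedding dimension 64 and code dimension 16 — scaled-down analogues of the
512/200 defaults appropriate to a graph this size; the interactome-scale
defaults remain in the configuration for real inputs.

**What the fixture does not show.** A planted-partition block is small,
dense and homogeneous; real interactomes are sparse, scale-free and
heterogeneous, with disease modules that are far less clean. One visible
consequence: on the fixture, plain adjacency distance (ED) is already an
excellent scorer — same-block genes share most of their neighbor sets — so
the embedding variants do not dominate the baselines here the way they are
expected to on a 13k-node interactome where adjacency rows of related genes
barely overlap. Passing the fixture tests validates the machinery
(correct transition rule, faithful training, leak-free cross-validation),
not the relative merits of the methods on real data.

## Numerical and design notes

* Edge lists are deduplicated keeping the first weight seen (warned);
  self-loops are dropped (the d_tx ∈ {0,1,2} logic assumes simple graphs);
  weights must be strictly positive and finite.
* Transition distributions are normalized to within 1e-12; alias-table
  construction tolerates probability sums within 1e-9.
* Stage seeds (walks, embedding, autoencoder, negative sampling, CV,
  calibration) are derived from one master seed via a keyed blake2 hash, so
  each stage is independently reproducible and no two stages share a
  stream.
* Ranking ties are broken lexicographically by gene id; duplicate-edge,
  missing-feature and overlap conditions raise typed errors naming the
  offending entity.
* Degenerate inputs: isolated candidate nodes get the restart point mass in
  RWR; an empty positive intersection with the graph, single-class AUROC
  input, and insufficient non-positives for negative sampling are all
  explicit validation errors rather than silent results.

## Limitations

* The SGNS and autoencoder trainers are single-threaded by design; exact
  determinism is traded for speed at interactome scale.
* No gene identifier normalization or cross-database mapping is provided;
  inputs must already share one identifier space.
* The autoencoder implements the plain reconstruction objective only — no
  denoising, sparsity or variational variants.
* `rwa-svm` builds the dense diffusion-state matrix (|V|² memory), which is
  practical to a few thousand nodes; the variant exists for ablation, not
  production use.
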