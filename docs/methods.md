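# Methods

## Model

The pipeline assumes that (i) genes interacting in a prior-knowledge
network tend to carry related information about the phenotype, so
informative genes come in redundant network neighborhoods, and (ii) a
panel with one representative per neighborhood classifies as well as — and
generalizes better than — a panel of marginally top-ranked genes.

Four stages implement this:

1. **Graph construction.** Nodes are the dataset's genes (sorted, so all
   derived matrices are reproducible); edges are the interaction records
   whose both endpoints are present. Isolated genes are kept by default:
   they still flow into clustering through their own expression state, and
   dropping them would silently shrink the feature space. Initial node
   states are the per-gene z-scored expression profiles (length
   n_samples); both the training similarity and the spectral kernel are
   scale-sensitive, so raw intensity units would let high-variance genes
   dominate.

2. **Neighborhood aggregation.** Each layer forms a weighted mean of the
   first-order neighborhood (edge weights normalized to sum to one per
   node — aggregation magnitudes stay comparable across nodes of very
   different degree), concatenates it with the node's own state, applies a
   linear map and a ReLU, and L2-normalizes. Zero vectors pass through
   normalization unchanged rather than raising (isolated all-zero nodes).
   Updates are synchronous (Jacobi-style): all layer-K states are computed
   from layer-(K−1) states, so results do not depend on node order.

3. **Link prediction.** Positives are the graph's edges; for each
   positive, each endpoint draws γ uniform non-neighbor partners (never
   reproducing an existing edge or a self-pair) as its negative group.
   The loss is the standard negative-sampling objective over cosine
   similarities of final embeddings. Training is full-batch gradient
   descent with hand-derived reverse-mode gradients through the
   aggregation stack (normalization, activation and weighted aggregation
   are all explicitly differentiated; a finite-difference test pins the
   implementation). Positives and negatives are split 80/20 into training
   and validation: validation edges are excluded from the loss *and*
   removed from the propagation graph during training, because an edge
   that stays in the graph directly couples its endpoints' embeddings
   through aggregation and its ranking score is then trivially high — a
   leak that makes epoch selection meaningless. The epoch snapshot with
   the best validation (or caller-supplied held-out) MRR becomes the link
   model. Ranks use competition ranking; score ties count half.
   Augmentation scores non-adjacent pairs two hops apart (all-pairs
   optional but O(d²)) and adds an edge weighted by the confidence
   σ(cosine) when it reaches θ.

4. **Spectral clustering and selection.** Embeddings are re-computed on
   the augmented graph with the trained weights — the only reading under
   which link prediction influences clustering through both the edge set
   and the states. The Gaussian kernel is evaluated densely on all node
   pairs; the symmetric normalized Laplacian's μ smallest eigenvectors
   (sign-fixed: each column's largest-magnitude entry positive) are
   row-normalized and clustered by seeded k-means++ (best of 10 restarts).
   Within each cluster genes are scored by a univariate ordinary
   least-squares fit of the label on each standardized gene; one top gene
   per cluster forms the panel. Ties break by higher expression variance,
   then lexicographic gene ID.

## Initialization

Equal-dimension layers initialize to ½[I | I] ("diffusion"
initialization); the first layer, which changes dimension, stays a
Glorot-uniform random projection (approximately distance-preserving). A
deep stack of fully random layers scrambles the input geometry — measured
on the default synthetic study, held-out ranking from a random 10-layer
stack is substantially worse than ranking from the raw states, and
gradient descent does not fully recover — whereas the untrained diffusion
stack computes a topology-aware smoothing of expression that training then
refines. Fully random initialization remains available
(`gnn.init: glorot`).

## Parameters

| key | default | meaning / rationale |
|---|---|---|
| `gnn.layers` | 10 | aggregation depth (layers of neighborhood mixing) |
| `gnn.hidden_dim` | 32 | embedding width; enough for a few hundred genes |
| `gnn.activation` | relu | {relu, sigmoid, tanh, identity} |
| `gnn.init` | diffusion | see above |
| `link.gamma` | 5 | negatives per endpoint per positive |
| `link.lr` | 0.01 | full-batch gradient step |
| `link.delta` | 1e-4 | stop when adjacent-epoch loss change falls below it |
| `link.max_epochs` | 200 | hard cap; best-MRR snapshot returned either way |
| `link.theta` | 0.7 | confidence σ(cos) needed to add an edge; σ(cos) ≤ σ(1) ≈ 0.731, so θ must stay below that to ever fire |
| `link.scope` | two_hop | candidate pairs for augmentation |
| `spectral.mu` | 5 | cluster count = panel size (user input, swept 1–15) |
| `spectral.omega` | auto | Gaussian bandwidth; auto = median pairwise distance |
| `spectral.restarts` | 10 | k-means restarts |
| `select.scorer` | linear | univariate OLS; `{"joint": true}` fits the cluster jointly with a ridge fallback when singular |
| `eval.k` | 5 | stratified CV folds |
| `eval.classifier` | svm_linear | C=1 on per-fold standardized features; rbf optional |

All stage seeds derive from the single run seed via `SeedSequence`, and a
(config, seed) pair reproduces every artifact byte for byte. Fold
assignment hashes sample IDs (stratified by class), so folds are invariant
to row order and shared across every arm of a comparison — method
comparisons are paired.

## Synthetic studies

The generator emulates a two-class expression study over a gene network:
genes partition into modules (default: half the genes in
`n_genes/(2·n_modules)`-sized modules, half background); same-module pairs
gain edges with probability 0.3, all other pairs 0.01, weights
Uniform(0.5, 1); expression is i.i.d. Gaussian noise, and the first
`informative_per_module` genes of each module shift by `effect_size`
within-class SDs between classes. Classes are balanced to within one
sample. An optional per-module latent factor (`module_factor_sd`, off by
default) adds shared co-expression; note that such factors chance-correlate
with the labels of any finite sample, which within-dataset cross-validation
rewards — redundant same-module panels then genuinely score higher on that
dataset, which is why the default model keeps noise i.i.d.

What the generator does **not** emulate: probe effects, batch effects,
heavy-tailed intensities, class-dependent variance, multiple interaction
evidence channels, or realistic network topology (edges are independent
Bernoulli draws). Passing tests therefore show algorithmic correctness and
the intended qualitative behavior (redundancy removal, link-prediction
lift), not performance on real microarray data.

`holdout_edges` splits an edge list for link-prediction evaluation,
preferring candidates whose removal isolates no endpoint (proceeding with
a warning when only isolating candidates remain).

## Numerical choices

- Cosine similarity of zero vectors is 0; similarities are clipped to
  [−1, 1] against rounding.
- −log σ(x) is computed as softplus(−x) (no overflow).
- Row normalization backward passes project out the radial gradient
  component; zero-norm rows pass gradients through unchanged.
- Laplacian assembly symmetrizes `(L + Lᵀ)/2` before `eigh`.
- k-means empty clusters (possible with duplicate embedding rows) are
  repaired by splitting the largest cluster, so exactly μ non-empty
  clusters always come back.
- Wilcoxon rank-sum p-values are exact (enumeration) for tie-free groups
  of ≤ 12, else normal approximation with tie correction; a constant gene
  reports p = 1.
- AUC uses continuous decision scores with the Mann–Whitney ½-tie
  convention; constant scores give 0.5.

## Test and script problem sizes

The end-to-end suites and `scripts/acceptance.py` use the generator's
default study (60 samples × 200 genes, 5 modules, 4 informative genes
each, effect 1.5) with 10–20 replicate seeds per property — large enough
for the planted structure to dominate sampling noise while a full pipeline
run stays in seconds.

## Limitations

- Binary labels only; multi-class selection is out of scope.
- One interaction channel; multiple evidence types are not merged.
- The augmentation threshold compares σ(cos) ∈ (0.27, 0.73), so θ outside
  that band silently means "always"/"never"; θ = 1 is the documented
  ablation switch.
- Graphs are handled densely (fine to a few thousand genes; not meant for
  whole-transcriptome × whole-interactome scales).
- Panel evaluation selects features on the full dataset before
  cross-validation, as is conventional for this family of methods; the
  accuracies are comparative, not unbiased estimates of generalization.
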