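# gnnsc — gene-network-aware biomarker selection

`gnnsc` selects small biomarker panels from expression studies (bulk
microarray or pre-aggregated single-cell matrices) that have the classic
"few samples, many genes" shape, for researchers who want a prior-knowledge
gene network — not just marginal statistics — to drive the selection.

Marginal filters (correlation, per-gene tests) rank genes independently and
happily return five near-copies of the same signal. `gnnsc` instead treats
redundancy as structure: genes that interact tend to carry the same
information, so the package groups genes along the interaction network and
takes one representative per group.

## Method

Given an expression matrix `X ∈ ℝ^{n×d}` with binary labels `y ∈ {0,1}^n`
and a weighted gene–gene interaction graph `G = (V, E)`:

1. **Message propagation.** Each gene starts from its (z-scored) expression
   profile `h⁰_v` and runs L layers (default 10) of neighborhood
   aggregation:
   `agg_v = Σ_{u∈N(v)} a_vu h_u`, with `a_vu = w_vu / Σ_{u'} w_vu'`, then
   `h_v ← σ(W·concat(h_v, agg_v)) / ‖·‖₂`. Equal-dimension layers
   initialize to ½[I | I], so the untrained stack is a lazy diffusion of
   expression over the network that training then refines.
2. **Link prediction.** Existing edges are positives; each endpoint draws γ
   random non-neighbors as negatives. The layer weights are trained by
   gradient descent on
   `L = E_{(j,r)∈Pos}[ −log σ(sim(z_j, z_r)) − Σ_{Neg} log σ(−sim) ]`
   with cosine `sim`, stopping when the loss change falls below δ; across
   epochs the snapshot with the best mean reciprocal rank
   `MRR = (1/ε) Σ 1/rank_τ` on a held-back edge set is kept. Non-adjacent
   pairs with confidence `σ(sim) ≥ θ` become new edges, giving the
   augmented graph `G*`.
3. **Spectral clustering.** A Gaussian kernel
   `w_{ρ1ρ2} = exp(−‖e_{ρ1}−e_{ρ2}‖²/2Ω²)` on the `G*` embeddings feeds the
   normalized Laplacian `L = D^{−1/2}(D−W)D^{−1/2}`; the eigenvectors of
   its μ smallest eigenvalues are row-clustered by k-means, splitting `G*`
   into μ subgraphs of mutually redundant genes.
4. **Selection & evaluation.** An embedded linear scorer ranks each
   subgraph's genes; the top gene per cluster forms the μ-gene panel,
   scored by stratified 5-fold linear-SVM accuracy, sensitivity,
   specificity and AUC.

A synthetic-study generator (`gnnsc simulate` /
`gnnsc.generate_synthetic_study`) plants informative gene modules in a
matching network so the whole pipeline is testable without any downloads.

## Worked example

```sh
$ gnnsc simulate --n-genes 200 --seed 7 --outdir demo
wrote demo/expression.tsv (60x200), demo/edges.tsv (465 edges), demo/truth.json

$ gnnsc run --expression demo/expression.tsv --edges demo/edges.tsv --seed 11 --out demo/run
selected panel (5): g041, g020, g063, g083, g002
5-fold means  acc=0.9833 sens=1.0000 spec=0.9667 auc=1.0000
artifacts in demo/run
```

The five selected genes are one per spectral cluster; here all five are
planted informative genes (`demo/truth.json` lists them), and the 5-gene
panel classifies the 60 samples at 98.3% mean cross-validated accuracy.
`demo/run/` holds `ranking.tsv` (every gene with cluster and score),
`metrics.tsv` (per-fold metrics), `train_history.tsv` (epoch, loss, MRR)
and the resolved config; reruns with the same seed are byte-identical.

Per-biomarker group statistics with Wilcoxon rank-sum tests:

```sh
$ gnnsc report --expression demo/expression.tsv --ranking demo/run/ranking.tsv
gene  mean_pos  mean_neg   sd_pos   sd_neg  rank_sum      p_value stars
g063  1.034665 -0.844609 0.992598 0.877432    1299.0 1.429417e-08  ****
g002  0.590322 -0.901377 1.162286 0.815055    1242.0 1.385252e-06  ****
...
```

`gnnsc compare` sweeps panel sizes and benchmarks the pipeline (with and
without link-prediction augmentation) against whole-matrix baseline
scorers (logistic regression, random forest, Pearson correlation, RFE).

Real studies enter as a delimited expression table (genes in columns or
rows, a label column), a 2–3 column edge list as exported from an
interaction resource such as GeneMANIA, and optionally a probe→gene map
for renaming array probe IDs.

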