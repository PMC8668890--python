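"""End-to-end orchestration and evaluation.

The pipeline runs: build gene graph → propagate → negative sampling →
link-model training (MRR-selected snapshot) → graph augmentation →
re-propagation on G* → Gaussian similarity → spectral clustering →
one-biomarker-per-cluster selection → stratified k-fold SVM evaluation.
Also here: the comparison protocol against whole-matrix baseline scorers
and the link-prediction ablation, and the per-biomarker rank-sum report.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from . import link_prediction as lp
from .config import PipelineConfig
from .data_io import ExpressionDataset, WeightedEdgeList, write_ranking
from .feature_select import FeatureRanking, ScorerSpec, score_subcluster, select_biomarkers
from .gnn import GNNParams, propagate
from .graph_build import build_gene_graph
from .spectral_cluster import (
    cluster_rows,
    gaussian_similarity,
    partition_graph,
    spectral_embed,
)

log = logging.getLogger(__name__)

__all__ = [
    "CVResult",
    "cross_validate",
    "run_pipeline",
    "compare_with_baselines",
    "biomarker_report",
    "rank_sum_test",
]


@dataclass
class CVResult:
    """Per-fold and mean classification metrics of a biomarker panel."""

    per_fold: list[tuple[float, float, float, float]]  # (acc, sens, spec, auc)
    means: tuple[float, float, float, float]
    k: int
    seed: int

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"fold": i, "accuracy": a, "sensitivity": s, "specificity": p, "auc": u}
            for i, (a, s, p, u) in enumerate(self.per_fold, 1)
        ]
        a, s, p, u = self.means
        rows.append({"fold": "mean", "accuracy": a, "sensitivity": s, "specificity": p, "auc": u})
        return pd.DataFrame(rows)

    @property
    def mean_accuracy(self) -> float:
        return self.means[0]


def _fold_assignment(sample_ids: Sequence[str], y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Stratified fold ids from a seeded hash of sample IDs.

    Hashing makes the assignment a function of the ID set, not of row order,
    so shuffling samples (or comparing methods on the same dataset) keeps
    folds identical.
    """
    folds = np.empty(len(sample_ids), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        keys = sorted(
            (hashlib.md5(f"{seed}:{sample_ids[i]}".encode()).hexdigest(), i) for i in idx
        )
        for rank, (_, i) in enumerate(keys):
            folds[i] = rank % k
    return folds


def cross_validate(
    ds: ExpressionDataset,
    features: Sequence[str],
    k: int = 5,
    classifier: str = "svm_linear",
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold SVM evaluation of a gene panel.

    Per fold: features are standardized on the training split, an SVM
    (linear kernel, C=1 by default; ``svm_rbf`` optional) is fit on the
    panel genes only, and accuracy, sensitivity (recall of class 1),
    specificity (recall of class 0) and AUC of the decision scores are
    computed. AUC follows the Mann–Whitney tie convention (constant scores
    give 0.5).
    """
    if not features:
        raise ValueError("empty feature list")
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(ds.y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs >= k={k} samples, got {counts.tolist()}")
    if classifier not in ("svm_linear", "svm_rbf"):
        raise ValueError(f"unknown classifier {classifier!r}")
    cols = [ds.gene_index(g) for g in features]
    X, y = ds.X[:, cols], ds.y
    folds = _fold_assignment(ds.sample_ids, y, k, seed)
    per_fold = []
    for f in range(k):
        test = folds == f
        train = ~test
        mu = X[train].mean(axis=0, keepdims=True)
        sd = X[train].std(axis=0, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        Xtr, Xte = (X[train] - mu) / sd, (X[test] - mu) / sd
        kernel = "linear" if classifier == "svm_linear" else "rbf"
        model = SVC(kernel=kernel, C=1.0)
        model.fit(Xtr, y[train])
        pred = model.predict(Xte)
        score = model.decision_function(Xte)
        yt = y[test]
        if len(set(yt.tolist())) < 2:
            raise ValueError(f"fold {f} contains a single class")
        acc = float((pred == yt).mean())
        sens = float((pred[yt == 1] == 1).mean())
        spec = float((pred[yt == 0] == 0).mean())
        if np.ptp(score) == 0:
            auc = 0.5
        else:
            auc = float(roc_auc_score(yt, score))
        per_fold.append((acc, sens, spec, auc))
    means = tuple(float(np.mean([m[i] for m in per_fold])) for i in range(4))
    return CVResult(per_fold=per_fold, means=means, k=k, seed=seed)


def run_pipeline(
    ds: ExpressionDataset,
    edges: WeightedEdgeList,
    cfg: PipelineConfig,
    run_dir: str | Path | None = None,
) -> tuple[FeatureRanking, CVResult, dict]:
    """Execute the full pipeline; optionally write run artifacts.

    Returns the biomarker ranking, the cross-validation result and a dict of
    intermediate artifacts (graph, train state, G*, cluster assignment).
    When ``run_dir`` is given, the resolved config, ranking, metrics and
    training history are written there (byte-identical across reruns with
    the same config and seed).
    """
    seeds = cfg.stage_seeds()
    graph = build_gene_graph(ds, edges, keep_isolated=cfg.keep_isolated, zscore=cfg.zscore)
    params0 = GNNParams.initialize(
        input_dim=graph.state_dim,
        n_layers=cfg.gnn.layers,
        hidden_dim=cfg.gnn.hidden_dim,
        activation=cfg.gnn.activation,
        seed=seeds["gnn_init"],
        scheme=cfg.gnn.init,
    )
    samples = lp.build_link_samples(graph, gamma=cfg.link.gamma, seed=seeds["link_samples"])
    state = lp.train_link_model(
        graph,
        params0,
        samples,
        lr=cfg.link.lr,
        delta=cfg.link.delta,
        max_epochs=cfg.link.max_epochs,
    )
    emb = propagate(graph, state.best_params)
    gstar = lp.augment_graph(graph, emb, theta=cfg.link.theta, candidate_scope=cfg.link.scope)
    emb_star = propagate(gstar, state.best_params)
    sim = gaussian_similarity(emb_star, omega=cfg.spectral.omega)
    se = spectral_embed(sim, cfg.spectral.mu, row_normalize=cfg.spectral.row_normalize)
    labels = cluster_rows(se, cfg.spectral.mu, seed=seeds["spectral"], restarts=cfg.spectral.restarts)
    ca = partition_graph(gstar, labels)
    scorer = ScorerSpec(name=cfg.select.scorer, params=dict(cfg.select.params), seed=seeds["select"])
    ranking = select_biomarkers(ds, ca, scorer)
    cv = cross_validate(
        ds, ranking.selected, k=cfg.eval.k, classifier=cfg.eval.classifier, seed=seeds["cv"]
    )
    artifacts = {
        "graph": graph,
        "train_state": state,
        "gstar": gstar,
        "clusters": ca,
        "seeds": seeds,
    }
    if run_dir is not None:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        (run_dir / "config.resolved.yaml").write_text(cfg.to_yaml())
        write_ranking(ranking.entries, run_dir / "ranking.tsv")
        cv.as_frame().to_csv(run_dir / "metrics.tsv", sep="\t", index=False)
        hist = pd.DataFrame(state.history, columns=["epoch", "loss", "mrr"])
        hist.to_csv(run_dir / "train_history.tsv", sep="\t", index=False)
        lines = [
            f"seed={cfg.seed}",
            *(f"seed.{k}={v}" for k, v in seeds.items()),
            f"nodes={graph.n_nodes} edges={graph.n_edges} edges_gstar={gstar.n_edges}",
            f"train_epochs={state.epoch} best_mrr={state.best_mrr:.6f}",
            f"selected={','.join(ranking.selected)}",
            f"mean_accuracy={cv.mean_accuracy:.6f}",
            *state.warnings,
        ]
        (run_dir / "log.txt").write_text("\n".join(lines) + "\n")
    return ranking, cv, artifacts


def _panel_from_scores(
    ds: ExpressionDataset, scores: dict[str, float], m: int
) -> list[str]:
    variances = ds.X.var(axis=0)
    order = sorted(
        scores.items(), key=lambda kv: (-kv[1], -variances[ds.gene_index(kv[0])], kv[0])
    )
    return [g for g, _ in order[:m]]


def compare_with_baselines(
    ds: ExpressionDataset,
    edges: WeightedEdgeList,
    cfg: PipelineConfig,
    feature_counts: Sequence[int],
    baselines: Sequence[ScorerSpec],
) -> pd.DataFrame:
    """Panel-size sweep: full pipeline vs ablation vs whole-matrix scorers.

    For each panel size m: (a) the pipeline with μ=m and augmentation on;
    (b) the same with augmentation disabled (θ=1, the link-prediction
    ablation arm); (c) each baseline scorer applied to all genes with the
    top-m taken. All arms share the same hashed fold assignment. Returns a
    long-format table (method, m, metric, value).
    """
    feature_counts = [m for m in feature_counts if m >= 1]
    skipped = [m for m in feature_counts if m > ds.n_genes]
    if skipped:
        log.warning("skipping panel sizes beyond gene count: %s", skipped)
        feature_counts = [m for m in feature_counts if m <= ds.n_genes]
    seeds = cfg.stage_seeds()
    graph = build_gene_graph(ds, edges, keep_isolated=cfg.keep_isolated, zscore=cfg.zscore)
    params0 = GNNParams.initialize(
        input_dim=graph.state_dim,
        n_layers=cfg.gnn.layers,
        hidden_dim=cfg.gnn.hidden_dim,
        activation=cfg.gnn.activation,
        seed=seeds["gnn_init"],
        scheme=cfg.gnn.init,
    )
    samples = lp.build_link_samples(graph, gamma=cfg.link.gamma, seed=seeds["link_samples"])
    state = lp.train_link_model(
        graph, params0, samples, lr=cfg.link.lr, delta=cfg.link.delta, max_epochs=cfg.link.max_epochs
    )
    emb = propagate(graph, state.best_params)
    arms = {
        "pipeline": lp.augment_graph(graph, emb, cfg.link.theta, cfg.link.scope),
        "pipeline_no_lp": graph,  # theta=1 adds nothing: sigma(sim) <= sigma(1) < 1
    }
    scorer = ScorerSpec(name=cfg.select.scorer, params=dict(cfg.select.params), seed=seeds["select"])
    rows = []
    metric_names = ("accuracy", "sensitivity", "specificity", "auc")

    for arm, g_arm in arms.items():
        emb_arm = propagate(g_arm, state.best_params)
        sim = gaussian_similarity(emb_arm, omega=cfg.spectral.omega)
        for m in feature_counts:
            se = spectral_embed(sim, m, row_normalize=cfg.spectral.row_normalize)
            labels = cluster_rows(se, m, seed=seeds["spectral"], restarts=cfg.spectral.restarts)
            ca = partition_graph(g_arm, labels)
            panel = select_biomarkers(ds, ca, scorer).selected
            cv = cross_validate(ds, panel, cfg.eval.k, cfg.eval.classifier, seeds["cv"])
            rows.extend(
                {"method": arm, "m": m, "metric": name, "value": val}
                for name, val in zip(metric_names, cv.means)
            )
    for spec in baselines:
        scores = score_subcluster(ds, ds.gene_ids, spec)
        for m in feature_counts:
            panel = _panel_from_scores(ds, scores, m)
            cv = cross_validate(ds, panel, cfg.eval.k, cfg.eval.classifier, seeds["cv"])
            rows.extend(
                {"method": spec.name, "m": m, "metric": name, "value": val}
                for name, val in zip(metric_names, cv.means)
            )
    return pd.DataFrame(rows, columns=["method", "m", "metric", "value"])


def plot_accuracy_vs_m(table: pd.DataFrame, path: str | Path) -> None:
    """Accuracy-vs-panel-size curves for every method in a comparison table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    acc = table[table["metric"] == "accuracy"]
    fig, ax = plt.subplots(figsize=(6, 4))
    for method, grp in acc.groupby("method"):
        grp = grp.sort_values("m")
        ax.plot(grp["m"], grp["value"], marker="o", label=method)
    ax.set_xlabel("panel size m (clusters)")
    ax.set_ylabel("mean CV accuracy")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum test of two samples.

    Returns (W, p) where W is the rank sum of the first sample. The p-value
    is exact (enumeration) when both groups have ≤ 12 observations and the
    data are tie-free, else a normal approximation with tie correction —
    scipy's Mann–Whitney "auto" policy, shifted to the rank-sum statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = len(x)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    w = float(res.statistic + n1 * (n1 + 1) / 2.0)
    return w, float(res.pvalue)


def _stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def biomarker_report(ds: ExpressionDataset, selected: Sequence[str]) -> pd.DataFrame:
    """Per-biomarker group statistics and rank-sum significance.

    For each selected gene: group means and SDs (class 1 = positive group,
    class 0 = negative), the rank-sum statistic of the positive group, the
    two-sided p-value and a star code (* p<0.05, ** p<0.01, **** p<0.0001).
    """
    rows = []
    for gene in selected:
        v = ds.X[:, ds.gene_index(gene)]
        pos, neg = v[ds.y == 1], v[ds.y == 0]
        if np.ptp(v) == 0:
            w, p = float(stats.rankdata(v)[ds.y == 1].sum()), 1.0
        else:
            w, p = rank_sum_test(pos, neg)
        rows.append(
            {
                "gene": gene,
                "mean_pos": float(pos.mean()),
                "mean_neg": float(neg.mean()),
                "sd_pos": float(pos.std(ddof=1)) if len(pos) > 1 else 0.0,
                "sd_neg": float(neg.std(ddof=1)) if len(neg) > 1 else 0.0,
                "rank_sum": w,
                "p_value": p,
                "stars": _stars(p),
            }
        )
    return pd.DataFrame(rows)
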