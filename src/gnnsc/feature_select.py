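"""Embedded per-cluster gene scoring and biomarker selection.

Each spectral subgraph groups genes the pipeline considers redundant; an
embedded scorer assigns every gene in a cluster a non-negative weight, and
the top-weighted gene of each cluster becomes one biomarker of the panel.
The default scorer fits an ordinary least-squares model of the label on
each standardized gene separately (a joint multivariate fit is available
via ``params={"joint": True}`` but degenerates when clusters hold more
genes than samples); the comparison scorers (logistic regression, Pearson
correlation, random-forest importance, RFE rank) are pluggable through
:class:`ScorerSpec`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression, Ridge

from .data_io import ExpressionDataset
from .spectral_cluster import ClusterAssignment

log = logging.getLogger(__name__)

__all__ = ["ScorerSpec", "FeatureRanking", "score_subcluster", "select_biomarkers", "SCORERS"]


@dataclass
class ScorerSpec:
    """Named scorer with free-form settings and a seed."""

    name: str = "linear"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in SCORERS:
            raise ValueError(f"unknown scorer {self.name!r}; registered: {sorted(SCORERS)}")


@dataclass
class FeatureRanking:
    """Full per-gene ranking plus the one-per-cluster biomarker panel."""

    entries: list[tuple[str, int, float]]  # (gene, cluster, score), score-descending
    selected: list[str]  # top gene per cluster, score-descending


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, keepdims=True)
    return np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)


def _score_linear(X: np.ndarray, y: np.ndarray, spec: ScorerSpec) -> np.ndarray:
    Xs = _standardize(X)
    if not spec.params.get("joint", False):
        # univariate default: one OLS fit of y on each standardized gene.
        # Joint fits degenerate when a cluster holds more genes than there
        # are samples, which is routine for microarray data.
        return np.abs(
            np.array([np.linalg.lstsq(np.column_stack([np.ones(len(y)), Xs[:, [j]]]),
                                      y.astype(float), rcond=None)[0][1]
                      for j in range(Xs.shape[1])])
        )
    A = np.column_stack([np.ones(len(y)), Xs])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        log.info("singular joint fit on %d gene(s); falling back to ridge", X.shape[1])
        model = Ridge(alpha=1e-3).fit(Xs, y.astype(float))
        return np.abs(model.coef_)
    coef = np.linalg.lstsq(A, y.astype(float), rcond=None)[0]
    return np.abs(coef[1:])


def _score_logistic(X: np.ndarray, y: np.ndarray, spec: ScorerSpec) -> np.ndarray:
    Xs = _standardize(X)
    model = LogisticRegression(C=spec.params.get("C", 1.0), max_iter=2000)
    model.fit(Xs, y)
    return np.abs(model.coef_[0])


def _score_corr(X: np.ndarray, y: np.ndarray, spec: ScorerSpec) -> np.ndarray:
    yc = y - y.mean()
    Xc = X - X.mean(axis=0, keepdims=True)
    denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc.T @ yc / np.where(denom > 0, denom, 1.0), 0.0)
    return np.abs(r)  # constant gene columns score 0, not NaN


def _score_rf(X: np.ndarray, y: np.ndarray, spec: ScorerSpec) -> np.ndarray:
    model = RandomForestClassifier(
        n_estimators=spec.params.get("n_estimators", 200), random_state=spec.seed
    )
    model.fit(X, y)
    return model.feature_importances_


def _score_rfe(X: np.ndarray, y: np.ndarray, spec: ScorerSpec) -> np.ndarray:
    if X.shape[1] == 1:
        return np.ones(1)
    est = LogisticRegression(max_iter=2000)
    rfe = RFE(est, n_features_to_select=1, step=1)
    rfe.fit(_standardize(X), y)
    return (X.shape[1] - rfe.ranking_).astype(float)  # rank 1 (kept last) scores highest


SCORERS = {
    "linear": _score_linear,
    "logistic": _score_logistic,
    "corr": _score_corr,
    "rf_importance": _score_rf,
    "rfe_rank": _score_rfe,
}


def score_subcluster(
    ds: ExpressionDataset, genes: Iterable[str], scorer: ScorerSpec
) -> dict[str, float]:
    """Score the genes of one cluster; all scores are non-negative."""
    genes = sorted(set(genes))
    if not genes:
        raise ValueError("empty gene set")
    missing = [g for g in genes if g not in set(ds.gene_ids)]
    if missing:
        raise KeyError(f"genes absent from dataset: {missing}")
    idx = [ds.gene_index(g) for g in genes]
    scores = SCORERS[scorer.name](ds.X[:, idx], ds.y, scorer)
    return {g: float(s) for g, s in zip(genes, scores)}


def _order_key(ds: ExpressionDataset, variances: np.ndarray):
    def key(entry: tuple[str, int, float]):
        gene, _, score = entry
        return (-score, -variances[ds.gene_index(gene)], gene)

    return key


def select_biomarkers(
    ds: ExpressionDataset, ca: ClusterAssignment, scorer: ScorerSpec
) -> FeatureRanking:
    """One top-weighted gene per cluster, plus the full score ranking.

    Ties are broken by higher expression variance, then lexicographic gene
    ID. Clusters with no gene present in the dataset are skipped with a
    warning.
    """
    variances = ds.X.var(axis=0)
    present = set(ds.gene_ids)
    entries: list[tuple[str, int, float]] = []
    winners: list[tuple[str, int, float]] = []
    key = _order_key(ds, variances)
    for k in range(ca.mu):
        members = [g for g in ca.members(k) if g in present]
        if not members:
            log.warning("cluster %d has no gene present in the dataset; skipped", k)
            continue
        scores = score_subcluster(ds, members, scorer)
        cluster_entries = sorted(((g, k, s) for g, s in scores.items()), key=key)
        entries.extend(cluster_entries)
        winners.append(cluster_entries[0])
    entries.sort(key=key)
    winners.sort(key=key)
    return FeatureRanking(entries=entries, selected=[g for g, _, _ in winners])
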