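"""Normalized spectral clustering of node embeddings.

A dense Gaussian kernel over all node pairs,

    w_{ρ1,ρ2} = exp(−‖e_{ρ1} − e_{ρ2}‖² / (2Ω²)),

feeds the symmetric normalized Laplacian L = D^{−1/2}(D − W)D^{−1/2}; the
eigenvectors of its μ smallest eigenvalues form the ζ×μ matrix U, whose
(optionally row-normalized) rows are clustered by k-means. The resulting
μ-way partition of the augmented gene graph yields the subgraphs from which
one biomarker each is later selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .graph_build import GeneGraph
from .gnn import NodeEmbeddings

log = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "SpectralEmbedding",
    "ClusterAssignment",
    "gaussian_similarity",
    "normalized_laplacian",
    "spectral_embed",
    "cluster_rows",
    "partition_graph",
]


@dataclass
class SimilarityMatrix:
    """Dense Gaussian similarity over all node pairs (entries in (0, 1])."""

    nodes: tuple[str, ...]
    W: np.ndarray
    omega: float

    def __post_init__(self) -> None:
        n = len(self.nodes)
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class SpectralEmbedding:
    """First μ eigenpairs of the normalized Laplacian (ascending)."""

    eigenvalues: np.ndarray
    U: np.ndarray
    row_normalized: bool


@dataclass
class ClusterAssignment:
    """A μ-way partition of graph nodes into induced subgraphs."""

    labels: dict[str, int]
    mu: int
    subgraphs: list[tuple[list[str], list[tuple[str, str, float]]]]

    def members(self, k: int) -> list[str]:
        return self.subgraphs[k][0]


def gaussian_similarity(emb: NodeEmbeddings, omega: float | str = "auto") -> SimilarityMatrix:
    """Gaussian kernel on embedding distances; Ω="auto" uses the median
    pairwise distance as bandwidth."""
    if emb.vectors.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    d = pdist(emb.vectors)
    if omega == "auto":
        positive = d[d > 0]
        omega_val = float(np.median(positive)) if positive.size else 1.0
    else:
        omega_val = float(omega)
        if omega_val <= 0:
            raise ValueError("omega must be positive")
    W = np.exp(-squareform(d) ** 2 / (2.0 * omega_val**2))
    return SimilarityMatrix(nodes=emb.nodes, W=W, omega=omega_val)


def normalized_laplacian(sim: SimilarityMatrix) -> np.ndarray:
    """L = D^{−1/2}(D − W)D^{−1/2}; symmetric, eigenvalues in [0, 2]."""
    W = sim.W
    dvec = W.sum(axis=1)
    if np.any(dvec <= 0):
        raise FloatingPointError("zero row sum in similarity matrix")
    inv_sqrt = 1.0 / np.sqrt(dvec)
    L = -W * inv_sqrt[:, None] * inv_sqrt[None, :]
    np.fill_diagonal(L, 1.0 - np.diag(W) / dvec)
    return (L + L.T) / 2.0  # enforce exact symmetry for eigh


def spectral_embed(sim: SimilarityMatrix, mu: int, row_normalize: bool = True) -> SpectralEmbedding:
    """Eigenvectors of the μ smallest Laplacian eigenvalues, as columns of U.

    Each column's sign is fixed so its largest-magnitude entry is positive;
    with ``row_normalize`` every nonzero row of U is rescaled to unit norm
    (standard for the symmetric normalized Laplacian).
    """
    zeta = sim.n_nodes
    if not (1 <= mu <= zeta):
        raise ValueError(f"mu must be in [1, {zeta}], got {mu}")
    L = normalized_laplacian(sim)
    vals, vecs = scipy.linalg.eigh(L, subset_by_index=[0, mu - 1])
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    U = vecs
    if row_normalize:
        norms = np.linalg.norm(U, axis=1)
        U = U / np.where(norms > 0, norms, 1.0)[:, None]
    return SpectralEmbedding(eigenvalues=vals, U=U, row_normalized=row_normalize)


def cluster_rows(se: SpectralEmbedding, mu: int, seed: int = 0, restarts: int = 10) -> np.ndarray:
    """k-means on the rows of U (k-means++ init, best of ``restarts`` runs).

    Empty clusters — possible when U has fewer than μ distinct rows — are
    repaired by splitting the largest cluster, so every label 0..μ−1 is used.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if se.U.shape[1] != mu:
        raise ValueError(f"embedding has {se.U.shape[1]} columns, expected mu={mu}")
    if mu == 1:
        return np.zeros(se.U.shape[0], dtype=int)
    km = KMeans(n_clusters=mu, init="k-means++", n_init=restarts, random_state=seed)
    labels = km.fit_predict(se.U)
    missing = sorted(set(range(mu)) - set(labels.tolist()))
    for m in missing:
        sizes = np.bincount(labels, minlength=mu)
        big = int(np.argmax(sizes))
        movable = np.flatnonzero(labels == big)
        labels[movable[: max(1, len(movable) // 2)]] = m
        log.warning("cluster_rows: repaired empty cluster %d by splitting cluster %d", m, big)
    return labels


def partition_graph(gstar: GeneGraph, labels: np.ndarray | dict) -> ClusterAssignment:
    """Split G* into induced subgraphs, one per cluster label.

    Cross-cluster edges are dropped (counted in the log); non-contiguous
    label sets are relabeled canonically to 0..μ−1.
    """
    if isinstance(labels, dict):
        lab = np.asarray([labels[g] for g in gstar.nodes], dtype=int)
    else:
        lab = np.asarray(labels, dtype=int)
    if lab.shape[0] != gstar.n_nodes:
        raise ValueError("labels must cover all nodes")
    uniq = sorted(set(lab.tolist()))
    remap = {old: new for new, old in enumerate(uniq)}
    lab = np.asarray([remap[v] for v in lab], dtype=int)
    mu = len(uniq)
    subgraphs = []
    dropped = 0
    pairs = gstar.edge_pairs()
    for k in range(mu):
        members = [gstar.nodes[i] for i in np.flatnonzero(lab == k)]
        edges = [
            (gstar.nodes[i], gstar.nodes[j], float(gstar.weights[i, j]))
            for i, j in pairs
            if lab[i] == k and lab[j] == k
        ]
        subgraphs.append((members, edges))
    dropped = int(sum(lab[i] != lab[j] for i, j in pairs))
    if dropped:
        log.info("partition_graph: dropped %d cross-cluster edge(s)", dropped)
    return ClusterAssignment(
        labels={g: int(v) for g, v in zip(gstar.nodes, lab)},
        mu=mu,
        subgraphs=subgraphs,
    )
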