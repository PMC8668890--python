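"""Assembly of the gene relationship graph G = (V, E).

Nodes are genes, edges come from the prior-knowledge interaction network
(restricted to genes actually present in the expression dataset), and every
node carries an initial state vector h⁰ — the gene's expression profile
across samples, optionally z-scored per gene (default on, since the
downstream similarity computations are scale-sensitive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionDataset, WeightedEdgeList

log = logging.getLogger(__name__)

__all__ = ["GeneGraph", "GraphConstructionError", "build_gene_graph"]


class GraphConstructionError(ValueError):
    pass


@dataclass
class GeneGraph:
    """Weighted undirected gene graph with per-node initial state vectors.

    ``nodes`` is sorted so matrices built from the graph are reproducible.
    ``weights`` is the dense symmetric weight matrix (zero diagonal, zero for
    absent edges); ``init_states[i]`` is node i's h⁰ of length n_samples.
    """

    nodes: tuple[str, ...]
    weights: np.ndarray
    init_states: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.nodes)
        self.weights = np.asarray(self.weights, dtype=float)
        self.init_states = np.asarray(self.init_states, dtype=float)
        if self.weights.shape != (n, n):
            raise GraphConstructionError(f"weights shape {self.weights.shape} != ({n}, {n})")
        if not np.allclose(self.weights, self.weights.T):
            raise GraphConstructionError("weight matrix must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise GraphConstructionError("weight matrix must have zero diagonal")
        if np.any(self.weights < 0):
            raise GraphConstructionError("edge weights must be positive")
        if self.init_states.shape[0] != n:
            raise GraphConstructionError("one init_state per node required")
        self._index = {g: i for i, g in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def state_dim(self) -> int:
        return self.init_states.shape[1]

    def index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"node {gene!r} not in graph") from None

    def has_edge(self, a: str, b: str) -> bool:
        return self.weights[self.index(a), self.index(b)] > 0

    def edge_pairs(self) -> np.ndarray:
        """Index pairs (i, j), i < j, of all edges."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        mask = self.weights[iu, ju] > 0
        return np.column_stack([iu[mask], ju[mask]])

    def edges(self) -> list[tuple[str, str, float]]:
        return [
            (self.nodes[i], self.nodes[j], float(self.weights[i, j]))
            for i, j in self.edge_pairs()
        ]

    @property
    def n_edges(self) -> int:
        return int((self.weights > 0).sum() // 2)

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.weights[i] > 0)

    def aggregation_matrix(self) -> np.ndarray:
        """Row-normalized weight matrix Â: Â[v, u] = w_vu / Σ_u' w_vu'.

        Each row sums to 1 (weighted-mean aggregation); isolated nodes get an
        all-zero row, so their neighborhood aggregate is the zero vector.
        """
        rowsum = self.weights.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(rowsum > 0, self.weights / rowsum, 0.0)
        return a

    def with_weights(self, weights: np.ndarray) -> "GeneGraph":
        return GeneGraph(nodes=self.nodes, weights=weights, init_states=self.init_states.copy())


def build_gene_graph(
    ds: ExpressionDataset,
    edges: WeightedEdgeList,
    keep_isolated: bool = True,
    zscore: bool = True,
) -> GeneGraph:
    """Build the gene graph from a dataset and an interaction edge list.

    Edges are restricted to pairs whose both endpoints are in ``ds``; nodes
    are all dataset genes (``keep_isolated=True``, the default — genes absent
    from the network still flow into clustering via their own state) or only
    genes incident to a retained edge. Initial states are the expression
    columns, z-scored per gene unless ``zscore=False``.
    """
    present = set(ds.gene_ids)
    kept = [(a, b, w) for a, b, w in edges if a in present and b in present]
    n_dropped = len(edges) - len(kept)
    if n_dropped:
        log.info("dropped %d edge(s) with endpoints outside the dataset", n_dropped)
    if keep_isolated:
        nodes = tuple(sorted(ds.gene_ids))
    else:
        incident = {g for a, b, _ in kept for g in (a, b)}
        nodes = tuple(sorted(incident))
    if not nodes:
        overlap = len(present & edges.node_set())
        raise GraphConstructionError(
            f"no nodes after restriction ({overlap} dataset gene(s) appear in the edge list)"
        )
    index = {g: i for i, g in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for a, b, w in kept:
        i, j = index[a], index[b]
        W[i, j] = W[j, i] = w

    cols = [ds.gene_index(g) for g in nodes]
    states = ds.X[:, cols].T.copy()  # node-major: (n_nodes, n_samples)
    if zscore:
        mu = states.mean(axis=1, keepdims=True)
        sd = states.std(axis=1, keepdims=True)
        states = np.where(sd > 0, (states - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return GeneGraph(nodes=nodes, weights=W, init_states=states)
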