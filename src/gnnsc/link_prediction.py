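"""Link prediction: negative sampling, similarity loss, MRR model selection,
and graph augmentation.

Existing edges of the gene graph are positive examples; for each positive
edge, γ random non-neighbor partners are drawn for each endpoint to form
its negative group. The embedding stack is trained by gradient descent on a
negative-sampling objective over cosine similarities of final embeddings,

    L = mean over positives of [ −log σ(sim(v_j, v_r))
                                 − Σ_{(v̄_j, v̄_r) ∈ Neg} log σ(−sim(v̄_j, v̄_r)) ],

stopping when the loss change falls below δ. Across epochs, the parameter
snapshot with the highest mean reciprocal rank (each positive ranked
against its own negatives — held-out edges when supplied) is kept as the
link model. Finally, non-adjacent pairs whose predicted link confidence
σ(sim) clears a threshold θ are added as new edges, giving the augmented
graph G*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import gnn
from .data_io import WeightedEdgeList
from .graph_build import GeneGraph
from .gnn import GNNParams, NodeEmbeddings

log = logging.getLogger(__name__)

__all__ = [
    "LinkSampleSet",
    "TrainState",
    "TrainingError",
    "build_link_samples",
    "similarity",
    "link_loss",
    "mean_reciprocal_rank",
    "expected_random_mrr",
    "train_link_model",
    "augment_graph",
]


class TrainingError(RuntimeError):
    pass


@dataclass
class LinkSampleSet:
    """Positive edges with per-positive negative groups (node index pairs)."""

    nodes: tuple[str, ...]
    pos: list[tuple[int, int]]
    neg: list[list[tuple[int, int]]]  # parallel to pos
    gamma: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.pos) != len(self.neg):
            raise ValueError("one negative group per positive required")

    @property
    def n_pos(self) -> int:
        return len(self.pos)


def _draw_negatives(
    adj: np.ndarray, pairs: list[tuple[int, int]], gamma: int, rng: np.random.Generator
) -> list[list[tuple[int, int]]]:
    """For each pair (a, b): γ non-neighbor partners for a and γ for b.

    Sampling is uniform without replacement from each endpoint's
    non-neighbors (excluding itself and its current partner); an endpoint
    adjacent to nearly everything contributes what exists.
    """
    n = adj.shape[0]
    groups: list[list[tuple[int, int]]] = []
    short = 0
    for a, b in pairs:
        group: list[tuple[int, int]] = []
        for v, other in ((a, b), (b, a)):
            pool = np.flatnonzero(~adj[v])
            pool = pool[(pool != v) & (pool != other)]
            take = min(gamma, pool.size)
            if take < gamma:
                short += gamma - take
            if take:
                picks = rng.choice(pool, size=take, replace=False)
                group.extend((int(v), int(u)) for u in picks)
        groups.append(group)
    if short:
        log.warning("negative sampling short by %d draw(s): saturated neighborhoods", short)
    return groups


def build_link_samples(g: GeneGraph, gamma: int = 5, seed: int = 0) -> LinkSampleSet:
    """All edges of ``g`` as positives, with γ negatives per endpoint each.

    For every positive edge the edge itself is set aside, then γ uniform
    non-neighbor partners are drawn for each endpoint (never reproducing an
    existing edge or a self-pair). Reproducible per seed.
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    if g.n_edges < 1 or g.n_nodes < 3:
        raise ValueError("graph needs at least one edge and three nodes")
    rng = np.random.default_rng(seed)
    pos = [(int(i), int(j)) for i, j in g.edge_pairs()]
    adj = g.weights > 0
    neg = _draw_negatives(adj, pos, gamma, rng)
    return LinkSampleSet(nodes=g.nodes, pos=pos, neg=neg, gamma=gamma, seed=seed)


def similarity(z_a: np.ndarray, z_b: np.ndarray) -> float:
    """Cosine similarity; zero vectors have similarity 0 by convention."""
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    if z_a.shape != z_b.shape:
        raise ValueError(f"dimension mismatch: {z_a.shape} vs {z_b.shape}")
    na, nb = np.linalg.norm(z_a), np.linalg.norm(z_b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(z_a @ z_b / (na * nb), -1.0, 1.0))


def _pair_sims(H: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    u, v = H[pairs[:, 0]], H[pairs[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    denom = nu * nv
    s = np.where(denom > 0, (u * v).sum(axis=1) / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(s, -1.0, 1.0)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _flatten_samples(samples: LinkSampleSet):
    pos = np.asarray(samples.pos, dtype=int).reshape(-1, 2)
    if samples.neg and any(samples.neg):
        neg = np.asarray([p for grp in samples.neg for p in grp], dtype=int).reshape(-1, 2)
    else:
        neg = np.empty((0, 2), dtype=int)
    owner = np.asarray(
        [k for k, grp in enumerate(samples.neg) for _ in grp], dtype=int
    )
    return pos, neg, owner


def link_loss(samples: LinkSampleSet, emb: NodeEmbeddings) -> float:
    """Negative-sampling loss over cosine similarities (Pos vs Neg)."""
    if not samples.pos:
        raise ValueError("no positive samples")
    H = emb.vectors
    pos, neg, owner = _flatten_samples(samples)
    s_pos = _pair_sims(H, pos)
    per_pos = _softplus(-s_pos)  # −log σ(s)
    if len(neg):
        s_neg = _pair_sims(H, neg)
        acc = np.zeros(len(pos))
        np.add.at(acc, owner, _softplus(s_neg))  # −log σ(−s) per owning positive
        per_pos = per_pos + acc
    return float(per_pos.mean())


def _loss_and_grad_H(H: np.ndarray, pos, neg, owner) -> tuple[float, np.ndarray]:
    P = len(pos)
    s_pos = _pair_sims(H, pos)
    loss_vec = _softplus(-s_pos)
    G = np.zeros_like(H)
    _accumulate_cosine_grad(H, pos, -_sigmoid(-s_pos) / P, G)
    if len(neg):
        s_neg = _pair_sims(H, neg)
        acc = np.zeros(P)
        np.add.at(acc, owner, _softplus(s_neg))
        loss_vec = loss_vec + acc
        _accumulate_cosine_grad(H, neg, _sigmoid(s_neg) / P, G)
    return float(loss_vec.mean()), G


def _accumulate_cosine_grad(H, pairs, dscore, G):
    u, v = H[pairs[:, 0]], H[pairs[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    ok = (nu > 0) & (nv > 0)
    if not ok.any():
        return
    nu = np.where(ok, nu, 1.0)
    nv = np.where(ok, nv, 1.0)
    s = np.where(ok, (u * v).sum(axis=1) / (nu * nv), 0.0)
    c = np.where(ok, dscore, 0.0)[:, None]
    du = c * (v / (nu * nv)[:, None] - (s / nu**2)[:, None] * u)
    dv = c * (u / (nu * nv)[:, None] - (s / nv**2)[:, None] * v)
    np.add.at(G, pairs[:, 0], du)
    np.add.at(G, pairs[:, 1], dv)


def loss_and_grads(g: GeneGraph, params: GNNParams, samples: LinkSampleSet):
    """One forward/backward pass: (loss, per-layer weight gradients, states)."""
    states, caches = gnn.forward(g, params)
    pos, neg, owner = _flatten_samples(samples)
    loss, G_H = _loss_and_grad_H(states[-1], pos, neg, owner)
    grads = gnn.backward(g, params, states, caches, G_H)
    return loss, grads, states


def _ranks(H: np.ndarray, pos, neg_groups) -> list[int]:
    """Rank of each positive among its own negatives (1 = best; ties split)."""
    ranks = []
    for (a, b), grp in zip(pos, neg_groups):
        s_p = _pair_sims(H, np.asarray([(a, b)], dtype=int))[0]
        if grp:
            s_n = _pair_sims(H, np.asarray(grp, dtype=int))
            rank = 1 + int((s_n > s_p).sum()) + int((s_n == s_p).sum() // 2)
        else:
            rank = 1
        ranks.append(rank)
    return ranks


def mean_reciprocal_rank(rank_list: list[int]) -> float:
    """(1/ε) Σ 1/rank over ε ranked positives."""
    if not rank_list:
        raise ValueError("rank list is empty")
    if any(r < 1 for r in rank_list):
        raise ValueError("ranks must be >= 1")
    return float(np.mean([1.0 / r for r in rank_list]))


def expected_random_mrr(candidate_counts: list[int]) -> float:
    """E[MRR] of a uniform random ranker: mean of H_c / c per positive."""
    vals = []
    for c in candidate_counts:
        if c < 1:
            raise ValueError("candidate count must be >= 1")
        vals.append(sum(1.0 / k for k in range(1, c + 1)) / c)
    return float(np.mean(vals))


@dataclass
class TrainState:
    """Training trajectory and the best (by MRR) parameter snapshot."""

    epoch: int
    loss: float
    delta: float
    best_mrr: float
    best_params: GNNParams
    history: list[tuple[int, float, float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _heldout_eval_samples(
    g: GeneGraph, eval_heldout: WeightedEdgeList, gamma: int, seed: int
) -> tuple[list[tuple[int, int]], list[list[tuple[int, int]]]]:
    rng = np.random.default_rng(seed)
    pairs = []
    for a, b, _ in eval_heldout:
        if a in g._index and b in g._index:
            pairs.append((g.index(a), g.index(b)))
    if not pairs:
        raise ValueError("no held-out edge joins two graph nodes")
    adj = g.weights > 0
    groups = _draw_negatives(adj, pairs, gamma, rng)
    return pairs, groups


def _split_for_validation(
    g: GeneGraph, samples: LinkSampleSet, seed: int
) -> tuple[GeneGraph, LinkSampleSet, list[tuple[int, int]], list[list[tuple[int, int]]]]:
    """Hold out a seeded 20% of the positives as a validation set.

    Validation edges are excluded from the training loss AND removed from
    the propagation graph, so their MRR measures genuine link prediction
    rather than adjacency leaking through the aggregation.
    """
    n_pos = samples.n_pos
    rng = np.random.default_rng(seed)
    n_val = int(round(0.2 * n_pos))
    if n_pos < 2 or n_val < 1:
        log.warning("too few positives (%d) for a validation split; validating in-sample", n_pos)
        return g, samples, list(samples.pos), list(samples.neg)
    val = set(rng.choice(n_pos, size=n_val, replace=False).tolist())
    train_idx = [i for i in range(n_pos) if i not in val]
    val_idx = sorted(val)
    W = g.weights.copy()
    for i in val_idx:
        a, b = samples.pos[i]
        W[a, b] = W[b, a] = 0.0
    g_fit = g.with_weights(W)
    fit_samples = LinkSampleSet(
        nodes=samples.nodes,
        pos=[samples.pos[i] for i in train_idx],
        neg=[samples.neg[i] for i in train_idx],
        gamma=samples.gamma,
        seed=samples.seed,
    )
    return g_fit, fit_samples, [samples.pos[i] for i in val_idx], [samples.neg[i] for i in val_idx]


def train_link_model(
    g: GeneGraph,
    params0: GNNParams,
    samples: LinkSampleSet,
    lr: float = 0.01,
    delta: float = 1e-4,
    max_epochs: int = 200,
    eval_heldout: WeightedEdgeList | None = None,
) -> TrainState:
    """Gradient-descent training with δ-stopping and MRR model selection.

    Positives and negatives are divided into a training and a test part:
    with ``eval_heldout`` the held-out edges (already absent from ``g``) are
    ranked against freshly drawn negatives, otherwise a seeded 20% of the
    positives is held back — excluded from the loss and removed from the
    propagation graph — and ranked against its own negatives. Each epoch
    runs propagate → loss → full-batch gradient step on all layer weights,
    scoring MRR with the pre-step parameters. Training stops when
    |L_t − L_{t−1}| < δ or at ``max_epochs``; the returned state's
    ``best_params`` is the epoch snapshot with the highest MRR.
    """
    if lr <= 0 or delta <= 0 or max_epochs < 1:
        raise ValueError("require lr > 0, delta > 0, max_epochs >= 1")
    if eval_heldout is not None:
        eval_pos, eval_neg = _heldout_eval_samples(g, eval_heldout, samples.gamma, samples.seed + 1)
        g_fit, fit_samples = g, samples
    else:
        g_fit, fit_samples, eval_pos, eval_neg = _split_for_validation(g, samples, samples.seed + 1)
    params = params0.copy()
    history: list[tuple[int, float, float]] = []
    warnings: list[str] = []
    best_mrr = -1.0
    best_params = params.copy()
    prev_loss = None
    loss = np.nan
    for epoch in range(1, max_epochs + 1):
        loss, grads, states = loss_and_grads(g_fit, params, fit_samples)
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        mrr = mean_reciprocal_rank(_ranks(states[-1], eval_pos, eval_neg))
        history.append((epoch, loss, mrr))
        if mrr > best_mrr:
            best_mrr = mrr
            best_params = params.copy()
        for W, G in zip(params.weights, grads):
            W -= lr * G
        if prev_loss is not None and abs(loss - prev_loss) < delta:
            break
        prev_loss = loss
    else:
        msg = f"reached max_epochs={max_epochs} without delta-stop (delta={delta})"
        warnings.append(msg)
        log.warning(msg)
    return TrainState(
        epoch=history[-1][0],
        loss=float(loss),
        delta=delta,
        best_mrr=best_mrr,
        best_params=best_params,
        history=history,
        warnings=warnings,
    )


def augment_graph(
    g: GeneGraph,
    emb: NodeEmbeddings,
    theta: float = 0.7,
    candidate_scope: str = "two_hop",
) -> GeneGraph:
    """Add predicted edges to form G*.

    Every non-adjacent candidate pair (all of them, or only pairs two hops
    apart) whose link confidence σ(cosine similarity) reaches ``theta`` gains
    an edge weighted by that confidence; original edges are untouched.
    """
    if not (0 < theta <= 1):
        raise ValueError("theta must be in (0, 1]")
    if candidate_scope not in ("all_pairs", "two_hop"):
        raise ValueError(f"unknown candidate_scope {candidate_scope!r}")
    adj = g.weights > 0
    n = g.n_nodes
    eye = np.eye(n, dtype=bool)
    if candidate_scope == "two_hop":
        reach2 = (adj.astype(int) @ adj.astype(int)) > 0
        cand = reach2 & ~adj & ~eye
    else:
        cand = ~adj & ~eye
    iu, ju = np.triu_indices(n, k=1)
    mask = cand[iu, ju]
    pairs = np.column_stack([iu[mask], ju[mask]])
    W = g.weights.copy()
    n_added = 0
    if len(pairs):
        conf = _sigmoid(_pair_sims(emb.vectors, pairs))
        add = conf >= theta
        for (i, j), c in zip(pairs[add], conf[add]):
            W[i, j] = W[j, i] = c
        n_added = int(add.sum())
    log.info("augment_graph: %d predicted edge(s) added (theta=%.3g, %s)",
             n_added, theta, candidate_scope)
    return g.with_weights(W)
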