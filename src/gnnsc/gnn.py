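"""Layered neighborhood aggregation producing per-node hidden states.

Each layer K updates every node v synchronously:

    agg_v = Σ_{u ∈ N(v)} a_vu · h_u^{K-1},   a_vu = w_vu / Σ_{u'} w_vu'
    h_v^K = σ(W^K · concat(h_v^{K-1}, agg_v))
    h_v^K ← h_v^K / ‖h_v^K‖₂            (zero vectors pass through)

so the aggregate is a weighted mean over the first-order neighborhood
(edge-weight coefficients normalized to sum to 1), and every nonzero state
is unit-norm after each layer. After L layers a node's state mixes
information from its L-hop neighborhood.

:func:`forward` additionally returns the per-layer caches that
``link_prediction`` uses for hand-derived reverse-mode gradients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .graph_build import GeneGraph

__all__ = [
    "GNNParams",
    "NodeEmbeddings",
    "PropagationError",
    "aggregate_neighborhood",
    "update_node_state",
    "propagate",
    "forward",
]


class PropagationError(RuntimeError):
    pass


def _relu(z):
    return np.maximum(z, 0.0)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "relu": _relu,
    "sigmoid": _sigmoid,
    "tanh": np.tanh,
    "identity": lambda z: z,
}


def _activation_grad(name: str, Z: np.ndarray, V: np.ndarray) -> np.ndarray:
    # dV/dZ expressed through Z and V = act(Z)
    if name == "relu":
        return (Z > 0).astype(float)
    if name == "sigmoid":
        return V * (1.0 - V)
    if name == "tanh":
        return 1.0 - V * V
    if name == "identity":
        return np.ones_like(Z)
    raise ValueError(f"unknown activation {name!r}")


@dataclass
class GNNParams:
    """Per-layer weight matrices of the aggregation stack.

    ``weights[k]`` has shape (layer_dims[k], 2 * input_dim_k): it acts on the
    concatenation of a node's previous state and its neighborhood aggregate.
    """

    layer_dims: list[int]
    weights: list[np.ndarray]
    activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.layer_dims):
            raise ValueError("one weight matrix per layer required")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def n_layers(self) -> int:
        return len(self.layer_dims)

    def validate(self, input_dim: int) -> None:
        d = input_dim
        for k, (W, out) in enumerate(zip(self.weights, self.layer_dims), 1):
            if W.shape != (out, 2 * d):
                raise ValueError(
                    f"layer {k}: weight shape {W.shape} does not conform to "
                    f"({out}, {2 * d}) for input dim {d}"
                )
            d = out

    def copy(self) -> "GNNParams":
        return GNNParams(
            layer_dims=list(self.layer_dims),
            weights=[W.copy() for W in self.weights],
            activation=self.activation,
            seed=self.seed,
        )

    @classmethod
    def glorot(
        cls,
        input_dim: int,
        n_layers: int = 10,
        hidden_dim: int = 32,
        activation: str = "relu",
        seed: int = 0,
    ) -> "GNNParams":
        """Glorot-uniform initialization from the run seed."""
        if n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        rng = np.random.default_rng(seed)
        dims = [hidden_dim] * n_layers
        weights = []
        d = input_dim
        for out in dims:
            fan_in = 2 * d
            limit = np.sqrt(6.0 / (fan_in + out))
            weights.append(rng.uniform(-limit, limit, size=(out, fan_in)))
            d = out
        return cls(layer_dims=dims, weights=weights, activation=activation, seed=seed)

    @classmethod
    def initialize(
        cls,
        input_dim: int,
        n_layers: int = 10,
        hidden_dim: int = 32,
        activation: str = "relu",
        seed: int = 0,
        scheme: str = "diffusion",
    ) -> "GNNParams":
        """Initialize a stack for training.

        ``"diffusion"`` (default) keeps a Glorot-random first layer (a
        random projection to the hidden dimension, which approximately
        preserves distances) and sets every later weight to ½[I | I], so the
        untrained stack computes a lazy diffusion of the node states over
        the graph. A deep stack of fully random layers scrambles the input
        geometry beyond what gradient descent recovers; starting at
        diffusion preserves the expression signal and lets training refine
        it. ``"glorot"`` gives the fully random stack.
        """
        params = cls.glorot(input_dim, n_layers, hidden_dim, activation, seed)
        if scheme == "glorot":
            return params
        if scheme != "diffusion":
            raise ValueError(f"unknown init scheme {scheme!r}")
        eye = np.eye(hidden_dim)
        lazy = 0.5 * np.hstack([eye, eye])
        for k in range(1, n_layers):
            params.weights[k] = lazy.copy()
        return params


@dataclass
class NodeEmbeddings:
    """Per-node hidden state vectors at one layer (rows align with nodes)."""

    nodes: tuple[str, ...]
    vectors: np.ndarray
    layer_index: int = 0

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape[0] != len(self.nodes):
            raise ValueError("one vector per node required")
        self._index = {g: i for i, g in enumerate(self.nodes)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, gene: str) -> np.ndarray:
        return self.vectors[self._index[gene]]


def aggregate_neighborhood(g: GeneGraph, states: NodeEmbeddings, node: str) -> np.ndarray:
    """Weighted-mean aggregate of ``node``'s first-order neighborhood.

    Edge-weight coefficients are normalized to sum to one over the
    neighborhood; an isolated node aggregates to the zero vector.
    """
    i = g.index(node)
    nb = g.neighbors(i)
    if nb.size == 0:
        return np.zeros(states.dim)
    w = g.weights[i, nb]
    return (w / w.sum()) @ states.vectors[nb]


def update_node_state(
    agg: np.ndarray, prev: np.ndarray, W: np.ndarray, activation: str = "relu"
) -> np.ndarray:
    """One node's layer update: normalize(σ(W · concat(prev, agg)))."""
    cat = np.concatenate([prev, agg])
    if W.shape[1] != cat.size:
        raise ValueError(
            f"weight matrix expects input dim {W.shape[1]}, got {cat.size} "
            f"(prev {prev.size} + agg {agg.size})"
        )
    v = ACTIVATIONS[activation](W @ cat)
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _normalize_rows(V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(V, axis=1)
    H = V / np.where(norms > 0, norms, 1.0)[:, None]
    return H, norms


def forward(g: GeneGraph, params: GNNParams):
    """Run all layers; return (inputs per layer, caches per layer).

    ``states[k]`` is the input to layer k (``states[0]`` = h⁰, ``states[L]`` =
    final embeddings); ``caches[k] = (C, Z, V, norms, H)`` holds layer k's
    concatenated input, pre-activation, activation, row norms and normalized
    output, in the shapes the backward pass needs.
    """
    params.validate(g.state_dim)
    A = g.aggregation_matrix()
    act = ACTIVATIONS[params.activation]
    states = [g.init_states]
    caches = []
    H = g.init_states
    for k, W in enumerate(params.weights):
        Agg = A @ H
        C = np.hstack([H, Agg])
        Z = C @ W.T
        V = act(Z)
        H, norms = _normalize_rows(V)
        if not np.isfinite(H).all():
            bad = int(np.flatnonzero(~np.isfinite(H).all(axis=1))[0])
            raise PropagationError(
                f"non-finite state at layer {k + 1}, node {g.nodes[bad]!r}"
            )
        caches.append((C, Z, V, norms, H))
        states.append(H)
    return states, caches


def propagate(g: GeneGraph, params: GNNParams) -> NodeEmbeddings:
    """Run L synchronous layers and return the final-layer embeddings H."""
    states, _ = forward(g, params)
    return NodeEmbeddings(nodes=g.nodes, vectors=states[-1], layer_index=params.n_layers)


def backward(
    g: GeneGraph, params: GNNParams, states: list, caches: list, G_H: np.ndarray
) -> list[np.ndarray]:
    """Reverse-mode gradients of a scalar loss w.r.t. every layer's weights.

    ``G_H`` is the loss gradient w.r.t. the final embeddings; returns one
    gradient array per layer, matching ``params.weights``.
    """
    A = g.aggregation_matrix()
    grads: list[np.ndarray] = [np.empty(0)] * params.n_layers
    for k in range(params.n_layers - 1, -1, -1):
        C, Z, V, norms, H = caches[k]
        nz = norms > 0
        # through row normalization H = V/‖V‖: project out the radial component
        dot = (H * G_H).sum(axis=1, keepdims=True)
        G_V = (G_H - H * dot) / np.where(nz, norms, 1.0)[:, None]
        G_V[~nz] = G_H[~nz]
        G_Z = G_V * _activation_grad(params.activation, Z, V)
        grads[k] = G_Z.T @ C
        G_C = G_Z @ params.weights[k]
        d_prev = states[k].shape[1]
        G_H = G_C[:, :d_prev] + A.T @ G_C[:, d_prev:]
    return grads
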