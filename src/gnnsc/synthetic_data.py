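"""Synthetic two-class expression studies with planted network modules.

The generator emulates the kind of study the pipeline targets: a
samples × genes matrix with a binary phenotype, together with a
prior-knowledge gene graph. Genes are organized into modules — densely
wired groups mirroring the biological premise that physically interacting
gene products share function. A subset of each module's genes is
*informative*: its mean expression shifts between the two classes, so the
informative genes inside one module are redundant readouts of one signal —
exactly the situation cluster-then-pick-one selection is meant to exploit.
An optional per-module latent factor (``module_factor_sd``) additionally
co-expresses module genes.

A held-out edge split (:func:`holdout_edges`) supports evaluating link
prediction against known-true edges.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionDataset, WeightedEdgeList

log = logging.getLogger(__name__)

__all__ = ["SyntheticTruth", "generate_synthetic_study", "holdout_edges"]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated study.

    ``module_membership`` maps every gene to its module index, with -1 for
    background genes outside any module. ``heldout_edges`` is filled by
    :func:`holdout_edges`, never by the generator itself.
    """

    informative_genes: set[str]
    module_membership: dict[str, int]
    heldout_edges: list[tuple[str, str, float]] = field(default_factory=list)
    effect_size: float = 0.0
    seed: int = 0

    def to_json(self) -> str:
        payload = {
            "informative_genes": sorted(self.informative_genes),
            "module_membership": dict(sorted(self.module_membership.items())),
            "heldout_edges": [list(e) for e in self.heldout_edges],
            "effect_size": self.effect_size,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            informative_genes=set(d["informative_genes"]),
            module_membership={k: int(v) for k, v in d["module_membership"].items()},
            heldout_edges=[(a, b, float(w)) for a, b, w in d["heldout_edges"]],
            effect_size=float(d["effect_size"]),
            seed=int(d["seed"]),
        )


def generate_synthetic_study(
    n_samples: int = 60,
    n_genes: int = 200,
    n_modules: int = 5,
    informative_per_module: int = 4,
    effect_size: float = 1.5,
    intra_module_edge_prob: float = 0.3,
    inter_module_edge_prob: float = 0.01,
    noise_sd: float = 1.0,
    seed: int = 0,
    module_size: int | None = None,
    module_factor_sd: float = 0.0,
) -> tuple[ExpressionDataset, WeightedEdgeList, SyntheticTruth]:
    """Generate one synthetic study: expression matrix, gene graph, truth.

    Parameters
    ----------
    n_samples, n_genes : int
        Matrix shape. Classes are balanced to within one sample.
    n_modules, informative_per_module : int
        Number of planted modules and informative genes per module; the
        first ``informative_per_module`` genes of each module are shifted by
        ``effect_size`` within-class standard deviations between classes
        (±effect/2 per class).
    intra_module_edge_prob, inter_module_edge_prob : float
        Independent Bernoulli edge probabilities for same-module pairs and
        for every other pair (background genes behave like singleton
        modules). Edge weights are Uniform(0.5, 1.0).
    noise_sd : float
        SD of the i.i.d. per-gene noise.
    module_size : int, optional
        Genes per module; defaults to ``n_genes // (2 * n_modules)`` (half
        the genes live in modules, half are background), floored at
        ``informative_per_module``.
    module_factor_sd : float
        SD of an optional per-module latent factor shared by all genes of a
        module, making module genes co-express beyond the class signal.
        Off (0.0) by default: co-expression factors interact with
        within-dataset cross-validation in ways that reward redundant
        panels, so the default expression model keeps gene noise i.i.d.

    Returns
    -------
    (ExpressionDataset, WeightedEdgeList, SyntheticTruth)
        Reproducibly identical for identical arguments and seed.
    """
    if n_samples < 2 or n_genes < 1 or n_modules < 0 or informative_per_module < 0:
        raise ValueError("sizes must be positive")
    if n_modules * informative_per_module > n_genes:
        raise ValueError("n_modules * informative_per_module exceeds n_genes")
    if not (0 < intra_module_edge_prob <= 1):
        raise ValueError("intra_module_edge_prob must be in (0, 1]")
    if not (0 <= inter_module_edge_prob < 1):
        raise ValueError("inter_module_edge_prob must be in [0, 1)")
    if not noise_sd > 0:
        raise ValueError("noise_sd must be positive")
    if module_size is None:
        module_size = max(informative_per_module, n_genes // (2 * max(n_modules, 1)))
    if n_modules * module_size > n_genes:
        raise ValueError("n_modules * module_size exceeds n_genes")
    if module_factor_sd < 0:
        raise ValueError("module_factor_sd must be non-negative")

    rng = np.random.default_rng(seed)
    width = len(str(max(n_genes - 1, 0)))
    genes = [f"g{i:0{width}d}" for i in range(n_genes)]
    samples = [f"s{i:03d}" for i in range(n_samples)]

    # module index per gene: modules occupy the first n_modules*module_size
    # genes in blocks; remaining genes are background (-1)
    membership = np.full(n_genes, -1, dtype=int)
    for m in range(n_modules):
        membership[m * module_size : (m + 1) * module_size] = m

    informative_idx = [
        m * module_size + j for m in range(n_modules) for j in range(informative_per_module)
    ]
    informative = {genes[i] for i in informative_idx}

    # labels: balanced within one sample, class 0 first
    n1 = n_samples // 2
    y = np.concatenate([np.zeros(n_samples - n1, dtype=int), np.ones(n1, dtype=int)])

    X = rng.normal(0.0, noise_sd, size=(n_samples, n_genes))
    if n_modules and module_factor_sd > 0:
        factors = rng.normal(0.0, module_factor_sd, size=(n_samples, n_modules))
        in_module = membership >= 0
        X[:, in_module] += factors[:, membership[in_module]]
    within_sd = float(np.hypot(noise_sd, module_factor_sd))
    shift = effect_size * within_sd
    sign = np.where(y == 1, 0.5, -0.5)
    for i in informative_idx:
        X[:, i] += sign * shift

    # edges: one Bernoulli draw per unordered pair
    iu, ju = np.triu_indices(n_genes, k=1)
    same = (membership[iu] >= 0) & (membership[iu] == membership[ju])
    p = np.where(same, intra_module_edge_prob, inter_module_edge_prob)
    keep = rng.random(iu.size) < p
    weights = rng.uniform(0.5, 1.0, size=iu.size)  # drawn for all pairs: keeps the
    # edge-weight stream independent of which pairs survive
    edges = [
        (genes[int(a)], genes[int(b)], float(w))
        for a, b, w in zip(iu[keep], ju[keep], weights[keep])
    ]

    ds = ExpressionDataset(sample_ids=samples, gene_ids=genes, X=X, y=y)
    edge_list = WeightedEdgeList(edges=edges)
    truth = SyntheticTruth(
        informative_genes=informative,
        module_membership={genes[i]: int(membership[i]) for i in range(n_genes)},
        effect_size=effect_size,
        seed=seed,
    )
    return ds, edge_list, truth


def holdout_edges(
    edges: WeightedEdgeList, fraction: float, seed: int = 0
) -> tuple[WeightedEdgeList, WeightedEdgeList]:
    """Split an edge list into training and held-out sets.

    ``round(fraction * |edges|)`` edges are held out, preferring candidates
    whose removal does not isolate either endpoint; if only isolating
    candidates remain the split proceeds with a logged warning.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    n_edges = len(edges)
    if n_edges == 0:
        raise ValueError("edge list is empty")
    n_hold = int(round(fraction * n_edges))
    if n_hold < 1:
        raise ValueError(f"fraction {fraction} rounds to zero held-out edges")
    if n_hold >= n_edges:
        raise ValueError("fraction leaves no training edge")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_edges)
    degree: dict[str, int] = {}
    for a, b, _ in edges:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1

    held: list[int] = []
    deferred: list[int] = []
    for k in order:
        if len(held) == n_hold:
            break
        a, b, _ = edges.edges[int(k)]
        if degree[a] > 1 and degree[b] > 1:
            held.append(int(k))
            degree[a] -= 1
            degree[b] -= 1
        else:
            deferred.append(int(k))
    if len(held) < n_hold:
        n_forced = n_hold - len(held)
        log.warning(
            "holdout_edges: %d held-out edge(s) isolate an endpoint (no alternative)",
            n_forced,
        )
        for k in deferred[:n_forced]:
            held.append(k)
            a, b, _ = edges.edges[k]
            degree[a] -= 1
            degree[b] -= 1
    held_set = set(held)
    train = WeightedEdgeList(edges=[e for i, e in enumerate(edges.edges) if i not in held_set])
    heldout = WeightedEdgeList(edges=[edges.edges[i] for i in sorted(held_set)])
    return train, heldout
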