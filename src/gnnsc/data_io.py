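"""Readers and writers for the pipeline's tabular formats.

The pipeline consumes three kinds of delimited text files:

* an expression matrix — samples in rows, genes in columns (or the
  transpose), plus a binary label column naming the disease state of each
  sample;
* a weighted gene–gene edge list, as exported from an interaction resource
  such as GeneMANIA (``gene_a<TAB>gene_b[<TAB>weight]``, ``#`` comments);
* an optional two-column probe → gene-symbol map used to rename microarray
  probe IDs to gene symbols so they can be matched against the network.

Everything is loaded into two small containers, :class:`ExpressionDataset`
and :class:`WeightedEdgeList`, which the rest of the package works with.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "WeightedEdgeList",
    "FormatError",
    "LabelError",
    "DuplicateIDError",
    "MappingError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_edge_list",
    "write_edge_list",
    "apply_probe_map",
    "summarize_dataset",
    "write_ranking",
]


class FormatError(ValueError):
    """The file does not match the expected tabular layout."""


class LabelError(ValueError):
    """Sample labels are missing, non-binary, or single-class."""


class DuplicateIDError(ValueError):
    """Gene identifiers are not unique."""


class MappingError(ValueError):
    """A probe map shares no identifiers with the dataset."""


@dataclass
class ExpressionDataset:
    """A samples × genes expression matrix with binary sample labels.

    Attributes
    ----------
    sample_ids : list of str
        One identifier per row of ``X``.
    gene_ids : list of str
        Unique gene (column) identifiers.
    X : ndarray, shape (n_samples, n_genes)
        Expression values; units are whatever the source file used.
    y : ndarray of {0, 1}, shape (n_samples,)
        Class label per sample; both classes must be present.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise FormatError("X must be a 2-D matrix")
        n, d = self.X.shape
        if len(self.sample_ids) != n:
            raise FormatError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.gene_ids) != d:
            raise FormatError(f"{len(self.gene_ids)} gene ids for {d} columns")
        if not self.gene_ids or any(g == "" for g in self.gene_ids):
            raise FormatError("gene ids must be non-empty")
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise DuplicateIDError(f"duplicate gene ids: {sorted(dupes)}")
        if np.isnan(self.X).any():
            raise FormatError("X contains missing values; impute or drop first")
        if self.y.shape != (n,):
            raise LabelError(f"y has shape {self.y.shape}, expected ({n},)")
        classes = set(self.y.tolist())
        if classes != {0, 1}:
            raise LabelError(f"labels must contain both classes 0 and 1, got {sorted(classes)}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in dataset") from None

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        """Return a dataset restricted to ``genes`` (kept in the given order)."""
        idx = [self.gene_index(g) for g in genes]
        return ExpressionDataset(
            sample_ids=list(self.sample_ids),
            gene_ids=[self.gene_ids[i] for i in idx],
            X=self.X[:, idx].copy(),
            y=self.y.copy(),
        )


@dataclass
class WeightedEdgeList:
    """Deduplicated, undirected, positively weighted gene–gene edges."""

    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b, w in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if not w > 0:
                raise ValueError(f"non-positive weight {w} on ({a!r}, {b!r})")
        pairs = [frozenset((a, b)) for a, b, _ in self.edges]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate unordered pairs in edge list")

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def pair_set(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b, _ in self.edges}

    def node_set(self) -> set[str]:
        return {g for a, b, _ in self.edges for g in (a, b)}


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup


def _raw_header_tokens(path: Path, sep: str | None) -> list[str]:
    import csv

    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.lstrip().startswith("#"):
                header = line.rstrip("\n")
                break
        else:
            raise FormatError(f"{path} is empty")
    if sep is None:
        try:
            delim = csv.Sniffer().sniff(header).delimiter
        except csv.Error:
            delim = ","
        return header.split(delim)
    return header.split(sep)


def _encode_labels(raw: pd.Series, label_map: Mapping | None) -> np.ndarray:
    values = raw.tolist()
    if label_map is not None:
        try:
            encoded = [int(label_map[v]) for v in values]
        except KeyError as exc:
            raise LabelError(f"label {exc.args[0]!r} missing from label map") from None
        if not set(encoded) <= {0, 1}:
            raise LabelError("label map must map onto {0, 1}")
        return np.asarray(encoded, dtype=int)
    distinct = sorted({str(v) for v in values})
    if len(distinct) != 2:
        raise LabelError(f"expected exactly two classes, found {distinct}")
    # lexicographically smaller class label becomes 0 (so "0"/"1" stay as-is)
    mapping = {distinct[0]: 0, distinct[1]: 1}
    return np.asarray([mapping[str(v)] for v in values], dtype=int)


def read_expression_matrix(
    path: str | Path,
    genes_in: str = "columns",
    label_column: str = "label",
    label_map: Mapping | None = None,
    sep: str | None = None,
    impute: str | None = None,
) -> ExpressionDataset:
    """Load a delimited expression table into an :class:`ExpressionDataset`.

    Parameters
    ----------
    path : path
        Delimited text file. First column holds sample IDs (or gene IDs when
        ``genes_in="rows"``); the delimiter is sniffed unless ``sep`` is given.
    genes_in : {"columns", "rows"}
        Layout of the table. With ``"rows"`` the table is transposed after
        loading so genes are always columns internally; the label entries then
        form a row named ``label_column``.
    label_column : str
        Name of the column (or row) holding class labels.
    label_map : mapping, optional
        Explicit label → {0, 1} encoding. Without it, the lexicographically
        smaller of the two class labels maps to 0.
    impute : {None, "mean"}
        Missing expression values are refused by default; ``"mean"`` fills
        them with the per-gene mean.
    """
    path = Path(path)
    if genes_in not in ("columns", "rows"):
        raise ValueError(f"genes_in must be 'columns' or 'rows', got {genes_in!r}")
    df = pd.read_csv(
        path,
        sep=sep,
        engine="python" if sep is None else "c",
        index_col=0,
        comment="#",
    )
    if genes_in == "columns":
        # pandas silently mangles duplicate header names; check the raw header
        header = _raw_header_tokens(path, sep)
        dupes = _duplicates(header[1:])
        if dupes:
            raise DuplicateIDError(f"duplicate gene ids in {path}: {sorted(dupes)}")
    else:
        dupes = _duplicates([str(i) for i in df.index if str(i) != label_column])
        if dupes:
            raise DuplicateIDError(f"duplicate gene ids in {path}: {sorted(dupes)}")
    if genes_in == "rows":
        df = df.T
    if label_column not in df.columns:
        raise FormatError(f"label column {label_column!r} not found in {path}")
    y = _encode_labels(df[label_column], label_map)
    expr = df.drop(columns=[label_column])
    gene_ids = [str(c) for c in expr.columns]
    dupes = _duplicates(gene_ids)
    if dupes:
        raise DuplicateIDError(f"duplicate gene ids in {path}: {sorted(dupes)}")
    X = expr.to_numpy(dtype=float)
    if np.isnan(X).any():
        if impute == "mean":
            n_missing = int(np.isnan(X).sum())
            col_mean = np.nanmean(X, axis=0)
            X = np.where(np.isnan(X), col_mean[None, :], X)
            log.warning("imputed %d missing expression values with gene means", n_missing)
        else:
            raise FormatError(f"{path} contains missing expression values (use impute='mean')")
    return ExpressionDataset(
        sample_ids=[str(s) for s in expr.index],
        gene_ids=gene_ids,
        X=X,
        y=y,
    )


def write_expression_matrix(
    ds: ExpressionDataset, path: str | Path, label_column: str = "label", sep: str = "\t"
) -> None:
    """Write a dataset back out in the genes-in-columns layout (round-trips)."""
    df = pd.DataFrame(ds.X, index=ds.sample_ids, columns=ds.gene_ids)
    df[label_column] = ds.y
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


def read_edge_list(path: str | Path, default_weight: float = 1.0, sep: str = r"\s+") -> WeightedEdgeList:
    """Load a 2- or 3-column edge list.

    Duplicate unordered pairs keep the maximum weight; self-loop records are
    dropped with a warning; 2-column rows take ``default_weight``.
    """
    if not default_weight > 0:
        raise ValueError("default_weight must be positive")
    best: dict[frozenset, tuple[str, str, float]] = {}
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 2:
                a, b, w = parts[0], parts[1], default_weight
            elif len(parts) == 3:
                a, b = parts[0], parts[1]
                try:
                    w = float(parts[2])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: bad weight {parts[2]!r}") from None
            else:
                raise FormatError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
            if not w > 0:
                raise ValueError(f"{path}:{lineno}: weight must be positive, got {w}")
            if a == b:
                n_loops += 1
                continue
            key = frozenset((a, b))
            if key not in best or w > best[key][2]:
                best[key] = (min(a, b), max(a, b), w)
    if n_loops:
        log.warning("dropped %d self-loop record(s) from %s", n_loops, path)
    edges = sorted(best.values())
    return WeightedEdgeList(edges=edges)


def write_edge_list(edges: WeightedEdgeList, path: str | Path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(f"# gene_a{sep}gene_b{sep}weight\n")
        for a, b, w in sorted(edges.edges):
            fh.write(f"{a}{sep}{b}{sep}{w!r}\n")


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column probe_id → gene_symbol table."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            mapping[parts[0]] = parts[1]
    return mapping


def apply_probe_map(ds: ExpressionDataset, probe_map: Mapping[str, str]) -> ExpressionDataset:
    """Rename probe IDs to gene symbols.

    Probes absent from the map are dropped (counted in the log). When several
    probes map to the same gene, the probe with the highest variance across
    samples is kept — the usual microarray collapse convention.
    """
    mapped = [p for p in ds.gene_ids if p in probe_map]
    if not mapped:
        raise MappingError("probe map shares no identifiers with the dataset")
    n_dropped = ds.n_genes - len(mapped)
    if n_dropped:
        log.info("dropped %d probe(s) absent from the probe map", n_dropped)
    variances = ds.X.var(axis=0)
    # gene symbol -> best (variance, probe index); ties resolved by probe order
    best: dict[str, tuple[float, int]] = {}
    for probe in mapped:
        i = ds.gene_ids.index(probe)
        gene = probe_map[probe]
        if gene not in best or variances[i] > best[gene][0]:
            best[gene] = (variances[i], i)
    genes = sorted(best)
    idx = [best[g][1] for g in genes]
    return ExpressionDataset(
        sample_ids=list(ds.sample_ids),
        gene_ids=genes,
        X=ds.X[:, idx].copy(),
        y=ds.y.copy(),
    )


def summarize_dataset(ds: ExpressionDataset) -> dict:
    """Dataset summary: sizes, per-class counts, and the unbalance rate.

    The unbalance rate (UR) is the majority/minority class-count ratio,
    reported to two decimals.
    """
    counts = np.bincount(ds.y, minlength=2)
    ur = round(float(counts.max() / counts.min()), 2)
    return {
        "n_samples": ds.n_samples,
        "n_genes": ds.n_genes,
        "class_counts": {0: int(counts[0]), 1: int(counts[1])},
        "unbalance_rate": ur,
    }


def write_ranking(entries: Sequence[tuple[str, int, float]], path: str | Path) -> None:
    """Write a feature ranking as TSV: rank, gene_id, cluster_id, score."""
    with open(path, "w") as fh:
        fh.write("rank\tgene_id\tcluster_id\tscore\n")
        for rank, (gene, cluster, score) in enumerate(entries, 1):
            fh.write(f"{rank}\t{gene}\t{cluster}\t{score!r}\n")
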