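"""Reading standard inputs and building per-patient attributed graphs.

The shared knowledge graph is an undirected protein-protein interaction (PPI)
network over gene symbols. Each patient is modelled as a copy of that network
whose nodes carry the patient's expression values, turning disease prediction
into a graph-classification problem: one graph, one binary label, per patient.

All patient graphs built in one call share the *same* :class:`PPINetwork`
object, so downstream code may rely on identical node order across a cohort.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyNetworkError,
    IncompatibleInputsError,
    InputError,
    ParameterError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(eq=True)
class PPINetwork:
    """Undirected PPI topology over gene symbols.

    Nodes are sorted lexicographically; each undirected edge is stored once as
    a lexicographically sorted pair. Gene symbols are case-sensitive.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self):
        node_set = set(self.nodes)
        for a, b in self.edges:
            if a == b:
                raise ParameterError(f"self-loop on {a!r}")
            if a not in node_set or b not in node_set:
                raise ParameterError(f"edge endpoint not in nodes: ({a!r}, {b!r})")

    @classmethod
    def from_edges(
        cls, edges: Sequence[tuple[str, str]], extra_nodes: Sequence[str] = ()
    ) -> "PPINetwork":
        """Build a network from raw (possibly duplicated/reversed) edge pairs.

        Self-loops are dropped silently here; callers that parse files report
        them. ``extra_nodes`` adds isolated nodes (used by induced subgraphs).
        """
        dedup = {tuple(sorted(e)) for e in edges if e[0] != e[1]}
        nodes = sorted({g for e in dedup for g in e} | set(extra_nodes))
        return cls(tuple(nodes), tuple(sorted(dedup)))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_index(self) -> Mapping[str, int]:
        idx = self.__dict__.get("_node_index")
        if idx is None:
            idx = {g: i for i, g in enumerate(self.nodes)}
            self.__dict__["_node_index"] = idx
        return idx

    def adjacency(self, self_loops: bool = False) -> np.ndarray:
        """Dense symmetric 0/1 adjacency in node order (optionally A + I)."""
        idx = self.node_index()
        a = np.zeros((self.n_nodes, self.n_nodes))
        for u, v in self.edges:
            a[idx[u], idx[v]] = 1.0
            a[idx[v], idx[u]] = 1.0
        if self_loops:
            a[np.diag_indices(self.n_nodes)] = 1.0
        return a

    def neighbors(self) -> Mapping[str, tuple[str, ...]]:
        nb = self.__dict__.get("_neighbors")
        if nb is None:
            d: dict[str, list[str]] = {g: [] for g in self.nodes}
            for u, v in self.edges:
                d[u].append(v)
                d[v].append(u)
            nb = {g: tuple(sorted(s)) for g, s in d.items()}
            self.__dict__["_neighbors"] = nb
        return nb

    def induced(self, genes: Sequence[str]) -> "PPINetwork":
        """Induced subnetwork on ``genes`` (kept even if isolated)."""
        keep = set(genes)
        unknown = keep - set(self.nodes)
        if unknown:
            raise ParameterError(f"genes not in network: {sorted(unknown)[:5]}")
        edges = [e for e in self.edges if e[0] in keep and e[1] in keep]
        return PPINetwork.from_edges(edges, extra_nodes=sorted(keep))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass
class ExpressionTable:
    """Samples x genes expression matrix with a binary outcome per sample."""

    sample_ids: tuple[str, ...]
    genes: tuple[str, ...]
    values: np.ndarray  # (n_samples, n_genes)
    labels: np.ndarray  # (n_samples,) in {0, 1}

    def __post_init__(self):
        if self.values.shape != (len(self.sample_ids), len(self.genes)):
            raise ParameterError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.genes)} genes"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InputError("duplicate sample ids")
        if len(set(self.genes)) != len(self.genes):
            raise InputError("duplicate gene columns")
        if not np.isin(self.labels, (0, 1)).all():
            raise InputError("labels must all be 0 or 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class PatientGraph:
    """One patient: the shared PPI topology enriched with expression values."""

    topology: PPINetwork
    node_features: np.ndarray  # (n_nodes,), aligned with topology.nodes
    label: int
    sample_id: str

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features, dtype=float)
        if self.node_features.shape != (self.topology.n_nodes,):
            raise ParameterError(
                "feature vector length must equal topology node count"
            )


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test patient index sets covering a cohort."""

    train: tuple[int, ...]
    validation: tuple[int, ...]
    test: tuple[int, ...]

    def __iter__(self):
        yield from (self.train, self.validation, self.test)

    @property
    def n(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_ppi(path) -> PPINetwork:
    """Read a whitespace/tab two-column gene-symbol edge list.

    Comment lines starting with ``#`` and blank lines are skipped. A third
    numeric column (interaction confidence, STRING-style) is accepted and
    ignored. Self-loop lines are dropped with a logged warning. Edges are
    undirected and deduplicated; node order is lexicographic.
    """
    edges: set[tuple[str, str]] = set()
    n_self = 0
    try:
        with open(path, "rt", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise InputError(
                        f"{path}:{lineno}: expected at least two columns"
                    )
                a, b = parts[0], parts[1]
                if a == b:
                    n_self += 1
                    continue
                edges.add(tuple(sorted((a, b))))
    except OSError as exc:
        raise InputError(f"cannot read PPI file {path}: {exc}") from exc
    if n_self:
        logger.warning("dropped %d self-loop line(s) from %s", n_self, path)
    if not edges:
        raise EmptyNetworkError(f"no valid edges in {path}")
    return PPINetwork.from_edges(sorted(edges))


def write_ppi(ppi: PPINetwork, path) -> None:
    """Write the network as a two-column tab-separated edge list."""
    with open(path, "wt", encoding="utf-8") as fh:
        for a, b in ppi.edges:
            fh.write(f"{a}\t{b}\n")


def read_expression(path, label_column: str) -> ExpressionTable:
    """Read a tab-separated expression table.

    First column holds sample ids; ``label_column`` holds the binary outcome;
    every other column is a gene. Non-numeric labels with exactly two distinct
    values are coerced deterministically: the lexicographically smaller value
    maps to 0 (the mapping is logged).
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot read expression table {path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate sample ids: {dups[:5]}")
    if label_column not in df.columns:
        raise InputError(f"label column {label_column!r} not found in {path}")
    raw_labels = df[label_column]
    expr = df.drop(columns=[label_column])
    try:
        values = expr.astype(float).to_numpy()
    except ValueError as exc:
        raise InputError(f"non-numeric expression value: {exc}") from exc

    distinct = sorted(raw_labels.unique())
    if len(distinct) != 2:
        raise InputError(
            f"label column must hold exactly two distinct values, got {distinct}"
        )
    if set(distinct) <= {"0", "1", "0.0", "1.0"}:
        labels = raw_labels.astype(float).astype(int).to_numpy()
    else:
        mapping = {distinct[0]: 0, distinct[1]: 1}
        logger.info("coerced labels: %r -> 0, %r -> 1", distinct[0], distinct[1])
        labels = raw_labels.map(mapping).to_numpy()
    return ExpressionTable(
        sample_ids=tuple(str(s) for s in df.index),
        genes=tuple(expr.columns),
        values=values,
        labels=np.asarray(labels, dtype=int),
    )


def write_expression(table: ExpressionTable, path, label_column: str = "label") -> None:
    df = pd.DataFrame(table.values, index=list(table.sample_ids), columns=list(table.genes))
    df[label_column] = table.labels
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Graph construction and splitting
# ---------------------------------------------------------------------------


def build_patient_graphs(
    expr: ExpressionTable, ppi: PPINetwork
) -> list[PatientGraph]:
    """Build one attributed graph per sample on the gene intersection.

    The topology is the PPI induced on genes present in both inputs; genes
    found in only one input are dropped and counted in the log. All returned
    graphs share the identical topology object.
    """
    common = sorted(set(expr.genes) & set(ppi.nodes))
    if len(common) < 2:
        raise IncompatibleInputsError(
            f"expression and PPI share only {len(common)} gene(s); need >= 2"
        )
    dropped_expr = len(expr.genes) - len(common)
    dropped_ppi = ppi.n_nodes - len(common)
    if dropped_expr or dropped_ppi:
        logger.info(
            "gene intersection: kept %d, dropped %d expression-only and "
            "%d PPI-only gene(s)",
            len(common), dropped_expr, dropped_ppi,
        )
    topology = ppi.induced(common)
    col = {g: j for j, g in enumerate(expr.genes)}
    order = np.array([col[g] for g in topology.nodes])
    return [
        PatientGraph(
            topology=topology,
            node_features=expr.values[i, order],
            label=int(expr.labels[i]),
            sample_id=expr.sample_ids[i],
        )
        for i in range(expr.n_samples)
    ]


def zscore_expression(table: ExpressionTable) -> ExpressionTable:
    """Per-gene z-scoring (optional; generated cohorts are already standardized)."""
    mu = table.values.mean(axis=0)
    sd = table.values.std(axis=0)
    sd[sd == 0] = 1.0
    return ExpressionTable(
        table.sample_ids, table.genes, (table.values - mu) / sd, table.labels
    )


def _largest_remainder(count: int, fractions: Sequence[float]) -> list[int]:
    raw = [count * f for f in fractions]
    base = [math.floor(r) for r in raw]
    short = count - sum(base)
    # distribute the remainder by descending fractional part, ties to earlier splits
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def split_dataset(
    n: int,
    fractions: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    labels: Sequence[int] | None = None,
) -> DatasetSplit:
    """Partition patient indices 0..n-1 into train/validation/test.

    Fractions are (train, validation, test) and must sum to 1. When ``labels``
    is given the split is stratified: allocation by largest remainder within
    each class, so split label ratios track the cohort's. Deterministic under
    a fixed seed.
    """
    if n < 3:
        raise ParameterError(f"need at least 3 patients to split, got {n}")
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ParameterError(f"fractions must be three positive reals: {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ParameterError(f"fractions must sum to 1: {fractions}")
    if labels is None:
        labels = [0] * n
    labels = np.asarray(labels)
    if len(labels) != n:
        raise ParameterError("labels length must equal n")

    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        sizes = _largest_remainder(len(idx), fractions)
        start = 0
        for k, size in enumerate(sizes):
            parts[k].extend(int(i) for i in idx[start : start + size])
            start += size
    return DatasetSplit(
        train=tuple(sorted(parts[0])),
        validation=tuple(sorted(parts[1])),
        test=tuple(sorted(parts[2])),
    )


def write_splits(split: DatasetSplit, sample_ids: Sequence[str], path) -> None:
    """Audit export: one (sample_id, split) row per patient, TSV."""
    names = {}
    for name, idxs in zip(("train", "validation", "test"), split):
        for i in idxs:
            names[i] = name
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("sample_id\tsplit\n")
        for i, sid in enumerate(sample_ids):
            fh.write(f"{sid}\t{names[i]}\n")
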