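"""Synthetic PPI networks and patient cohorts with a planted class signal.

The generator emulates the framework's two standard inputs — a scale-free
interaction network and a samples x genes expression table with a binary
outcome — plus a known ground truth for testing: a connected "signal"
subnetwork whose genes are shifted upward in class-1 patients.

Model: background expression is i.i.d. Normal(0, noise_sd^2) for every gene
and patient; for class-1 patients, each signal gene's value is shifted by
``effect_size * noise_sd``. Classes are balanced by default. Everything is
deterministic under ``spec.seed``; the three operations draw from
independent seeded streams so, e.g., changing the cohort size never changes
the network.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import ParameterError
from .explain import SubgraphSpec
from .graphio import ExpressionTable, PPINetwork, write_expression, write_ppi


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition knobs for one synthetic dataset."""

    n_genes: int = 100
    attachment_edges: int = 2       # preferential-attachment growth parameter
    n_patients_per_class: int = 100
    signal_size: int = 5
    effect_size: float = 2.0        # class-1 mean shift, in noise-sd units
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 3:
            raise ParameterError("n_genes must be >= 3")
        if self.attachment_edges < 1:
            raise ParameterError("attachment_edges must be >= 1")
        if self.signal_size > self.n_genes:
            raise ParameterError("signal_size cannot exceed n_genes")
        if self.n_patients_per_class < 2:
            raise ParameterError("n_patients_per_class must be >= 2")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")


def _gene_name(i: int, n_genes: int) -> str:
    width = max(4, len(str(n_genes)))
    return f"G{i + 1:0{width}d}"


def generate_ppi(spec: SyntheticSpec) -> PPINetwork:
    """Connected preferential-attachment network over G0001..Gn."""
    rng = np.random.default_rng([spec.seed, 0])
    g = nx.barabasi_albert_graph(
        spec.n_genes, spec.attachment_edges, seed=int(rng.integers(2**31))
    )
    mapping = {i: _gene_name(i, spec.n_genes) for i in g.nodes}
    edges = [(mapping[u], mapping[v]) for u, v in g.edges]
    return PPINetwork.from_edges(edges, extra_nodes=list(mapping.values()))


def plant_signal(ppi: PPINetwork, spec: SyntheticSpec) -> SubgraphSpec:
    """Pick the ground-truth signal subnetwork by seeded breadth-first growth.

    Starts at a random node and takes the first ``signal_size`` genes in BFS
    order (neighbours visited lexicographically), so the result is connected
    and reproducible.
    """
    if spec.signal_size < 2:
        raise ParameterError("signal_size must be >= 2")
    rng = np.random.default_rng([spec.seed, 1])
    start = ppi.nodes[int(rng.integers(ppi.n_nodes))]
    neighbors = ppi.neighbors()
    visited = [start]
    seen = {start}
    queue = [start]
    while queue and len(visited) < spec.signal_size:
        node = queue.pop(0)
        for nb in neighbors[node]:
            if nb not in seen:
                seen.add(nb)
                visited.append(nb)
                queue.append(nb)
                if len(visited) == spec.signal_size:
                    break
    if len(visited) < spec.signal_size:
        raise ParameterError(
            "start component smaller than signal_size"  # cannot happen: PA graphs are connected
        )
    genes = tuple(sorted(visited))
    members = set(genes)
    edges = tuple(e for e in ppi.edges if e[0] in members and e[1] in members)
    return SubgraphSpec(genes=genes, edges=edges)


def generate_cohort(
    ppi: PPINetwork, signal: SubgraphSpec, spec: SyntheticSpec
) -> ExpressionTable:
    """Balanced two-class cohort with the signal genes shifted in class 1."""
    rng = np.random.default_rng([spec.seed, 2])
    n = 2 * spec.n_patients_per_class
    values = rng.normal(0.0, spec.noise_sd, size=(n, ppi.n_nodes))
    labels = np.array([0] * spec.n_patients_per_class + [1] * spec.n_patients_per_class)
    idx = ppi.node_index()
    sig_cols = [idx[g] for g in signal.genes]
    values[np.ix_(labels == 1, sig_cols)] += spec.effect_size * spec.noise_sd
    sample_ids = tuple(f"P{i + 1:04d}" for i in range(n))
    return ExpressionTable(
        sample_ids=sample_ids,
        genes=ppi.nodes,
        values=values,
        labels=labels,
    )


def generate_dataset(spec: SyntheticSpec):
    """Convenience: (ppi, signal, cohort) for one spec."""
    ppi = generate_ppi(spec)
    signal = plant_signal(ppi, spec)
    cohort = generate_cohort(ppi, signal, spec)
    return ppi, signal, cohort


def write_dataset(spec: SyntheticSpec, out_dir) -> dict[str, str]:
    """Write the standard inputs plus the ground-truth signal gene list.

    Produces ``ppi.tsv`` (edge list), ``expression.tsv`` (TSV with a
    ``label`` column) and ``signal_genes.txt``; returns their paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ppi, signal, cohort = generate_dataset(spec)
    paths = {
        "ppi": str(out / "ppi.tsv"),
        "expression": str(out / "expression.tsv"),
        "signal_genes": str(out / "signal_genes.txt"),
    }
    write_ppi(ppi, paths["ppi"])
    write_expression(cohort, paths["expression"])
    with open(paths["signal_genes"], "wt", encoding="utf-8") as fh:
        fh.write("\n".join(signal.genes) + "\n")
    return paths
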