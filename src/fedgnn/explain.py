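"""Edge/node importance scoring and importance-guided subgraph extraction.

The explainer attributes a trained classifier's decisions to the interaction
edges it passes messages over: each undirected edge gets the absolute
gradient of the predicted-class logit with respect to a multiplicative gate
on that edge's adjacency entries (evaluated at gate = 1), averaged over the
correctly-classified graphs of a cohort. A node inherits the maximum score of
its incident edges, so highly scored nodes sit on highly scored interactions.

Top-scoring genes then seed connected subgraphs, grown greedily along
high-importance neighbours; each subgraph later becomes one ensemble member.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ParameterError, TopologyMismatchError
from .gnn import TrainedModel, _backward, _check_common_topology, _forward, _softmax, _stack_features
from .graphio import PatientGraph, PPINetwork

logger = logging.getLogger(__name__)


@dataclass
class ImportanceScores:
    """Per-gene and per-edge relevance in [0, 1], keyed by the PPI's elements.

    After normalization the maximum score in each table is 1, unless every
    score is exactly 0 (an untrained or all-zero model).
    """

    node_importance: Mapping[str, float]
    edge_importance: Mapping[tuple[str, str], float]


@dataclass(frozen=True)
class SubgraphSpec:
    """A connected induced PPI subgraph (>= 2 genes) seeding one member."""

    genes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if len(self.genes) < 2:
            raise ParameterError("a subgraph needs at least 2 genes")

    def to_network(self) -> PPINetwork:
        return PPINetwork.from_edges(self.edges, extra_nodes=self.genes)

    def is_connected_in(self, ppi: PPINetwork) -> bool:
        import networkx as nx

        sub = ppi.to_networkx().subgraph(self.genes)
        return sub.number_of_nodes() > 0 and nx.is_connected(sub)


def compute_importance(
    model: TrainedModel, graphs: Sequence[PatientGraph]
) -> ImportanceScores:
    """Average absolute edge sensitivity of the predicted-class logit.

    Scores are averaged over the correctly-classified graphs; if no graph is
    classified correctly the average falls back to all graphs, with a
    warning. Both tables are rescaled so their maximum is 1 (skipped when all
    scores are 0, e.g. for an all-zero model).
    """
    if not graphs:
        raise ParameterError("need at least one graph")
    topo = _check_common_topology(graphs)
    if set(topo.nodes) != set(model.node_order):
        raise TopologyMismatchError("graphs do not match the model's gene set")

    a_hat = topo.adjacency(self_loops=True)
    x = _stack_features(graphs)
    logits, caches = _forward(a_hat, x, model.params)
    probs = _softmax(logits)
    pred = (probs[:, 1] > probs[:, 0]).astype(int)

    # backprop the predicted-class logit (not the loss) to the edge gates
    dlogits = np.zeros_like(logits)
    dlogits[np.arange(len(graphs)), pred] = 1.0
    idx = topo.node_index()
    edge_idx = np.array([(idx[a], idx[b]) for a, b in topo.edges], dtype=int)
    if len(edge_idx) == 0:
        edge_idx = np.zeros((0, 2), dtype=int)
    _, edge_grads = _backward(
        a_hat, model.params, caches, dlogits, want_edge_grads=edge_idx
    )

    labels = np.array([g.label for g in graphs])
    correct = pred == labels
    if correct.any():
        sel = correct
    else:
        warnings.warn(
            "no correctly-classified graph; averaging importance over all graphs",
            stacklevel=2,
        )
        sel = np.ones(len(graphs), dtype=bool)
    edge_scores = np.abs(edge_grads[sel]).mean(axis=0) if len(edge_idx) else np.zeros(0)

    node_scores = {g: 0.0 for g in topo.nodes}
    for (a, b), s in zip(topo.edges, edge_scores):
        node_scores[a] = max(node_scores[a], float(s))
        node_scores[b] = max(node_scores[b], float(s))

    e_max = float(edge_scores.max()) if len(edge_scores) else 0.0
    n_max = max(node_scores.values()) if node_scores else 0.0
    edge_imp = {
        e: (float(s) / e_max if e_max > 0 else 0.0)
        for e, s in zip(topo.edges, edge_scores)
    }
    node_imp = {
        g: (s / n_max if n_max > 0 else 0.0) for g, s in node_scores.items()
    }
    return ImportanceScores(node_importance=node_imp, edge_importance=edge_imp)


def extract_subgraphs(
    ppi: PPINetwork,
    scores: ImportanceScores,
    n_members: int = 10,
    member_size: int = 5,
) -> list[SubgraphSpec]:
    """Grow one connected subgraph per top-importance seed gene.

    Seeds are the ``n_members`` highest-importance nodes (ties broken
    lexicographically). Each subgraph starts at its seed and repeatedly adds
    the neighbouring node of highest importance until ``member_size`` nodes
    are reached or the component is exhausted. Subgraphs may overlap; the
    procedure is fully deterministic. Seeds whose component has a single node
    cannot form a valid subgraph and are skipped with a log message.
    """
    if n_members < 1:
        raise ParameterError("n_members must be >= 1")
    if member_size < 2:
        raise ParameterError("member_size must be >= 2")
    if n_members > ppi.n_nodes:
        raise ParameterError(
            f"n_members={n_members} exceeds node count {ppi.n_nodes}"
        )
    if ppi.n_nodes < member_size:
        raise ParameterError(
            f"member_size={member_size} exceeds node count {ppi.n_nodes}"
        )
    imp = scores.node_importance
    missing = set(ppi.nodes) - set(imp)
    if missing:
        raise ParameterError(f"importance missing for genes: {sorted(missing)[:5]}")

    rank = sorted(ppi.nodes, key=lambda g: (-imp[g], g))
    seeds = rank[:n_members]
    neighbors = ppi.neighbors()
    specs: list[SubgraphSpec] = []
    for seed in seeds:
        members = {seed}
        while len(members) < member_size:
            frontier = {
                nb for g in members for nb in neighbors[g] if nb not in members
            }
            if not frontier:
                break
            members.add(min(frontier, key=lambda g: (-imp[g], g)))
        if len(members) < 2:
            logger.warning("seed %s is isolated; skipping its subgraph", seed)
            continue
        genes = tuple(sorted(members))
        edges = tuple(
            e for e in ppi.edges if e[0] in members and e[1] in members
        )
        specs.append(SubgraphSpec(genes=genes, edges=edges))
    return specs


def write_importance_tables(scores: ImportanceScores, node_path, edge_path) -> None:
    """Export (gene, score) and (gene_a, gene_b, score) TSV tables."""
    with open(node_path, "wt", encoding="utf-8") as fh:
        fh.write("gene\timportance\n")
        for g in sorted(scores.node_importance, key=lambda g: (-scores.node_importance[g], g)):
            fh.write(f"{g}\t{scores.node_importance[g]:.6g}\n")
    with open(edge_path, "wt", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\timportance\n")
        for (a, b) in sorted(scores.edge_importance, key=lambda e: (-scores.edge_importance[e], e)):
            fh.write(f"{a}\t{b}\t{scores.edge_importance[(a, b)]:.6g}\n")
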