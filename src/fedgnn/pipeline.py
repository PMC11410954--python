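"""Local (single-site) training pipeline: the per-client workhorse.

Splits a cohort, fits the full-network classifier, scores edge/node
importance, extracts subgraphs, trains the subgraph ensemble and evaluates
it on the held-out splits. The federation driver runs this once per client;
it is equally usable standalone for a single-site analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ensemble import (
    EnsembleClassifier,
    PerformanceReport,
    WeightConfiguration,
    evaluate,
    train_ensemble,
)
from .explain import ImportanceScores, SubgraphSpec, compute_importance, extract_subgraphs
from .gnn import GNNConfig, TrainedModel, train_gnn
from .graphio import DatasetSplit, PatientGraph, split_dataset

DEFAULT_FRACTIONS = (0.6, 0.2, 0.2)  # train / validation / test


@dataclass
class ClientRunConfig:
    """Everything one participant needs to train its local ensemble."""

    gnn: GNNConfig = field(default_factory=GNNConfig)
    n_members: int = 10
    member_size: int = 5
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    interactive: bool = False
    seed: int = 0


@dataclass
class LocalResult:
    """Outcome of one client's local pipeline."""

    ensemble: EnsembleClassifier
    split: DatasetSplit
    train_graphs: list[PatientGraph]
    validation_graphs: list[PatientGraph]
    test_graphs: list[PatientGraph]
    full_model: TrainedModel
    importance: ImportanceScores
    subgraphs: list[SubgraphSpec]
    reports: dict[str, PerformanceReport]


def train_local(
    graphs: Sequence[PatientGraph], config: ClientRunConfig
) -> LocalResult:
    """Run the full local pipeline on one cohort of patient graphs."""
    labels = [g.label for g in graphs]
    split = split_dataset(len(graphs), config.fractions, config.seed, labels=labels)
    train_g = [graphs[i] for i in split.train]
    val_g = [graphs[i] for i in split.validation]
    test_g = [graphs[i] for i in split.test]

    full_model = train_gnn(train_g, config.gnn)
    importance = compute_importance(full_model, train_g)
    topo = graphs[0].topology
    n_members = min(config.n_members, topo.n_nodes)
    subgraphs = extract_subgraphs(topo, importance, n_members, config.member_size)
    ensemble = train_ensemble(train_g, subgraphs, config.gnn, val_g)

    w = WeightConfiguration.default(len(ensemble))
    reports = {
        "validation": evaluate(ensemble, w, val_g, "validation"),
        "test": evaluate(ensemble, w, test_g, "test"),
    }
    return LocalResult(
        ensemble=ensemble,
        split=split,
        train_graphs=train_g,
        validation_graphs=val_g,
        test_graphs=test_g,
        full_model=full_model,
        importance=importance,
        subgraphs=subgraphs,
        reports=reports,
    )
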