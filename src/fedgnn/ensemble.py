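"""Subgraph ensembles: per-subgraph classifiers combined by weighted vote.

One classifier is trained per extracted PPI subgraph, seeing only that
subgraph's genes; members vote with hard labels and the ensemble prediction
is the class with the larger weighted vote sum. Weights default to 1 per
member and may be adjusted by a domain expert (and later averaged across
sites); only non-negativity is required, since rescaling every weight by the
same positive constant cannot change any prediction.

``detach_data`` strips an ensemble down to a shareable payload — topology,
gene names, model parameters, aggregate performance — containing no sample
ids, labels or expression values, so it can leave a clinical site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import DegenerateDataError, FedGNNError, ParameterError, WeightShapeError
from .explain import SubgraphSpec
from .gnn import (
    GNNConfig,
    TrainedModel,
    model_from_dict,
    model_to_dict,
    predict_labels,
)
from .graphio import PatientGraph, PPINetwork

_RATE_FMT = "+.6f"  # fixed-width rates keep payload size data-independent


@dataclass
class PerformanceReport:
    """Confusion counts and derived rates for one split (positive class = 1)."""

    split_name: str
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else 0.0

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else 0.0

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else 0.0

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    def summary(self) -> "PerformanceSummary":
        return PerformanceSummary(
            split_name=self.split_name,
            accuracy=self.accuracy,
            balanced_accuracy=self.balanced_accuracy,
            sensitivity=self.sensitivity,
            specificity=self.specificity,
        )

    def to_dict(self) -> dict:
        return {
            "split_name": self.split_name,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


@dataclass
class PerformanceSummary:
    """Rates-only view of a report; the form shared in detached payloads."""

    split_name: str
    accuracy: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float

    def to_dict(self) -> dict:
        return {
            "split_name": self.split_name,
            "accuracy": format(self.accuracy, _RATE_FMT),
            "balanced_accuracy": format(self.balanced_accuracy, _RATE_FMT),
            "sensitivity": format(self.sensitivity, _RATE_FMT),
            "specificity": format(self.specificity, _RATE_FMT),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PerformanceSummary":
        return cls(
            split_name=d["split_name"],
            accuracy=float(d["accuracy"]),
            balanced_accuracy=float(d["balanced_accuracy"]),
            sensitivity=float(d["sensitivity"]),
            specificity=float(d["specificity"]),
        )


@dataclass
class EnsembleMember:
    """One PPI subgraph with its trained classifier and validation score."""

    subgraph: SubgraphSpec
    model: TrainedModel
    gene_names: tuple[str, ...]
    member_performance: PerformanceReport | PerformanceSummary | None = None

    def __post_init__(self):
        if tuple(self.model.node_order) != tuple(self.subgraph.genes):
            raise ParameterError("model node_order must equal subgraph genes")
        if tuple(self.gene_names) != tuple(self.subgraph.genes):
            raise ParameterError("gene_names must equal subgraph genes")


@dataclass
class EnsembleClassifier:
    """Ordered ensemble members; weight indices refer to this order."""

    members: list[EnsembleMember]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.members:
            raise ParameterError("an ensemble needs at least one member")
        if not self.provenance:
            self.provenance = ["local"] * len(self.members)
        if len(self.provenance) != len(self.members):
            raise ParameterError("provenance length must equal member count")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class WeightConfiguration:
    """Ordered per-member vote weights; every entry defaults to 1."""

    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise WeightShapeError("weights must be a flat sequence")
        if (self.weights < 0).any():
            raise ParameterError("weights must be non-negative")

    @classmethod
    def default(cls, n_members: int) -> "WeightConfiguration":
        return cls(np.ones(n_members))

    def __len__(self) -> int:
        return len(self.weights)


# ---------------------------------------------------------------------------
# Training and voting
# ---------------------------------------------------------------------------


def restrict_graphs(
    graphs: Sequence[PatientGraph], spec: SubgraphSpec
) -> list[PatientGraph]:
    """Project patient graphs onto a subgraph's genes (shared new topology)."""
    topo = spec.to_network()
    parent = graphs[0].topology
    idx = parent.node_index()
    try:
        cols = np.array([idx[g] for g in topo.nodes])
    except KeyError as exc:
        raise ParameterError(f"subgraph gene {exc} not in patient graphs") from exc
    return [
        PatientGraph(topo, g.node_features[cols], g.label, g.sample_id)
        for g in graphs
    ]


def train_ensemble(
    train_graphs: Sequence[PatientGraph],
    subgraphs: Sequence[SubgraphSpec],
    config: GNNConfig,
    eval_graphs: Sequence[PatientGraph],
) -> EnsembleClassifier:
    """Fit one member per subgraph and score each on the validation graphs.

    Each member sees only its subgraph's gene features, with a per-member
    seed offset so members are decorrelated. A member whose training fails
    (e.g. degenerate restriction) is dropped with a warning; at least one
    member must survive. Member order follows subgraph order.
    """
    from .gnn import train_gnn

    if not subgraphs:
        raise ParameterError("need at least one subgraph")
    members: list[EnsembleMember] = []
    for i, spec in enumerate(subgraphs):
        member_cfg = replace(config, seed=config.seed + i)
        try:
            sub_train = restrict_graphs(train_graphs, spec)
            model = train_gnn(sub_train, member_cfg)
        except FedGNNError as exc:
            warnings.warn(f"dropping member {i}: {exc}", stacklevel=2)
            continue
        perf = None
        if eval_graphs:
            sub_eval = restrict_graphs(eval_graphs, spec)
            preds = predict_labels(model, sub_eval)
            labels = np.array([g.label for g in sub_eval])
            perf = _confusion_report(preds, labels, "validation")
        members.append(
            EnsembleMember(
                subgraph=spec,
                model=model,
                gene_names=tuple(spec.genes),
                member_performance=perf,
            )
        )
    if not members:
        raise DegenerateDataError("every ensemble member failed to train")
    return EnsembleClassifier(members=members)


def combine_votes(votes: Sequence[int], weights: Sequence[float]) -> int:
    """Weighted majority over hard member votes; exact ties go to class 0."""
    votes = np.asarray(votes)
    weights = np.asarray(weights, dtype=float)
    if votes.shape != weights.shape:
        raise WeightShapeError(
            f"{len(votes)} votes but {len(weights)} weights"
        )
    score1 = float(weights[votes == 1].sum())
    score0 = float(weights[votes == 0].sum())
    return 1 if score1 > score0 else 0


def _member_votes(
    ensemble: EnsembleClassifier, graphs: Sequence[PatientGraph]
) -> np.ndarray:
    """(n_members, n_graphs) hard votes; each member sees its own genes."""
    rows = []
    for member in ensemble.members:
        sub = restrict_graphs(graphs, member.subgraph)
        rows.append(predict_labels(member.model, sub))
    return np.stack(rows)


def weighted_vote(
    ensemble: EnsembleClassifier,
    weights: WeightConfiguration,
    graph: PatientGraph,
) -> int:
    """Ensemble prediction for one patient graph."""
    if len(weights) != len(ensemble):
        raise WeightShapeError(
            f"{len(ensemble)} members but {len(weights)} weights"
        )
    votes = _member_votes(ensemble, [graph])[:, 0]
    return combine_votes(votes, weights.weights)


def _confusion_report(preds: np.ndarray, labels: np.ndarray, split_name: str) -> PerformanceReport:
    return PerformanceReport(
        split_name=split_name,
        tp=int(((preds == 1) & (labels == 1)).sum()),
        fp=int(((preds == 1) & (labels == 0)).sum()),
        tn=int(((preds == 0) & (labels == 0)).sum()),
        fn=int(((preds == 0) & (labels == 1)).sum()),
    )


def evaluate(
    ensemble: EnsembleClassifier,
    weights: WeightConfiguration,
    graphs: Sequence[PatientGraph],
    split_name: str,
) -> PerformanceReport:
    """Score the weighted ensemble on a labelled split."""
    if not graphs:
        raise ParameterError("cannot evaluate on an empty split")
    if len(weights) != len(ensemble):
        raise WeightShapeError(
            f"{len(ensemble)} members but {len(weights)} weights"
        )
    votes = _member_votes(ensemble, graphs)
    preds = np.array(
        [combine_votes(votes[:, j], weights.weights) for j in range(votes.shape[1])]
    )
    labels = np.array([g.label for g in graphs])
    return _confusion_report(preds, labels, split_name)


# ---------------------------------------------------------------------------
# Detachment (sharing without patient data)
# ---------------------------------------------------------------------------


def detach_data(ensemble: EnsembleClassifier) -> dict:
    """Shareable payload: topologies, gene names, parameters, rate summaries.

    Contains no sample ids, labels or expression values; all numbers use
    fixed-width formatting so the payload size does not depend on how many
    patients the ensemble was trained on.
    """
    members = []
    for member, src in zip(ensemble.members, ensemble.provenance):
        perf = member.member_performance
        summary = perf.summary() if isinstance(perf, PerformanceReport) else perf
        members.append(
            {
                "genes": list(member.gene_names),
                "edges": [list(e) for e in member.subgraph.edges],
                "model": model_to_dict(member.model),
                "performance": summary.to_dict() if summary else None,
                "provenance": src,
            }
        )
    return {"format": "fedgnn-ensemble", "version": 1, "members": members}


def ensemble_from_payload(payload: dict) -> EnsembleClassifier:
    """Rebuild a voting-capable ensemble from a detached payload."""
    if payload.get("format") != "fedgnn-ensemble":
        raise ParameterError("not an ensemble payload")
    members, provenance = [], []
    for m in payload["members"]:
        spec = SubgraphSpec(
            genes=tuple(m["genes"]),
            edges=tuple(tuple(e) for e in m["edges"]),
        )
        perf = (
            PerformanceSummary.from_dict(m["performance"])
            if m.get("performance")
            else None
        )
        members.append(
            EnsembleMember(
                subgraph=spec,
                model=model_from_dict(m["model"]),
                gene_names=tuple(m["genes"]),
                member_performance=perf,
            )
        )
        provenance.append(m.get("provenance", "local"))
    return EnsembleClassifier(members=members, provenance=provenance)
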