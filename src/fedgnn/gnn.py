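"""Graph classification network for attributed patient graphs.

Architecture: ``message_passing_layers`` rounds of sum aggregation over the
(self-loop augmented) adjacency followed by a learned linear transform and
ReLU, then global mean pooling over nodes and a linear head with two logits.
Because the transform weights are shared across nodes, the classifier applies
to any graph over the model's gene set and is equivariant to a consistent
relabelling of the node order.

Everything is plain numpy with explicit reverse-mode gradients, which keeps
training bitwise deterministic under a fixed seed and lets the explainability
module reuse the same backward pass to score per-edge sensitivities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import DegenerateDataError, ParameterError, TopologyMismatchError
from .graphio import PatientGraph, PPINetwork

_IN_DIM = 1  # single expression channel per node


@dataclass(frozen=True)
class GNNConfig:
    """Training hyper-parameters; all randomness flows from ``seed``."""

    message_passing_layers: int = 2
    hidden_dim: int = 32
    epochs: int = 50
    learning_rate: float = 1e-2
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        for name in ("message_passing_layers", "hidden_dim", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be > 0")


def _param_shapes(config: GNNConfig) -> list[tuple[int, ...]]:
    h = config.hidden_dim
    shapes: list[tuple[int, ...]] = []
    d = _IN_DIM
    for _ in range(config.message_passing_layers):
        shapes += [(d, h), (h,)]
        d = h
    shapes += [(d, 2), (2,)]
    return shapes


def _init_params(config: GNNConfig, rng: np.random.Generator) -> list[np.ndarray]:
    params = []
    for shape in _param_shapes(config):
        if len(shape) == 2:
            bound = np.sqrt(6.0 / (shape[0] + shape[1]))  # Glorot uniform
            params.append(rng.uniform(-bound, bound, size=shape))
        else:
            params.append(np.zeros(shape))
    return params


@dataclass
class TrainedModel:
    """A fitted classifier: hyper-parameters, expected gene order, weights.

    ``params`` alternates (W, b) per message-passing layer, then the output
    head. Predictions depend only on (params, graph topology, features).
    ``training_log[0]`` is the pre-training loss; one entry follows per epoch.
    """

    config: GNNConfig
    node_order: tuple[str, ...]
    params: list[np.ndarray]
    training_log: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not self.node_order:
            raise ParameterError("node_order must be non-empty")
        for p in self.params:
            if not np.isfinite(p).all():
                raise ParameterError("model parameters must be finite")

    @property
    def parameters(self) -> np.ndarray:
        """All weights flattened to one float vector (serialization form)."""
        return np.concatenate([p.ravel() for p in self.params])

    @classmethod
    def from_parameters(
        cls,
        config: GNNConfig,
        node_order: Sequence[str],
        flat: np.ndarray,
        training_log: Sequence[float] = (),
    ) -> "TrainedModel":
        flat = np.asarray(flat, dtype=float)
        shapes = _param_shapes(config)
        sizes = [int(np.prod(s)) for s in shapes]
        if flat.size != sum(sizes):
            raise ParameterError(
                f"expected {sum(sizes)} parameters, got {flat.size}"
            )
        params, start = [], 0
        for shape, size in zip(shapes, sizes):
            params.append(flat[start : start + size].reshape(shape).copy())
            start += size
        return cls(config, tuple(node_order), params, list(training_log))


# ---------------------------------------------------------------------------
# Forward / backward
# ---------------------------------------------------------------------------


def _forward(a_hat: np.ndarray, x: np.ndarray, params: list[np.ndarray]):
    """Batched forward pass.

    a_hat: (n, n) adjacency + identity; x: (B, n, in_dim).
    Returns (logits (B, 2), caches) where caches hold per-layer inputs needed
    by both weight and edge-sensitivity gradients.
    """
    n_layers = (len(params) - 2) // 2
    h = x
    layer_caches = []
    for l in range(n_layers):
        w, b = params[2 * l], params[2 * l + 1]
        m = np.matmul(a_hat, h)          # sum aggregation incl. self message
        z = np.matmul(m, w) + b
        h_next = np.maximum(z, 0.0)
        layer_caches.append((h, m, z))
        h = h_next
    pooled = h.mean(axis=1)              # global mean pooling -> (B, hidden)
    w_o, b_o = params[-2], params[-1]
    logits = pooled @ w_o + b_o
    return logits, (layer_caches, h, pooled)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _backward(
    a_hat: np.ndarray,
    params: list[np.ndarray],
    caches,
    dlogits: np.ndarray,
    want_edge_grads: np.ndarray | None = None,
):
    """Reverse pass from an upstream logit gradient.

    Returns (weight gradients, per-graph-per-edge sensitivities or None).
    ``want_edge_grads`` is an (E, 2) int array of node index pairs; the
    sensitivity of an edge is the derivative of the backpropagated quantity
    with respect to a multiplicative gate on that edge's (symmetric) entries
    of the adjacency, evaluated at gate = 1.
    """
    layer_caches, h_last, pooled = caches
    n_layers = (len(params) - 2) // 2
    batch, n_nodes, _ = layer_caches[0][0].shape
    w_o = params[-2]

    grads = [np.zeros_like(p) for p in params]
    grads[-2] = pooled.T @ dlogits
    grads[-1] = dlogits.sum(axis=0)
    d_pooled = dlogits @ w_o.T
    dh = np.broadcast_to(d_pooled[:, None, :] / n_nodes, h_last.shape).copy()

    edge_grads = None
    if want_edge_grads is not None:
        edge_grads = np.zeros((batch, len(want_edge_grads)))
        eu = want_edge_grads[:, 0]
        ev = want_edge_grads[:, 1]

    for l in range(n_layers - 1, -1, -1):
        h_in, m, z = layer_caches[l]
        w = params[2 * l]
        dz = dh * (z > 0)
        grads[2 * l] = np.einsum("bnm,bnh->mh", m, dz)
        grads[2 * l + 1] = dz.sum(axis=(0, 1))
        dm = np.matmul(dz, w.T)          # (B, n, in_l)
        if edge_grads is not None:
            # gate on edge (u,v) scales A[u,v] and A[v,u]:
            # d/dgate = dM[u]·H[v] + dM[v]·H[u]
            edge_grads += np.einsum("beh,beh->be", dm[:, eu, :], h_in[:, ev, :])
            edge_grads += np.einsum("beh,beh->be", dm[:, ev, :], h_in[:, eu, :])
        dh = np.matmul(a_hat.T, dm)
    return grads, edge_grads


def _loss_and_grads(a_hat, x, y, params, want_grads=True):
    logits, caches = _forward(a_hat, x, params)
    probs = _softmax(logits)
    batch = len(y)
    eps = 1e-12
    loss = -np.log(probs[np.arange(batch), y] + eps).mean()
    if not want_grads:
        return loss, None
    dlogits = probs.copy()
    dlogits[np.arange(batch), y] -= 1.0
    dlogits /= batch
    grads, _ = _backward(a_hat, params, caches, dlogits)
    return loss, grads


def _check_common_topology(graphs: Sequence[PatientGraph]) -> PPINetwork:
    topo = graphs[0].topology
    for g in graphs[1:]:
        if g.topology.nodes != topo.nodes or g.topology.edges != topo.edges:
            raise TopologyMismatchError(
                "all graphs in one training set must share the same topology"
            )
    return topo


def _stack_features(graphs: Sequence[PatientGraph]) -> np.ndarray:
    return np.stack([g.node_features for g in graphs])[..., None]


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def train_gnn(graphs: Sequence[PatientGraph], config: GNNConfig) -> TrainedModel:
    """Fit the classifier on a cohort sharing one topology.

    Optimizes softmax cross-entropy with Adam in shuffled mini-batches; all
    random draws (init, shuffles) come from ``config.seed``, so repeated calls
    with identical inputs are bitwise identical.
    """
    if len(graphs) < 2:
        raise DegenerateDataError("need at least 2 training graphs")
    topo = _check_common_topology(graphs)
    if topo.n_nodes == 0:
        raise ParameterError("empty topology")
    y = np.array([g.label for g in graphs])
    if len(set(y.tolist())) < 2:
        raise DegenerateDataError("training set contains a single class")

    a_hat = topo.adjacency(self_loops=True)
    x = _stack_features(graphs)
    rng = np.random.default_rng(config.seed)
    params = _init_params(config, rng)

    # Adam state
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    log = [float(_loss_and_grads(a_hat, x, y, params, want_grads=False)[0])]
    n = len(graphs)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            loss, grads = _loss_and_grads(a_hat, x[sel], y[sel], params)
            epoch_loss += loss * len(sel)
            step += 1
            lr = config.learning_rate * (
                np.sqrt(1 - beta2**step) / (1 - beta1**step)
            )
            for p, g, m, v in zip(params, grads, m_t, v_t):
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g * g
                p -= lr * m / (np.sqrt(v) + eps)
        log.append(float(epoch_loss / n))
    return TrainedModel(config, topo.nodes, params, log)


def _predict_probs(model: TrainedModel, graphs: Sequence[PatientGraph]) -> np.ndarray:
    """Class probabilities for graphs sharing one topology, aligned to it."""
    topo = _check_common_topology(graphs)
    if set(topo.nodes) != set(model.node_order):
        raise TopologyMismatchError(
            "graph node set does not match the model's gene set"
        )
    a_hat = topo.adjacency(self_loops=True)
    logits, _ = _forward(a_hat, _stack_features(graphs), model.params)
    return _softmax(logits)


def predict(model: TrainedModel, graph: PatientGraph) -> tuple[int, tuple[float, float]]:
    """Predicted label and class-probability pair for one patient graph.

    Probabilities sum to 1; the label is the argmax, with exact ties resolved
    to class 0.
    """
    probs = _predict_probs(model, [graph])[0]
    label = 1 if probs[1] > probs[0] else 0
    return label, (float(probs[0]), float(probs[1]))


def predict_labels(model: TrainedModel, graphs: Sequence[PatientGraph]) -> np.ndarray:
    """Vectorized hard predictions for a cohort sharing one topology."""
    probs = _predict_probs(model, graphs)
    return (probs[:, 1] > probs[:, 0]).astype(int)


# serialization -------------------------------------------------------------

_FLOAT_FMT = "+.17e"  # fixed width, exact float64 round-trip


def model_to_dict(model: TrainedModel) -> dict:
    """Versioned, JSON-ready model payload with fixed-width parameters."""
    return {
        "format": "fedgnn-model",
        "version": 1,
        "config": {
            "message_passing_layers": model.config.message_passing_layers,
            "hidden_dim": model.config.hidden_dim,
            "epochs": model.config.epochs,
            "learning_rate": model.config.learning_rate,
            "batch_size": model.config.batch_size,
            "seed": model.config.seed,
        },
        "node_order": list(model.node_order),
        "parameters": [format(v, _FLOAT_FMT) for v in model.parameters],
    }


def model_from_dict(payload: dict) -> TrainedModel:
    if payload.get("format") != "fedgnn-model":
        raise ParameterError("not a model payload")
    config = GNNConfig(**payload["config"])
    flat = np.array([float(v) for v in payload["parameters"]])
    return TrainedModel.from_parameters(config, payload["node_order"], flat)
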