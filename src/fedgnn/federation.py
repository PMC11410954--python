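"""In-process simulation of the coordinator/client federation protocol.

The workflow is a state machine: clients train locally, detach their
ensembles from the patient data and send them to the coordinator, which
concatenates all members into one global ensemble and broadcasts it back.
Each client then evaluates the global model on its own held-out splits. In
interactive mode, clients (standing in for domain experts) may repeatedly
adjust per-member vote weights; submitted weight lists are padded with the
neutral weight 1, averaged elementwise by the coordinator and re-broadcast,
after which each client re-scores the global model on its validation split.

The simulation is synchronous and single-process but drives every
participant through the same state machine a distributed deployment would,
and records a full transcript (transitions, messages, evaluations) that
tests audit — in particular for data locality: no message payload ever
contains sample ids, labels or expression values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Mapping, Sequence

import numpy as np

from .ensemble import (
    EnsembleClassifier,
    PerformanceReport,
    WeightConfiguration,
    detach_data,
    ensemble_from_payload,
    evaluate,
)
from .errors import (
    DeadlockError,
    IllegalTransitionError,
    ParameterError,
    ProtocolError,
)
from .graphio import PatientGraph
from .pipeline import ClientRunConfig, LocalResult, train_local


class FederationState(Enum):
    """Protocol states; the terminal state is shared by both roles."""

    INITIAL = "initial"
    LOCAL_TRAINING = "local_training"
    GLOBAL_MODEL_AGGREGATION = "global_model_aggregation"
    WAITING_FOR_GLOBAL_MODEL = "waiting_for_global_model"
    WEB_CONTROLLED = "web_controlled"
    DISTRIBUTE_WEIGHTS = "distribute_weights"
    WAITING_FOR_CLIENTS_TO_FINISH = "waiting_for_clients_to_finish"
    GLOBAL_WEIGHT_AGGREGATION = "global_weight_aggregation"
    WAITING_FOR_GLOBAL_WEIGHTS = "waiting_for_global_weights"
    TERMINAL = "terminal"


class Role(Enum):
    COORDINATOR = "coordinator"
    CLIENT = "client"


class Event(Enum):
    START = "start"
    PAYLOAD_SENT = "payload_sent"
    MODEL_BROADCAST = "model_broadcast"
    MODEL_RECEIVED = "model_received"
    WEIGHTS_SUBMITTED = "weights_submitted"
    WEIGHTS_SENT = "weights_sent"
    WEIGHT_LISTS_RECEIVED = "weight_lists_received"
    WEIGHTS_BROADCAST = "weights_broadcast"
    GLOBAL_WEIGHTS_RECEIVED = "global_weights_received"
    TERMINATE = "terminate"
    ALL_CLIENTS_DONE = "all_clients_done"


S, R, E = FederationState, Role, Event

#: which states each role may occupy
ROLE_STATES: dict[Role, frozenset[FederationState]] = {
    R.COORDINATOR: frozenset(
        {
            S.INITIAL,
            S.GLOBAL_MODEL_AGGREGATION,
            S.WAITING_FOR_CLIENTS_TO_FINISH,
            S.GLOBAL_WEIGHT_AGGREGATION,
            S.TERMINAL,
        }
    ),
    R.CLIENT: frozenset(
        s
        for s in S
        if s not in (S.GLOBAL_MODEL_AGGREGATION, S.GLOBAL_WEIGHT_AGGREGATION)
    ),
}

_TRANSITIONS: dict[tuple[FederationState, Role, Event], FederationState] = {
    (S.INITIAL, R.COORDINATOR, E.START): S.GLOBAL_MODEL_AGGREGATION,
    (S.INITIAL, R.CLIENT, E.START): S.LOCAL_TRAINING,
    (S.LOCAL_TRAINING, R.CLIENT, E.PAYLOAD_SENT): S.WAITING_FOR_GLOBAL_MODEL,
    (S.GLOBAL_MODEL_AGGREGATION, R.COORDINATOR, E.MODEL_BROADCAST): S.WAITING_FOR_CLIENTS_TO_FINISH,
    # MODEL_RECEIVED branches on the interactive flag; handled in step()
    (S.WEB_CONTROLLED, R.CLIENT, E.WEIGHTS_SUBMITTED): S.DISTRIBUTE_WEIGHTS,
    (S.WEB_CONTROLLED, R.CLIENT, E.TERMINATE): S.TERMINAL,
    (S.DISTRIBUTE_WEIGHTS, R.CLIENT, E.WEIGHTS_SENT): S.WAITING_FOR_GLOBAL_WEIGHTS,
    (S.WAITING_FOR_CLIENTS_TO_FINISH, R.COORDINATOR, E.WEIGHT_LISTS_RECEIVED): S.GLOBAL_WEIGHT_AGGREGATION,
    (S.WAITING_FOR_CLIENTS_TO_FINISH, R.COORDINATOR, E.ALL_CLIENTS_DONE): S.TERMINAL,
    (S.GLOBAL_WEIGHT_AGGREGATION, R.COORDINATOR, E.WEIGHTS_BROADCAST): S.WAITING_FOR_CLIENTS_TO_FINISH,
    (S.WAITING_FOR_GLOBAL_WEIGHTS, R.CLIENT, E.GLOBAL_WEIGHTS_RECEIVED): S.WEB_CONTROLLED,
}


def step(
    current: FederationState,
    role: Role,
    event: Event,
    *,
    interactive: bool = False,
) -> FederationState:
    """One state-machine transition; anything unlisted is illegal.

    ``interactive`` only matters for a client receiving the global model:
    with the flag unset the workflow is complete and the client terminates,
    otherwise it enters the expert-controlled state.
    """
    if current not in ROLE_STATES[role]:
        raise IllegalTransitionError(
            f"role {role.value} may not occupy state {current.value}"
        )
    if (current, role, event) == (S.WAITING_FOR_GLOBAL_MODEL, R.CLIENT, E.MODEL_RECEIVED):
        return S.WEB_CONTROLLED if interactive else S.TERMINAL
    try:
        return _TRANSITIONS[(current, role, event)]
    except KeyError:
        raise IllegalTransitionError(
            f"no transition from {current.value} for role {role.value} "
            f"on event {event.value}"
        ) from None


def legal_events(current: FederationState, role: Role) -> list[Event]:
    """Events with a defined transition from (current, role); for fuzzing."""
    if current not in ROLE_STATES[role]:
        return []
    events = [
        e for (s, r, e) in _TRANSITIONS if s == current and r == role
    ]
    if (current, role) == (S.WAITING_FOR_GLOBAL_MODEL, R.CLIENT):
        events.append(E.MODEL_RECEIVED)
    return events


class MessageKind(Enum):
    ENSEMBLE_PAYLOAD = "ensemble_payload"   # client -> coordinator
    GLOBAL_MODEL = "global_model"           # coordinator -> clients
    WEIGHT_VECTOR = "weight_vector"         # client -> coordinator
    GLOBAL_WEIGHTS = "global_weights"       # coordinator -> clients
    TERMINATE = "terminate"                 # client -> coordinator


@dataclass
class Message:
    sender: str
    recipient: str
    kind: MessageKind
    payload: Any = None


# transcript records -------------------------------------------------------


@dataclass
class TransitionRecord:
    participant: str
    role: Role
    source: FederationState
    event: Event
    target: FederationState


@dataclass
class MessageRecord:
    message: Message


@dataclass
class EvaluationRecord:
    """A performance (re-)calculation; notes which model and split it used."""

    participant: str
    scope: str        # "local", "global", "interactive"
    split_name: str
    balanced_accuracy: float


Transcript = list  # of TransitionRecord | MessageRecord | EvaluationRecord


@dataclass
class FederationResult:
    global_model: EnsembleClassifier
    per_client_reports: dict[str, dict]
    aggregated_weights: WeightConfiguration | None
    transcript: Transcript
    local_results: dict[str, LocalResult] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Aggregation rules
# ---------------------------------------------------------------------------


def aggregate_models(
    payloads: Mapping[str, dict], client_order: Sequence[str]
) -> EnsembleClassifier:
    """Concatenate all clients' detached ensembles into the global model.

    Members are appended in ``client_order``, preserving each client's
    internal member order; provenance records the source client per member.
    A registered client without a payload is a protocol error — the global
    model is never silently partial.
    """
    if not client_order:
        raise ProtocolError("no clients registered")
    missing = [c for c in client_order if c not in payloads]
    if missing:
        raise ProtocolError(f"missing payload from client(s): {missing}")
    members, provenance = [], []
    for client in client_order:
        local = ensemble_from_payload(payloads[client])
        members.extend(local.members)
        provenance.extend([client] * len(local.members))
    return EnsembleClassifier(members=members, provenance=provenance)


def aggregate_weights(
    weight_lists: Sequence[Sequence[float]], target_length: int
) -> WeightConfiguration:
    """Average expert weight lists elementwise into one global configuration.

    Lists shorter than ``target_length`` are padded with the neutral default
    weight 1 before averaging; longer lists are invalid. Entry j of the
    result is the arithmetic mean of entry j over all submitted lists.
    """
    if not weight_lists:
        raise ProtocolError("no weight lists to aggregate")
    padded = []
    for wl in weight_lists:
        arr = np.asarray(list(wl), dtype=float)
        if (arr < 0).any():
            raise ParameterError("weights must be non-negative")
        if len(arr) > target_length:
            raise ParameterError(
                f"weight list of length {len(arr)} exceeds member count {target_length}"
            )
        padded.append(np.concatenate([arr, np.ones(target_length - len(arr))]))
    return WeightConfiguration(np.mean(padded, axis=0))


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

#: scripted expert actions understood by run_federation
#:   ("set_weights", [..])     adjust local copy, re-score on validation only
#:   ("submit_weights", [..])  share with the coordinator for averaging
#:   ("terminate",)            leave the workflow
Action = tuple


class _Participant:
    def __init__(self, name: str, role: Role, transcript: Transcript, interactive=False):
        self.name = name
        self.role = role
        self.state = S.INITIAL
        self.interactive = interactive
        self._transcript = transcript

    def fire(self, event: Event) -> None:
        new = step(self.state, self.role, event, interactive=self.interactive)
        self._transcript.append(
            TransitionRecord(self.name, self.role, self.state, event, new)
        )
        self.state = new


def _send(transcript: Transcript, message: Message) -> Message:
    # messages must be JSON-serializable: enforces that no live objects
    # (and hence no hidden patient data) cross participants
    json.dumps(message.payload)
    transcript.append(MessageRecord(message))
    return message


def run_federation(
    client_graphs: Mapping[str, Sequence[PatientGraph]],
    run_configs: Mapping[str, ClientRunConfig],
    scripted_actions: Mapping[str, Sequence[Action]] | None = None,
    seed: int | None = None,
) -> FederationResult:
    """Execute the full coordinator/client workflow in-process.

    ``client_graphs`` maps client ids to their private patient graphs; the
    coordinator holds no data. ``scripted_actions`` drives interactive
    clients; every weight-aggregation round blocks until each still-active
    client has submitted, and an active client left without a next scripted
    action raises :class:`DeadlockError` with the transcript attached.
    ``seed`` (optional) overrides each client's split/training seed with
    ``seed + index`` in registration order.
    """
    if not client_graphs:
        raise ProtocolError("need at least one client")
    scripted_actions = dict(scripted_actions or {})
    client_order = list(client_graphs)
    transcript: Transcript = []

    coordinator = _Participant("coordinator", R.COORDINATOR, transcript)
    clients = {
        cid: _Participant(
            cid, R.CLIENT, transcript, interactive=run_configs[cid].interactive
        )
        for cid in client_order
    }

    # State 1: coordinator registers the client count and starts aggregating
    coordinator.fire(E.START)

    # State 2: each client trains locally and detaches its ensemble
    local_results: dict[str, LocalResult] = {}
    payloads: dict[str, dict] = {}
    for i, cid in enumerate(client_order):
        cfg = run_configs[cid]
        if seed is not None:
            from dataclasses import replace as _replace

            cfg = _replace(
                cfg, seed=seed + i, gnn=_replace(cfg.gnn, seed=seed + i)
            )
        clients[cid].fire(E.START)
        result = train_local(client_graphs[cid], cfg)
        local_results[cid] = result
        payload = detach_data(result.ensemble)
        _send(transcript, Message(cid, "coordinator", MessageKind.ENSEMBLE_PAYLOAD, payload))
        payloads[cid] = payload
        clients[cid].fire(E.PAYLOAD_SENT)
        for split in ("validation", "test"):
            transcript.append(
                EvaluationRecord(
                    cid, "local", split, result.reports[split].balanced_accuracy
                )
            )

    # State 3: concatenate and broadcast the global model
    global_model = aggregate_models(payloads, client_order)
    global_payload = detach_data(global_model)
    for cid in client_order:
        _send(transcript, Message("coordinator", cid, MessageKind.GLOBAL_MODEL, global_payload))
    coordinator.fire(E.MODEL_BROADCAST)

    # State 4: clients score the global model on their own held-out splits
    per_client_reports: dict[str, dict] = {}
    client_global: dict[str, EnsembleClassifier] = {}
    client_weights: dict[str, WeightConfiguration] = {}
    active: list[str] = []
    for cid in client_order:
        res = local_results[cid]
        g_model = ensemble_from_payload(global_payload)
        client_global[cid] = g_model
        client_weights[cid] = WeightConfiguration.default(len(g_model))
        g_reports = {
            "validation": evaluate(
                g_model, client_weights[cid], res.validation_graphs, "validation"
            ),
            "test": evaluate(g_model, client_weights[cid], res.test_graphs, "test"),
        }
        for split, rep in g_reports.items():
            transcript.append(
                EvaluationRecord(cid, "global", split, rep.balanced_accuracy)
            )
        per_client_reports[cid] = {
            "local": dict(res.reports),
            "global": g_reports,
            "interactive": [],
        }
        clients[cid].fire(E.MODEL_RECEIVED)
        if clients[cid].state is S.TERMINAL:
            _send(transcript, Message(cid, "coordinator", MessageKind.TERMINATE, None))
        else:
            active.append(cid)

    def _rescore(cid: str, weights: WeightConfiguration) -> PerformanceReport:
        # every weight change is re-scored on the validation split only
        res = local_results[cid]
        rep = evaluate(
            client_global[cid], weights, res.validation_graphs, "validation"
        )
        transcript.append(
            EvaluationRecord(cid, "interactive", "validation", rep.balanced_accuracy)
        )
        per_client_reports[cid]["interactive"].append(
            {"weights": weights.weights.tolist(), "report": rep}
        )
        return rep

    # States 5-9: interactive weight rounds until every client terminates
    aggregated: WeightConfiguration | None = None
    target_len = len(global_model)
    while active:
        submissions: dict[str, list[float]] = {}
        for cid in list(active):
            queue = list(scripted_actions.get(cid, []))
            # consume local explorations until this client submits or leaves
            while True:
                if not queue:
                    raise DeadlockError(
                        f"active client {cid!r} has no next scripted action",
                        transcript,
                    )
                action = queue.pop(0)
                kind = action[0]
                if kind == "set_weights":
                    w = WeightConfiguration(np.asarray(action[1], dtype=float))
                    if len(w) != target_len:
                        raise ParameterError(
                            "set_weights length must equal global member count"
                        )
                    client_weights[cid] = w
                    _rescore(cid, w)
                    continue
                if kind == "submit_weights":
                    clients[cid].fire(E.WEIGHTS_SUBMITTED)
                    submissions[cid] = [float(v) for v in action[1]]
                    _send(
                        transcript,
                        Message(cid, "coordinator", MessageKind.WEIGHT_VECTOR, submissions[cid]),
                    )
                    clients[cid].fire(E.WEIGHTS_SENT)
                    break
                if kind == "terminate":
                    clients[cid].fire(E.TERMINATE)
                    _send(transcript, Message(cid, "coordinator", MessageKind.TERMINATE, None))
                    active.remove(cid)
                    break
                raise ParameterError(f"unknown scripted action {kind!r}")
            scripted_actions[cid] = queue

        if submissions:
            # State 7 -> 8: aggregate the freshly submitted lists
            coordinator.fire(E.WEIGHT_LISTS_RECEIVED)
            aggregated = aggregate_weights(
                [submissions[cid] for cid in client_order if cid in submissions],
                target_len,
            )
            weights_payload = aggregated.weights.tolist()
            for cid in list(submissions):
                _send(
                    transcript,
                    Message("coordinator", cid, MessageKind.GLOBAL_WEIGHTS, weights_payload),
                )
            coordinator.fire(E.WEIGHTS_BROADCAST)
            # State 9: submitters apply the averaged weights and re-score
            for cid in submissions:
                clients[cid].fire(E.GLOBAL_WEIGHTS_RECEIVED)
                client_weights[cid] = WeightConfiguration(
                    np.asarray(weights_payload)
                )
                _rescore(cid, client_weights[cid])

    # State 7: no clients active anymore -> the coordinator terminates
    coordinator.fire(E.ALL_CLIENTS_DONE)

    return FederationResult(
        global_model=global_model,
        per_client_reports=per_client_reports,
        aggregated_weights=aggregated,
        transcript=transcript,
        local_results=local_results,
    )


# ---------------------------------------------------------------------------
# Transcript auditing
# ---------------------------------------------------------------------------


def transcript_payload_text(transcript: Transcript) -> str:
    """All cross-participant payloads, serialized; the audit surface."""
    chunks = []
    for entry in transcript:
        if isinstance(entry, MessageRecord):
            chunks.append(json.dumps(entry.message.payload))
    return "\n".join(chunks)


def audit_data_locality(
    transcript: Transcript,
    sample_ids: Sequence[str] = (),
    expression_values: Sequence[float] = (),
) -> list[str]:
    """Return violations: forbidden patient-level tokens found in payloads.

    Checks every message payload for the given sample identifiers, for the
    textual representation of given expression values, and for any
    label-like per-sample field names. An empty return means the detachment
    contract held for the whole run.
    """
    text = transcript_payload_text(transcript)
    violations = []
    for sid in sample_ids:
        if f'"{sid}"' in text or f"'{sid}'" in text:
            violations.append(f"sample id {sid!r} found in a payload")
    for v in expression_values:
        for token in (repr(float(v)), format(float(v), "+.17e")):
            if token in text:
                violations.append(f"expression value {v!r} found in a payload")
                break
    for forbidden_key in ('"sample_id"', '"sample_ids"', '"labels"'):
        if forbidden_key in text:
            violations.append(f"per-sample field {forbidden_key} found in a payload")
    return violations


def transcript_ends_terminal(transcript: Transcript) -> bool:
    """True when every participant's last transition lands in TERMINAL."""
    last: dict[str, FederationState] = {}
    first: dict[str, FederationState] = {}
    for entry in transcript:
        if isinstance(entry, TransitionRecord):
            first.setdefault(entry.participant, entry.source)
            last[entry.participant] = entry.target
    return (
        bool(last)
        and all(s is S.INITIAL for s in first.values())
        and all(s is S.TERMINAL for s in last.values())
    )
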