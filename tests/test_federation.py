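"""Protocol state machine, aggregation rules and the simulation driver."""

import json

import numpy as np
import pytest

import fedgnn as f
from fedgnn.federation import (
    ROLE_STATES,
    EvaluationRecord,
    MessageRecord,
    TransitionRecord,
    legal_events,
    transcript_ends_terminal,
)
from tests.conftest import make_fed_inputs

S, R, E = f.FederationState, f.Role, f.Event


class TestStateMachine:
    def test_state_inventory(self):
        assert len(list(S)) == 10
        # coordinator-only aggregation states are closed to clients
        assert S.GLOBAL_MODEL_AGGREGATION not in ROLE_STATES[R.CLIENT]
        assert S.GLOBAL_WEIGHT_AGGREGATION not in ROLE_STATES[R.CLIENT]
        assert S.LOCAL_TRAINING not in ROLE_STATES[R.COORDINATOR]
        assert S.WEB_CONTROLLED not in ROLE_STATES[R.COORDINATOR]
        assert S.TERMINAL in ROLE_STATES[R.CLIENT] & ROLE_STATES[R.COORDINATOR]
        assert S.INITIAL in ROLE_STATES[R.CLIENT] & ROLE_STATES[R.COORDINATOR]

    @pytest.mark.parametrize(
        "current, role, event, kwargs, expected",
        [
            (S.INITIAL, R.COORDINATOR, E.START, {}, S.GLOBAL_MODEL_AGGREGATION),
            (S.INITIAL, R.CLIENT, E.START, {}, S.LOCAL_TRAINING),
            (S.LOCAL_TRAINING, R.CLIENT, E.PAYLOAD_SENT, {}, S.WAITING_FOR_GLOBAL_MODEL),
            (S.GLOBAL_MODEL_AGGREGATION, R.COORDINATOR, E.MODEL_BROADCAST, {}, S.WAITING_FOR_CLIENTS_TO_FINISH),
            (S.WAITING_FOR_GLOBAL_MODEL, R.CLIENT, E.MODEL_RECEIVED, {"interactive": False}, S.TERMINAL),
            (S.WAITING_FOR_GLOBAL_MODEL, R.CLIENT, E.MODEL_RECEIVED, {"interactive": True}, S.WEB_CONTROLLED),
            (S.WEB_CONTROLLED, R.CLIENT, E.WEIGHTS_SUBMITTED, {}, S.DISTRIBUTE_WEIGHTS),
            (S.WEB_CONTROLLED, R.CLIENT, E.TERMINATE, {}, S.TERMINAL),
            (S.DISTRIBUTE_WEIGHTS, R.CLIENT, E.WEIGHTS_SENT, {}, S.WAITING_FOR_GLOBAL_WEIGHTS),
            (S.WAITING_FOR_CLIENTS_TO_FINISH, R.COORDINATOR, E.WEIGHT_LISTS_RECEIVED, {}, S.GLOBAL_WEIGHT_AGGREGATION),
            (S.WAITING_FOR_CLIENTS_TO_FINISH, R.COORDINATOR, E.ALL_CLIENTS_DONE, {}, S.TERMINAL),
            (S.GLOBAL_WEIGHT_AGGREGATION, R.COORDINATOR, E.WEIGHTS_BROADCAST, {}, S.WAITING_FOR_CLIENTS_TO_FINISH),
            (S.WAITING_FOR_GLOBAL_WEIGHTS, R.CLIENT, E.GLOBAL_WEIGHTS_RECEIVED, {}, S.WEB_CONTROLLED),
        ],
    )
    def test_defined_transitions(self, current, role, event, kwargs, expected):
        assert f.step(current, role, event, **kwargs) is expected

    @pytest.mark.parametrize(
        "current, role, event",
        [
            (S.LOCAL_TRAINING, R.COORDINATOR, E.PAYLOAD_SENT),  # wrong role
            (S.WEB_CONTROLLED, R.COORDINATOR, E.TERMINATE),
            (S.INITIAL, R.CLIENT, E.MODEL_RECEIVED),            # wrong event
            (S.TERMINAL, R.CLIENT, E.START),
            # one-shot rule: a second submission while awaiting averaged
            # weights mirrors the blocked UI and is illegal
            (S.WAITING_FOR_GLOBAL_WEIGHTS, R.CLIENT, E.WEIGHTS_SUBMITTED),
        ],
    )
    def test_illegal_transitions_raise(self, current, role, event):
        with pytest.raises(f.IllegalTransitionError):
            f.step(current, role, event)

    def test_random_walks_stay_legal(self):
        """Fuzz: following any sequence of legal events never leaves the
        role's permitted states; TERMINAL is absorbing."""
        rng = np.random.default_rng(0)
        for role in (R.COORDINATOR, R.CLIENT):
            for _ in range(100):
                state = S.INITIAL
                interactive = bool(rng.integers(2))
                for _ in range(30):
                    events = legal_events(state, role)
                    if not events:
                        assert state is S.TERMINAL
                        break
                    event = events[int(rng.integers(len(events)))]
                    state = f.step(state, role, event, interactive=interactive)
                    assert state in ROLE_STATES[role]


class TestAggregateWeights:
    @pytest.mark.parametrize(
        "lists, target, expected",
        [
            ([[2, 0, 1], [0, 0, 1]], 3, [1.0, 0.0, 1.0]),
            ([[2], [0, 4]], 2, [1.0, 2.5]),  # pad [2] -> [2, 1], then mean
            ([[3, 3]], 2, [3.0, 3.0]),
            ([[], []], 2, [1.0, 1.0]),       # all missing -> neutral default
        ],
    )
    def test_pad_then_elementwise_mean(self, lists, target, expected):
        result = f.aggregate_weights(lists, target)
        assert result.weights.tolist() == expected

    def test_idempotent_on_identical_lists(self):
        for k in (1, 2, 5):
            result = f.aggregate_weights([[2.0, 0.5, 1.0]] * k, 3)
            assert result.weights.tolist() == [2.0, 0.5, 1.0]

    def test_errors(self):
        with pytest.raises(f.ProtocolError):
            f.aggregate_weights([], 3)
        with pytest.raises(f.ParameterError):
            f.aggregate_weights([[-1.0]], 2)
        with pytest.raises(f.ParameterError):
            f.aggregate_weights([[1, 1, 1, 1]], 3)


@pytest.fixture(scope="module")
def two_client_run():
    client_graphs, cfgs, cohort, _ = make_fed_inputs(2, n_members=3, seed=21)
    result = f.run_federation(client_graphs, cfgs)
    return result, client_graphs, cohort


class TestAggregateModels:
    def test_concatenation_and_provenance(self, two_client_run):
        result, client_graphs, _ = two_client_run
        locals_ = result.local_results
        expected = sum(len(r.ensemble) for r in locals_.values())
        assert len(result.global_model) == expected
        assert result.global_model.provenance == [
            cid for cid in client_graphs for _ in range(len(locals_[cid].ensemble))
        ]

    def test_single_client_identity(self, tiny_local_result, tiny_dataset):
        payload = f.detach_data(tiny_local_result.ensemble)
        global_model = f.aggregate_models({"only": payload}, ["only"])
        assert len(global_model) == len(tiny_local_result.ensemble)
        w = f.WeightConfiguration.default(len(global_model))
        for g in tiny_dataset[3][:4]:
            assert f.weighted_vote(global_model, w, g) == f.weighted_vote(
                tiny_local_result.ensemble,
                f.WeightConfiguration.default(len(tiny_local_result.ensemble)),
                g,
            )

    def test_client_order_controls_member_order(self, two_client_run):
        result, client_graphs, _ = two_client_run
        payloads = {
            cid: f.detach_data(res.ensemble)
            for cid, res in result.local_results.items()
        }
        ids = list(client_graphs)
        ab = f.aggregate_models(payloads, ids)
        ba = f.aggregate_models(payloads, ids[::-1])
        genes = lambda m: sorted(mem.gene_names for mem in m.members)
        assert genes(ab) == genes(ba)                      # same multiset
        assert ab.provenance != ba.provenance              # different order

    def test_missing_payload_is_protocol_error(self, tiny_local_result):
        payload = f.detach_data(tiny_local_result.ensemble)
        with pytest.raises(f.ProtocolError):
            f.aggregate_models({"a": payload}, ["a", "b"])


class TestRunFederation:
    def test_batch_run_reports_and_termination(self, two_client_run):
        result, client_graphs, _ = two_client_run
        assert transcript_ends_terminal(result.transcript)
        for cid in client_graphs:
            reports = result.per_client_reports[cid]
            for scope in ("local", "global"):
                assert set(reports[scope]) == {"validation", "test"}
            # global reports come from the local held-out splits
            res = result.local_results[cid]
            assert (
                reports["global"]["test"].tp + reports["global"]["test"].fp
                + reports["global"]["test"].tn + reports["global"]["test"].fn
            ) == len(res.test_graphs)

    def test_data_locality_audit(self, two_client_run):
        result, _, cohort = two_client_run
        violations = f.audit_data_locality(
            result.transcript,
            sample_ids=cohort.sample_ids,
            expression_values=cohort.values.ravel()[:100],
        )
        assert violations == []

    def test_all_ones_submission_broadcasts_ones(self):
        client_graphs, cfgs, _, _ = make_fed_inputs(3, n_members=2, seed=31)
        for cfg in cfgs.values():
            cfg.interactive = True
        n_global = 6
        actions = {
            cid: [("submit_weights", [1.0] * n_global), ("terminate",)]
            for cid in client_graphs
        }
        result = f.run_federation(client_graphs, cfgs, actions)
        assert result.aggregated_weights.weights.tolist() == [1.0] * n_global
        assert transcript_ends_terminal(result.transcript)

    def test_immediate_terminate_reaches_terminal(self):
        client_graphs, cfgs, _, _ = make_fed_inputs(1, n_members=2, seed=41)
        next(iter(cfgs.values())).interactive = True
        actions = {next(iter(client_graphs)): [("terminate",)]}
        result = f.run_federation(client_graphs, cfgs, actions)
        assert transcript_ends_terminal(result.transcript)

    def test_deadlock_detection(self):
        client_graphs, cfgs, _, _ = make_fed_inputs(1, n_members=2, seed=43)
        next(iter(cfgs.values())).interactive = True
        with pytest.raises(f.DeadlockError) as exc:
            f.run_federation(client_graphs, cfgs, {})
        assert exc.value.transcript  # transcript attached for post-mortem

    def test_weight_changes_rescore_on_validation_only(self):
        client_graphs, cfgs, _, _ = make_fed_inputs(1, n_members=2, seed=47)
        cid = next(iter(client_graphs))
        cfgs[cid].interactive = True
        actions = {
            cid: [
                ("set_weights", [2.0, 0.0]),
                ("submit_weights", [2.0, 0.0]),
                ("terminate",),
            ]
        }
        result = f.run_federation(client_graphs, cfgs, actions)
        interactive_evals = [
            e
            for e in result.transcript
            if isinstance(e, EvaluationRecord) and e.scope == "interactive"
        ]
        assert len(interactive_evals) == 2  # one set_weights + one averaged
        assert all(e.split_name == "validation" for e in interactive_evals)
        assert result.per_client_reports[cid]["interactive"]

    def test_message_payloads_are_json_serializable(self, two_client_run):
        result, _, _ = two_client_run
        for entry in result.transcript:
            if isinstance(entry, MessageRecord):
                json.dumps(entry.message.payload)

    def test_transcripts_start_initial(self, two_client_run):
        result, _, _ = two_client_run
        firsts = {}
        for entry in result.transcript:
            if isinstance(entry, TransitionRecord):
                firsts.setdefault(entry.participant, entry.source)
        assert set(firsts.values()) == {S.INITIAL}
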