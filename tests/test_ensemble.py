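"""Ensemble training, weighted majority voting and data detachment."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fedgnn as f
from fedgnn.ensemble import PerformanceReport, _member_votes


def brute_force_vote(votes, weights):
    """Independent oracle: accumulate both class scores, argmax, tie -> 0."""
    score = {0: 0.0, 1: 0.0}
    for v, w in zip(votes, weights):
        score[v] += w
    if score[1] > score[0]:
        return 1
    return 0


def test_brute_force_oracle_is_sane():
    assert brute_force_vote([1, 1, 0], [1, 1, 1]) == 1
    assert brute_force_vote([1, 0], [1, 1]) == 0


class TestCombineVotes:
    @pytest.mark.parametrize(
        "votes, weights, expected",
        [
            ((1, 1, 0), (1, 1, 1), 1),   # unweighted majority
            ((1, 1, 0), (0, 0, 5), 0),   # single dominant weight
            ((1, 0), (1, 1), 0),         # exact tie -> class 0
        ],
    )
    def test_examples(self, votes, weights, expected):
        assert f.combine_votes(votes, weights) == expected

    def test_length_mismatch(self):
        with pytest.raises(f.WeightShapeError):
            f.combine_votes([1, 0], [1.0])

    @given(
        votes=st.lists(st.integers(0, 1), min_size=1, max_size=4),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_enumeration(self, votes, data):
        weights = data.draw(
            st.lists(
                st.floats(0, 10, allow_nan=False),
                min_size=len(votes),
                max_size=len(votes),
            )
        )
        assert f.combine_votes(votes, weights) == brute_force_vote(votes, weights)

    @given(
        votes=st.lists(st.integers(0, 1), min_size=1, max_size=8),
        w=st.floats(0.01, 100),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_uniform_weights_reproduce_plain_majority(self, votes, w):
        uniform = [w] * len(votes)
        plain = 1 if sum(votes) * 2 > len(votes) else 0
        assert f.combine_votes(votes, uniform) == plain

    @given(
        votes=st.lists(st.integers(0, 1), min_size=1, max_size=6),
        data=st.data(),
        scale=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_positive_rescaling_never_changes_prediction(self, votes, data, scale):
        weights = data.draw(
            st.lists(
                st.floats(0, 10), min_size=len(votes), max_size=len(votes)
            )
        )
        before = f.combine_votes(votes, weights)
        after = f.combine_votes(votes, [w * scale for w in weights])
        assert before == after

    @given(
        votes=st.lists(st.integers(0, 1), min_size=1, max_size=6),
        data=st.data(),
        bump=st.floats(0.1, 50),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_raising_a_weight_never_flips_away_from_that_vote(
        self, votes, data, bump
    ):
        weights = data.draw(
            st.lists(
                st.floats(0, 10), min_size=len(votes), max_size=len(votes)
            )
        )
        i = data.draw(st.integers(0, len(votes) - 1))
        before = f.combine_votes(votes, weights)
        bumped = list(weights)
        bumped[i] += bump
        after = f.combine_votes(votes, bumped)
        if before == votes[i]:
            assert after == votes[i]


class TestPerformanceReport:
    def test_rate_identities(self):
        rep = PerformanceReport("test", tp=3, fn=1, tn=2, fp=2)
        assert rep.sensitivity == pytest.approx(0.75)
        assert rep.specificity == pytest.approx(0.5)
        assert rep.balanced_accuracy == pytest.approx(0.625)
        assert rep.accuracy == pytest.approx(5 / 8)

    def test_summary_round_trip(self):
        rep = PerformanceReport("validation", tp=3, fn=1, tn=2, fp=2)
        back = f.PerformanceSummary.from_dict(rep.summary().to_dict())
        assert back.balanced_accuracy == pytest.approx(rep.balanced_accuracy)


class TestTrainEnsemble:
    def test_one_member_per_subgraph_in_order(self, tiny_local_result):
        res = tiny_local_result
        assert len(res.ensemble) == len(res.subgraphs)
        for member, spec in zip(res.ensemble.members, res.subgraphs):
            assert member.subgraph == spec
            assert tuple(member.model.node_order) == spec.genes
            assert member.gene_names == spec.genes
            assert member.member_performance.split_name == "validation"

    def test_signal_member_scores_best(self):
        """Across seeds, the member overlapping the planted subnetwork most
        is usually the member with the highest validation score."""
        wins = 0
        for seed in range(6):
            spec = f.SyntheticSpec(
                n_genes=30, n_patients_per_class=30, signal_size=4,
                effect_size=2.0, seed=seed,
            )
            ppi, signal, cohort = f.generate_dataset(spec)
            graphs = f.build_patient_graphs(cohort, ppi)
            cfg = f.ClientRunConfig(
                gnn=f.GNNConfig(epochs=20, seed=seed), n_members=6,
                member_size=4, seed=seed,
            )
            res = f.train_local(graphs, cfg)
            target = set(signal.genes)
            overlap = [len(target & set(m.gene_names)) for m in res.ensemble.members]
            scores = [m.member_performance.balanced_accuracy for m in res.ensemble.members]
            best_score = max(range(len(scores)), key=scores.__getitem__)
            wins += overlap[best_score] == max(overlap)
        assert wins >= 4

    def test_weighted_vote_plumbing(self, tiny_local_result, tiny_dataset):
        res = tiny_local_result
        graph = tiny_dataset[3][0]
        w = f.WeightConfiguration.default(len(res.ensemble))
        assert f.weighted_vote(res.ensemble, w, graph) in (0, 1)
        with pytest.raises(f.WeightShapeError):
            f.weighted_vote(res.ensemble, f.WeightConfiguration([1.0]), graph)

    def test_negative_weights_rejected(self):
        with pytest.raises(f.ParameterError):
            f.WeightConfiguration([1.0, -0.5])


class TestEvaluate:
    def test_identities_hold_on_real_split(self, tiny_local_result):
        rep = tiny_local_result.reports["test"]
        total = rep.tp + rep.fp + rep.tn + rep.fn
        assert total == len(tiny_local_result.test_graphs)
        assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / total)

    def test_empty_split_rejected(self, tiny_local_result):
        w = f.WeightConfiguration.default(len(tiny_local_result.ensemble))
        with pytest.raises(f.ParameterError):
            f.evaluate(tiny_local_result.ensemble, w, [], "test")

    def test_zeroing_wrong_members_never_hurts(self, tiny_local_result):
        """Brute-force check on one fixture graph: silencing every member
        that votes wrongly makes the ensemble at least as accurate."""
        res = tiny_local_result
        graph = res.validation_graphs[0]
        votes = _member_votes(res.ensemble, [graph])[:, 0]
        uniform = f.WeightConfiguration.default(len(res.ensemble))
        silenced = f.WeightConfiguration(
            np.where(votes == graph.label, 1.0, 0.0)
        )
        plain_correct = f.weighted_vote(res.ensemble, uniform, graph) == graph.label
        tuned_correct = f.weighted_vote(res.ensemble, silenced, graph) == graph.label
        assert tuned_correct >= plain_correct
        assert tuned_correct  # some member is right on a fit fixture


class TestDetachment:
    def test_round_trip_predictions(self, tiny_local_result, tiny_dataset):
        res = tiny_local_result
        payload = f.detach_data(res.ensemble)
        back = f.ensemble_from_payload(payload)
        w = f.WeightConfiguration.default(len(res.ensemble))
        for g in tiny_dataset[3][:6]:
            assert f.weighted_vote(back, w, g) == f.weighted_vote(res.ensemble, w, g)

    def test_no_patient_data_in_payload(self, tiny_local_result, tiny_dataset):
        cohort = tiny_dataset[2]
        text = json.dumps(f.detach_data(tiny_local_result.ensemble))
        for sid in cohort.sample_ids:
            assert f'"{sid}"' not in text
        for key in ('"sample_id"', '"labels"', '"expression"'):
            assert key not in text

    def test_payload_size_independent_of_cohort_size(self):
        base = dict(n_genes=15, signal_size=3, effect_size=2.0, seed=5)
        sizes = []
        for n_per_class in (10, 100):
            spec = f.SyntheticSpec(n_patients_per_class=n_per_class, **base)
            ppi, signal, cohort = f.generate_dataset(spec)
            graphs = f.build_patient_graphs(cohort, ppi)
            split = f.split_dataset(
                len(graphs), seed=0, labels=[g.label for g in graphs]
            )
            train_g = [graphs[i] for i in split.train]
            val_g = [graphs[i] for i in split.validation]
            # identical subgraphs and config for both cohorts
            subs = [
                f.SubgraphSpec(genes=signal.genes, edges=signal.edges),
            ]
            ens = f.train_ensemble(train_g, subs, f.GNNConfig(epochs=5, seed=1), val_g)
            sizes.append(len(json.dumps(f.detach_data(ens))))
        assert sizes[0] == sizes[1]
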