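"""Structure sampling, initial weights, gradient epochs, replacement, train."""

import math

import numpy as np
import pytest

from hyperstage import (
    Hypergraph,
    LearningConfig,
    fit_hyperedge_stats,
    initial_weight,
    match_probability,
    parameter_update_epoch,
    replace_hyperedges,
    replacement_ratio,
    sample_hyperedge,
    stage_posterior,
    train,
)
from hyperstage.core_model import ParameterError
from hyperstage.learning import compute_mi_vectors, predict_dataset, selection_distribution

from conftest import make_dataset, make_edge


class TestReplacementRatio:
    def test_boundary_and_asymptote(self):
        assert replacement_ratio(0, 0.9, 0.5) == pytest.approx(0.9)
        assert replacement_ratio(1000, 0.9, 0.5) == pytest.approx(0.5)

    def test_direct_evaluation(self):
        assert replacement_ratio(1, 0.9, 0.5) == pytest.approx(0.4 / math.e + 0.5, abs=1e-12)
        assert replacement_ratio(1, 0.9, 0.5) == pytest.approx(0.6472, abs=1e-4)

    def test_strictly_decreasing_and_bounded(self):
        vals = [replacement_ratio(t, 0.9, 0.5) for t in range(30)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(0.5 <= v <= 0.9 for v in vals)

    def test_invalid_range_rejected(self):
        with pytest.raises(ParameterError):
            replacement_ratio(0, 0.4, 0.5)


class TestSampleHyperedge:
    ids = dict(mirna_ids=["m1", "m2", "m3"], mrna_ids=["g1", "g2", "g3", "g4"])

    def test_forced_full_pool(self):
        rng = np.random.default_rng(0)
        mirna, mrna = sample_hyperedge(
            np.ones(3), np.ones(4), 3, 4, rng, **self.ids
        )
        assert mirna == ("m1", "m2", "m3")
        assert mrna == ("g1", "g2", "g3", "g4")

    def test_seed_reproducibility(self):
        draws = [
            sample_hyperedge(
                np.array([3.0, 1.0, 1.0]), np.ones(4), 2, 2,
                np.random.default_rng(7), **self.ids
            )
            for _ in range(2)
        ]
        assert draws[0] == draws[1]

    def test_dominant_feature_always_selected(self):
        rng = np.random.default_rng(1)
        weights = np.array([1e9, 1.0, 1.0])
        hits = sum(
            "m1" in sample_hyperedge(weights, np.ones(4), 1, 1, rng, **self.ids)[0]
            for _ in range(1000)
        )
        assert hits == 1000

    def test_pool_overflow_rejected(self):
        with pytest.raises(ParameterError):
            sample_hyperedge(np.ones(3), np.ones(4), 4, 2, np.random.default_rng(0), **self.ids)

    def test_duplicate_sets_are_resampled(self):
        rng = np.random.default_rng(2)
        first = frozenset(("m1", "m2", "m3", "g1", "g2", "g3", "g4"))
        with pytest.raises(RuntimeError):
            # the full pool is the only possible draw; excluding it must fail
            sample_hyperedge(
                np.ones(3), np.ones(4), 3, 4, rng, existing=[first],
                max_tries=256, **self.ids
            )

    def test_pooled_mode_frees_the_split(self):
        rng = np.random.default_rng(3)
        sizes = {
            sum(len(b) for b in sample_hyperedge(
                np.ones(3), np.ones(4), 2, 2, rng, pooled=True, **self.ids
            ))
            for _ in range(50)
        }
        assert sizes == {4}  # total degree fixed ...
        splits = {
            len(sample_hyperedge(
                np.ones(3), np.ones(4), 2, 2, rng, pooled=True, **self.ids
            )[0])
            for _ in range(50)
        }
        assert len(splits) > 1  # ... but the block split floats


class TestInitialWeight:
    def test_direct_arithmetic(self):
        edge = make_edge(
            ["m1"], ["g1"], ["A"], {"A": [0, 0]}, {"A": [1.0, 1.0]}, {"A": 0.0}
        )
        assert initial_weight(edge, "A", kappa=1.0, mmi=0.2) == pytest.approx(2.2)

    def test_kappa_zero_isolates_variance_term(self):
        edge = make_edge(
            ["m1"], ["g1"], ["A"], {"A": [0, 0]}, {"A": [0.5, 2.0]}, {"A": 0.0}
        )
        assert initial_weight(edge, "A", kappa=0.0, mmi=9.9) == pytest.approx(4.0 + 0.25)

    def test_shrinking_variance_increases_weight(self):
        w = []
        for sd in (2.0, 1.0, 0.5):
            edge = make_edge(
                ["m1"], ["g1"], ["A"], {"A": [0, 0]}, {"A": [sd, 1.0]}, {"A": 0.0}
            )
            w.append(initial_weight(edge, "A", 1.0, 0.1))
        assert w[0] < w[1] < w[2]


class TestParameterUpdateEpoch:
    def build(self, gamma=1.0):
        """One 2-member edge; sample s0 matches stage A at probability 0.4,
        sample s1 is astronomically far (matching probability 0)."""
        a = math.log(2.5) * 2 / math.sqrt(2)  # offset giving P = 0.4
        ds = make_dataset(
            [[0.0, 3000.0]], [[0.0, 3000.0], [1.0, -1.0]], ["A", "B"]
        )
        edge = make_edge(
            ["mir1"], ["gene1"], ["A", "B"],
            {"A": [a, a], "B": [a, a]},
            {"A": [1.0, 1.0], "B": [1.0, 1.0]},
            {"A": 0.0, "B": 0.0},
        )
        model = Hypergraph(
            hyperedges=[edge], stages=["A", "B"], config=LearningConfig(gamma=gamma)
        )
        return ds, model

    def test_hand_computed_batch_delta(self):
        # all weights 0 => every posterior is exactly 0.5; s1 contributes 0;
        # stage A: delta = 0.5*0.5*(1-0.5)*0.4 = 0.05
        ds, model = self.build()
        parameter_update_epoch(model, ds, gamma=1.0)
        edge = model.hyperedges[0]
        assert edge.weights["A"] == pytest.approx(0.05, abs=1e-12)
        # stage B: wrong label for s0 => 0.5*0.5*(0-0.5)*0.4 = -0.05
        assert edge.weights["B"] == pytest.approx(-0.05, abs=1e-12)

    def test_gamma_zero_freezes_weights(self):
        ds, model = self.build()
        parameter_update_epoch(model, ds, gamma=0.0)
        assert model.hyperedges[0].weights == {"A": 0.0, "B": 0.0}

    def test_saturated_posterior_contributes_nothing(self):
        ds, model = self.build()
        # enormous weight saturates the sigmoid: expit(+-large) is exactly 0/1
        model.hyperedges[0].weights = {"A": 1e6, "B": -1e6}
        parameter_update_epoch(model, ds, gamma=1.0)
        assert model.hyperedges[0].weights["A"] == 1e6
        assert model.hyperedges[0].weights["B"] == -1e6

    def test_correct_well_matched_sample_pushes_weight_up(self):
        ds, model = self.build()
        parameter_update_epoch(model, ds, gamma=1.0)
        assert model.hyperedges[0].weights["A"] > 0

    def test_matches_scalar_composition_oracle(self, toy_dataset):
        """Vectorized batch update equals the update assembled sample by
        sample from the scalar matching/posterior primitives."""
        cfg = LearningConfig(l=1, m=2, n_hyperedges=3, structure_epochs=0, seed=3)
        model, _ = train(toy_dataset, cfg)
        expected = {
            i: dict(e.weights) for i, e in enumerate(model.hyperedges)
        }
        for i, e in enumerate(model.hyperedges):
            for y in model.stages:
                acc = 0.0
                for s in range(toy_dataset.n_samples):
                    prof = toy_dataset.profile(s)
                    p_y = stage_posterior(prof, model, y)
                    delta = 1.0 if toy_dataset.labels.iloc[s] == y else 0.0
                    match = match_probability(prof, e, y, model.beta).probability
                    acc += p_y * (1 - p_y) * (delta - p_y) * match
                expected[i][y] += 0.7 * acc
        parameter_update_epoch(model, toy_dataset, gamma=0.7)
        for i, e in enumerate(model.hyperedges):
            for y in model.stages:
                assert e.weights[y] == pytest.approx(expected[i][y], rel=1e-9)


class TestReplaceHyperedges:
    def setup_model(self, toy_dataset, weights):
        cfg = LearningConfig(l=1, m=2, n_hyperedges=len(weights), structure_epochs=0, seed=0)
        model, _ = train(toy_dataset, cfg)
        for e, w in zip(model.hyperedges, weights):
            e.weights = {y: float(w) for y in model.stages}
        mi_mirna, mi_mrna = compute_mi_vectors(toy_dataset, cfg)
        dists = (
            selection_distribution(mi_mirna, cfg.eta),
            selection_distribution(mi_mrna, cfg.eta),
        )
        return model, dists

    def test_ratio_zero_is_noop(self, toy_dataset):
        model, dists = self.setup_model(toy_dataset, [1, 2, 3, 4])
        before = [e.members for e in model.hyperedges]
        replace_hyperedges(model, 0.0, toy_dataset, *dists, np.random.default_rng(0))
        assert [e.members for e in model.hyperedges] == before

    def test_full_turnover_preserves_size(self, toy_dataset):
        model, dists = self.setup_model(toy_dataset, [1, 2, 3, 4])
        replace_hyperedges(model, 1.0, toy_dataset, *dists, np.random.default_rng(0))
        assert len(model) == 4

    def test_lowest_max_weight_edges_replaced(self, toy_dataset):
        model, dists = self.setup_model(toy_dataset, [1, 2, 3, 4])
        kept = {e.members for e in model.hyperedges[2:]}
        replace_hyperedges(model, 0.5, toy_dataset, *dists, np.random.default_rng(0))
        survivors = {e.members for e in model.hyperedges}
        assert kept <= survivors
        assert len(model) == 4

    def test_invalid_ratio_rejected(self, toy_dataset):
        model, dists = self.setup_model(toy_dataset, [1, 2])
        with pytest.raises(ParameterError):
            replace_hyperedges(model, 1.5, toy_dataset, *dists, np.random.default_rng(0))


class TestTrain:
    def test_zero_structure_epochs_returns_initial_population(self, toy_dataset):
        cfg = LearningConfig(l=1, m=2, n_hyperedges=4, structure_epochs=0, seed=5)
        model, trace = train(toy_dataset, cfg)
        assert len(model) == 4
        assert trace.mean_mmi == [] and trace.train_accuracy == []
        # weights are untouched initial weights
        for e in model.hyperedges:
            for y in model.stages:
                assert e.weights[y] == pytest.approx(
                    initial_weight(e, y, cfg.kappa, e.mmi)
                )

    def test_same_seed_reproduces_members_and_weights(self, toy_dataset, tiny_config):
        m1, t1 = train(toy_dataset, tiny_config)
        m2, t2 = train(toy_dataset, tiny_config)
        assert [e.members for e in m1.hyperedges] == [e.members for e in m2.hyperedges]
        assert [e.weights for e in m1.hyperedges] == [e.weights for e in m2.hyperedges]
        assert t1.mean_mmi == t2.mean_mmi

    def test_population_size_invariant(self, toy_dataset, tiny_config):
        model, trace = train(toy_dataset, tiny_config)
        assert len(model) == tiny_config.n_hyperedges
        assert (
            len(trace.mean_mmi)
            == len(trace.train_accuracy)
            == len(trace.replacement_ratio)
            == tiny_config.structure_epochs
        )

    def test_gamma_zero_keeps_initial_weights(self, toy_dataset):
        cfg = LearningConfig(
            l=1, m=2, n_hyperedges=4, structure_epochs=2, parameter_epochs=3,
            gamma=0.0, seed=1,
        )
        model, _ = train(toy_dataset, cfg)
        for e in model.hyperedges:
            for y in model.stages:
                assert e.weights[y] == pytest.approx(
                    initial_weight(e, y, cfg.kappa, e.mmi)
                )

    def test_predict_dataset_agrees_with_scalar_path(self, toy_dataset, tiny_config):
        from hyperstage import predict_stage

        model, _ = train(toy_dataset, tiny_config)
        vec = predict_dataset(model, toy_dataset)
        scalar = [
            predict_stage(toy_dataset.profile(i), model)
            for i in range(toy_dataset.n_samples)
        ]
        assert list(vec) == scalar
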