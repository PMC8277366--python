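import numpy as np
import pytest

from richddi import (AutoencoderParameters, BasicTriple, Hyperparameters,
                     conditional_probability, decode_labels,
                     encode_labels, joint_objective,
                     negative_sampling_objective, reconstruction_score,
                     reconstruction_weights, regularizer, sample_negatives,
                     score_basic, score_ddi, train)
from richddi.model import (SamplingError, TrainContext, build_parameters,
                           init_params, load_model, make_batch,
                           objective_and_grad, save_model)


def hp2(**kw):
    kw.setdefault("k", 2)
    kw.setdefault("d", 2)
    kw.setdefault("dropout", 0.0)
    return Hyperparameters(**kw)


class TestHyperparameters:
    @pytest.mark.parametrize("bad", [
        {"beta": 1.0}, {"beta": 0.5}, {"norm": "L3"}, {"k": 0},
        {"dropout": 1.0}, {"c": -1},
    ])
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ValueError):
            Hyperparameters(**bad)

    def test_relation_dim_defaults_to_entity_dim(self):
        assert Hyperparameters(k=7).d == 7


class TestScores:
    def test_exact_translation_attains_bias(self):
        params = build_parameters({"h": np.array([0.3, 0.4]),
                                   "t": np.array([0.4, 0.6])},
                                  {"r": np.array([0.1, 0.2])})
        z = score_basic(params, BasicTriple("h", "r", "t"), hp2(b1=5))
        assert z == pytest.approx(5.0)

    def test_l1_residual_subtracts_from_bias(self):
        params = build_parameters({"h": np.array([0.3, 0.4]),
                                   "t": np.array([0.4, 0.7])},
                                  {"r": np.array([0.1, 0.2])})
        z = score_basic(params, BasicTriple("h", "r", "t"), hp2(b1=5))
        assert z == pytest.approx(4.9)

    def test_score_bounded_by_bias(self):
        rng = np.random.default_rng(0)
        ents = {f"e{i}": rng.standard_normal(4) for i in range(6)}
        rels = {f"r{i}": rng.standard_normal(4) for i in range(2)}
        params = build_parameters(ents, rels)
        hp = hp2(k=4, d=4, b1=5)
        for norm in ("L1", "L2"):
            hp.norm = norm
            for i in range(5):
                z = score_basic(params, BasicTriple(f"e{i}", "r0", f"e{i+1}"), hp)
                assert z <= 5.0

    def test_ddi_score_with_identity_projection(self):
        params = build_parameters({"u": np.array([0.0, 0.0]),
                                   "v": np.array([1.0, 0.0])})
        z = score_ddi(params, "u", np.array([1.0, 0.0]), "v", hp2(b2=5))
        assert z == pytest.approx(5.0)

    def test_unknown_entity_raises_lookup_error(self):
        params = build_parameters({"u": np.zeros(2)})
        with pytest.raises(KeyError):
            score_ddi(params, "u", np.zeros(2), "nope", hp2())


class TestConditionalProbability:
    def test_equal_scores_give_uniform(self):
        params = build_parameters({"a": np.zeros(2), "b": np.zeros(2),
                                   "t": np.zeros(2)}, {"r": np.zeros(2)})
        p = conditional_probability(params, BasicTriple("a", "r", "t"),
                                    "head", ["a", "b"], hp2())
        assert p == pytest.approx([0.5, 0.5])

    def test_log_scores_give_proportional_probabilities(self):
        # z(h_i) = b1 - |h_i| = ln(i) for candidates i = 1, 2, 3
        b1 = 2.0
        ents = {f"h{i}": np.array([b1 - np.log(i)]) for i in (1, 2, 3)}
        ents["t"] = np.array([0.0])
        params = build_parameters(ents, {"r": np.array([0.0])})
        p = conditional_probability(params, BasicTriple("h1", "r", "t"),
                                    "head", ["h1", "h2", "h3"],
                                    hp2(k=1, d=1, b1=b1))
        assert p == pytest.approx([1 / 6, 2 / 6, 3 / 6])

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        ents = {f"e{i}": rng.standard_normal(3) for i in range(8)}
        params = build_parameters(ents, {"r": rng.standard_normal(3)})
        p = conditional_probability(params, BasicTriple("e0", "r", "e1"),
                                    "tail", [f"e{i}" for i in range(8)],
                                    hp2(k=3, d=3))
        assert p.sum() == pytest.approx(1.0, abs=1e-10)
        assert (p >= 0).all()

    def test_empty_candidates_rejected(self):
        params = build_parameters({"a": np.zeros(2)}, {"r": np.zeros(2)})
        with pytest.raises(ValueError):
            conditional_probability(params, BasicTriple("a", "r", "a"),
                                    "head", [], hp2())


def _ae(weights, biases, code):
    return AutoencoderParameters(weights=[np.asarray(w, float) for w in weights],
                                 biases=[np.asarray(b, float) for b in biases],
                                 code_layer_index=code)


class TestAutoencoder:
    def test_zero_weights_encode_to_zero_code(self):
        ae = _ae([np.zeros((3, 4)), np.zeros((2, 3))], [np.zeros(3), np.zeros(2)], 2)
        assert encode_labels(ae, np.ones(4)).tolist() == [0.0, 0.0]

    def test_identity_single_layer_applies_tanh(self):
        ae = _ae([np.eye(2)], [np.zeros(2)], 1)
        out = encode_labels(ae, np.array([1.0, 0.0]))
        assert out == pytest.approx([np.tanh(1.0), 0.0])

    def test_code_components_inside_tanh_range(self):
        rng = np.random.default_rng(3)
        ae = _ae([rng.standard_normal((5, 8)), rng.standard_normal((3, 5))],
                 [rng.standard_normal(5), rng.standard_normal(3)], 2)
        out = encode_labels(ae, rng.random(8))
        assert (np.abs(out) < 1.0).all()

    def test_zero_weight_decoder_outputs_half(self):
        ae = _ae([np.zeros((2, 4)), np.zeros((4, 2))], [np.zeros(2), np.zeros(4)], 1)
        assert decode_labels(ae, np.zeros(2)).tolist() == [0.5] * 4

    def test_decoder_output_length_is_vocabulary_size(self):
        rng = np.random.default_rng(4)
        ae = _ae([rng.standard_normal((3, 9)), rng.standard_normal((9, 3))],
                 [np.zeros(3), np.zeros(9)], 1)
        assert decode_labels(ae, rng.standard_normal(3)).shape == (9,)

    def test_shape_mismatch_rejected(self):
        ae = _ae([np.zeros((2, 4)), np.zeros((4, 2))], [np.zeros(2), np.zeros(4)], 1)
        with pytest.raises(ValueError):
            encode_labels(ae, np.zeros(5))
        with pytest.raises(ValueError):
            decode_labels(ae, np.zeros(3))


class TestReconstruction:
    def test_weights_all_ones_for_zero_vector(self):
        assert reconstruction_weights(np.zeros(3), 3.0).tolist() == [1.0] * 3

    def test_weights_beta_at_nonzero_components(self):
        x = reconstruction_weights(np.array([1.0, 0.0, 1.0]), 3.0)
        assert x.tolist() == [3.0, 1.0, 3.0]

    def test_beta_at_most_one_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_weights(np.zeros(2), 1.0)

    def test_perfect_reconstruction_scores_bias(self):
        s = np.array([1.0, 0.0])
        assert reconstruction_score(s, s, np.ones(2), b3=1.0) == pytest.approx(1.0)

    def test_weighted_l1_residual(self):
        z = reconstruction_score(np.array([1.0, 0.0]), np.array([0.5, 0.5]),
                                 np.array([2.0, 1.0]), b3=1.0, norm="L1")
        assert z == pytest.approx(-0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_score(np.zeros(2), np.zeros(3), np.zeros(2), 1.0)


class TestRegularizer:
    def test_inactive_hinge_gives_zero(self):
        params = build_parameters({"e": np.array([0.5, 0.5])})
        assert regularizer(params, 1.0) == 0.0

    def test_entity_above_unit_norm_contributes_hinge(self):
        params = build_parameters({"e": np.array([1.0, 1.0])})  # ||e||^2 = 2
        assert regularizer(params, 1.0) == pytest.approx(1.0)

    def test_gamma_zero_disables(self):
        params = build_parameters({"e": np.array([3.0, 3.0])})
        assert regularizer(params, 0.0) == 0.0


class TestNegativeSampling:
    def test_zero_count_gives_empty(self, tiny_kg):
        t = tiny_kg.basic[0]
        assert sample_negatives(t, "head", 0, tiny_kg,
                                np.random.default_rng(0)) == []

    def test_corruptions_avoid_training_triples(self, tiny_kg):
        existing = {(t.head, t.relation, t.tail) for t in tiny_kg.basic}
        rng = np.random.default_rng(1)
        for slot in ("head", "relation", "tail"):
            for neg in sample_negatives(tiny_kg.basic[0], slot, 10, tiny_kg, rng):
                assert (neg.head, neg.relation, neg.tail) not in existing

    def test_ddi_relation_corruption_uses_other_label_sets(self, tiny_kg):
        t = tiny_kg.ddi[0]
        rng = np.random.default_rng(2)
        negs = sample_negatives(t, "relation", 5, tiny_kg, rng)
        assert all(n.labels != t.labels for n in negs)

    def test_ddi_drug_corruption_avoids_known_pairs(self, tiny_kg):
        pairs = set(tiny_kg.undirected_pairs())
        rng = np.random.default_rng(3)
        for neg in sample_negatives(tiny_kg.ddi[0], "tail", 10, tiny_kg, rng):
            assert neg.pair not in pairs

    def test_exhausted_candidate_set_raises(self):
        from richddi import LabelVocabulary, build_kg
        kg = build_kg([BasicTriple("a", "hasTarget", "b")], [],
                      LabelVocabulary(["x"]))
        # the only relation in the KG reproduces the training triple
        with pytest.raises(SamplingError):
            sample_negatives(kg.basic[0], "relation", 3, kg,
                             np.random.default_rng(0))


class TestObjective:
    def test_log_half_at_zero_margin_without_negatives(self):
        # z = b1 - |h + r - t| = 1 - 1 = 0 -> ln(sigmoid(0)) = ln 0.5
        params = build_parameters({"h": np.array([1.0]), "t": np.array([0.0])},
                                  {"r": np.array([0.0])})
        val = negative_sampling_objective(params, BasicTriple("h", "r", "t"),
                                          [], hp2(k=1, d=1, b1=1.0))
        assert val == pytest.approx(np.log(0.5))

    def test_empty_batches_with_zero_gamma_give_zero(self, tiny_kg):
        hp = Hyperparameters(k=4, d=4, gamma=0.0, dropout=0.0, c=2, seed=0)
        params = init_params(tiny_kg, hp)
        val = joint_objective(params, [], [], hp, tiny_kg,
                              np.random.default_rng(0))
        assert val == 0.0

    def test_single_basic_triple_matches_slotwise_surrogate(self, tiny_kg):
        # with c=0 there are no negatives, so the joint objective is the
        # positive term once per slot
        hp = Hyperparameters(k=4, d=4, gamma=0.0, dropout=0.0, c=0, seed=0)
        params = init_params(tiny_kg, hp)
        t = tiny_kg.basic[0]
        joint = joint_objective(params, [t], [], hp, tiny_kg,
                                np.random.default_rng(0))
        single = negative_sampling_objective(params, t, [], hp)
        assert joint == pytest.approx(3.0 * single)

    def test_analytic_gradient_matches_finite_differences(self, tiny_kg):
        hp = Hyperparameters(k=4, d=3, c=3, gamma=0.01, dropout=0.0,
                             beta=3.0, seed=1)
        rng = np.random.default_rng(0)
        params = init_params(tiny_kg, hp, rng)
        ctx = TrainContext(tiny_kg, params)
        batch = make_batch(ctx, hp, rng)
        _, grads = objective_and_grad(params, batch, hp)
        h = 1e-6
        probe = np.random.default_rng(9)
        for name, arr in params.arrays.items():
            flat = arr.reshape(-1)
            for idx in probe.choice(flat.size, size=min(5, flat.size),
                                    replace=False):
                old = flat[idx]
                flat[idx] = old + h
                fp = objective_and_grad(params, batch, hp)[0]
                flat[idx] = old - h
                fm = objective_and_grad(params, batch, hp)[0]
                flat[idx] = old
                fd = (fp - fm) / (2 * h)
                ga = grads[name].reshape(-1)[idx]
                assert ga == pytest.approx(fd, rel=1e-5, abs=1e-7), name


class TestTraining:
    def test_identical_seeds_give_bitwise_identical_runs(self, small_kg):
        hp = Hyperparameters(k=8, c=4, iterations=40, batch_size=64, seed=12)
        p1, s1 = train(small_kg, hp)
        p2, s2 = train(small_kg, hp)
        assert s1.objective_trace == s2.objective_trace
        for name in p1.arrays:
            assert np.array_equal(p1.arrays[name], p2.arrays[name])

    def test_objective_improves_over_training(self, small_trained):
        _, state = small_trained
        tr = np.asarray(state.objective_trace)
        smooth = np.convolve(tr, np.ones(10) / 10, mode="valid")
        assert smooth[-1] > smooth[0]

    def test_trace_length_matches_iterations(self, small_trained, small_hp):
        _, state = small_trained
        assert len(state.objective_trace) == small_hp.iterations

    def test_true_triples_outscore_random_corruptions(self, small_trained,
                                                      small_split, small_hp):
        params, _ = small_trained
        kg = small_split.train_kg
        rng = np.random.default_rng(0)
        ents = params.entity_ids
        pos, neg = [], []
        for t in kg.basic[:80]:
            pos.append(score_basic(params, t, small_hp))
            corrupt = BasicTriple(ents[rng.integers(len(ents))], t.relation,
                                  t.tail)
            neg.append(score_basic(params, corrupt, small_hp))
        assert np.mean(pos) > np.mean(neg)

    def test_soft_constraints_shrink_embedding_norms(self, small_kg):
        frac = {}
        for gamma in (0.0, 0.1):
            hp = Hyperparameters(k=8, c=4, iterations=300, batch_size=64,
                                 gamma=gamma, dropout=0.0, seed=2)
            params, _ = train(small_kg, hp)
            sq = (params.E**2).sum(axis=1)
            frac[gamma] = (sq > 1.1).mean()
        assert frac[0.1] <= frac[0.0]

    def test_training_requires_both_triple_kinds(self, small_kg):
        import copy
        empty_ddi = copy.copy(small_kg)
        empty_ddi.ddi = []
        with pytest.raises(ValueError):
            train(empty_ddi, Hyperparameters(k=4))

    def test_checkpoint_roundtrip_is_bit_exact(self, small_trained, small_hp,
                                               small_kg, tmp_path):
        params, _ = small_trained
        path = str(tmp_path / "model.npz")
        save_model(path, params, small_hp, small_kg.vocabulary)
        loaded, hp, vocab = load_model(path)
        assert hp == small_hp
        assert vocab.labels == small_kg.vocabulary.labels
        assert loaded.entity_ids == params.entity_ids
        for name in params.arrays:
            assert np.array_equal(loaded.arrays[name], params.arrays[name])
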