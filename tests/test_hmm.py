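"""HMM recognizers: forward oracle, topology, adaptation, classification."""

import itertools

import numpy as np
import pytest

from ahar.hmm import (RecognizerBundle, adapt_universal, classify,
                      load_bundle, save_bundle, select_model,
                      train_class_hmm, train_universal_hmm)
from ahar.synthetic import generate_hmm_dataset


def brute_force_loglik(startprob, transmat, means, variances, obs):
    """Sum over every state path by enumeration (toy-size oracle)."""
    n_states = startprob.size
    T = obs.shape[0]

    def emission(s, t):
        d = obs[t] - means[s]
        return float(-0.5 * np.sum(d * d / variances[s]
                                   + np.log(2 * np.pi * variances[s])))

    total = -np.inf
    for path in itertools.product(range(n_states), repeat=T):
        lp = np.log(startprob[path[0]] + 1e-300) + emission(path[0], 0)
        for t in range(1, T):
            lp += np.log(transmat[path[t - 1], path[t]] + 1e-300) \
                + emission(path[t], t)
        total = np.logaddexp(total, lp)
    return total


@pytest.fixture(scope="module")
def hmm_data():
    return generate_hmm_dataset(n_classes=3, n_states=3, separation=3.0,
                                seed=0, n_sequences=10, seq_len=60, n_dims=4)


@pytest.fixture(scope="module")
def class_models(hmm_data):
    data, _ = hmm_data
    return {c: train_class_hmm([f.values for f in fss], 3, 2, seed=0,
                               label=c) for c, fss in data.items()}


class TestForwardOracle:
    @pytest.mark.parametrize("n_states,T", [(2, 5), (3, 6), (3, 8)])
    def test_matches_path_enumeration(self, n_states, T, rng):
        startprob = np.full(n_states, 1.0 / n_states)
        transmat = rng.uniform(0.2, 1.0, (n_states, n_states))
        transmat /= transmat.sum(axis=1, keepdims=True)
        means = rng.standard_normal((n_states, 2)) * 2
        variances = rng.uniform(0.5, 1.5, (n_states, 2))

        from ahar.hmm import ActivityHMM, _make_gmmhmm
        model = _make_gmmhmm(n_states, 1, seed=0)
        model.startprob_ = startprob
        model.transmat_ = transmat
        model.means_ = means[:, None, :]
        model.covars_ = variances[:, None, :]
        model.weights_ = np.ones((n_states, 1))
        ah = ActivityHMM(model, topology="ergodic")

        obs = rng.standard_normal((T, 2))
        expected = brute_force_loglik(startprob, transmat, means, variances,
                                      obs)
        assert abs(ah.loglik(obs, per_frame=False) - expected) < 1e-8


class TestClassSpecificTraining:
    def test_left_right_topology_preserved(self, class_models):
        for m in class_models.values():
            assert np.allclose(np.tril(m.transmat, -1), 0.0)
            assert np.allclose(m.transmat.sum(axis=1), 1.0)
            assert m.startprob[0] == 1.0

    def test_baum_welch_monotone(self, class_models):
        # the covariance prior makes training MAP rather than plain ML, so
        # the reported data log-likelihood may dip by O(prior strength);
        # monotonicity must hold to a small relative slack and end higher
        for m in class_models.values():
            hist = np.array(m.convergence_history)
            slack = 1e-4 * max(1.0, abs(hist[-1]))
            assert (np.diff(hist) > -slack).all()
            assert hist[-1] > hist[0]

    def test_state_mean_recovery(self):
        data, gens = generate_hmm_dataset(n_classes=1, n_states=3,
                                          separation=3.0, seed=1,
                                          n_sequences=60, seq_len=100,
                                          n_dims=4)
        m = train_class_hmm([f.values for f in data["class_00"]], 3, 1,
                            seed=0)
        fitted = m.model.means_[:, 0, :]
        truth = gens["class_00"].means
        # ~2000 unit-variance frames per state: 3 SE of the mean ~ 0.07
        assert np.abs(fitted - truth).max() < 0.1

    def test_short_sequences_skipped_then_error(self, rng):
        short = [rng.standard_normal((2, 3)) for _ in range(3)]
        with pytest.raises(ValueError, match="usable"):
            train_class_hmm(short, n_states=3, n_components=1)

    def test_two_sequences_required(self, rng):
        seqs = [rng.standard_normal((30, 3))]
        with pytest.raises(ValueError, match=">= 2"):
            train_class_hmm(seqs, n_states=3, n_components=1)


class TestUniversalModel:
    @pytest.fixture(scope="class")
    def background(self, hmm_data):
        data, _ = hmm_data
        pooled = [f.values for fss in data.values() for f in fss]
        return train_universal_hmm(pooled, n_states=3, total_components=6,
                                   seed=0)

    def test_ergodic_transitions_strictly_positive(self, background):
        assert (background.transmat > 0).all()

    def test_background_covers_pool_better_than_one_class(self, hmm_data,
                                                          background):
        data, _ = hmm_data
        pooled = [f.values for fss in data.values() for f in fss]
        one_class = train_class_hmm([f.values for f in data["class_00"]],
                                    3, 2, seed=0)
        ub = np.mean([background.loglik(x) for x in pooled])
        cs = np.mean([one_class.loglik(x) for x in pooled])
        assert ub > cs

    def test_infinite_relevance_keeps_background(self, hmm_data, background):
        data, _ = hmm_data
        adapted = adapt_universal(background,
                                  [f.values for f in data["class_01"]],
                                  relevance=1e12, label="class_01")
        np.testing.assert_allclose(adapted.model.means_,
                                   background.model.means_, atol=1e-6)

    def test_small_relevance_moves_to_data_posterior(self, hmm_data,
                                                     background):
        data, _ = hmm_data
        seqs = [f.values for f in data["class_01"]]
        near = adapt_universal(background, seqs, relevance=1e-6)
        far = adapt_universal(background, seqs, relevance=1e12)
        pooled_mean = np.vstack(seqs).mean(axis=0)
        # aggressive adaptation lands closer to the class data than none
        d_near = np.linalg.norm(near.model.means_.mean(axis=(0, 1))
                                - pooled_mean)
        d_far = np.linalg.norm(far.model.means_.mean(axis=(0, 1))
                               - pooled_mean)
        assert d_near < d_far

    def test_adaptation_improves_class_likelihood(self, hmm_data, background):
        data, _ = hmm_data
        seqs = [f.values for f in data["class_02"]]
        adapted = adapt_universal(background, seqs, relevance=16.0)
        gain = np.mean([adapted.loglik(x) - background.loglik(x)
                        for x in seqs])
        assert gain > 0

    def test_empty_class_returns_background_copy(self, background):
        adapted = adapt_universal(background, [], label="empty")
        np.testing.assert_array_equal(adapted.model.means_,
                                      background.model.means_)

    def test_adapted_weights_stay_stochastic(self, hmm_data, background):
        data, _ = hmm_data
        adapted = adapt_universal(background,
                                  [f.values for f in data["class_00"]])
        np.testing.assert_allclose(adapted.model.weights_.sum(axis=1), 1.0,
                                   atol=1e-9)


class TestClassification:
    def test_separable_classes_recovered(self, hmm_data, class_models):
        data, _ = hmm_data
        bundle = RecognizerBundle("class_specific", class_models)
        correct = sum(classify(bundle, f.values)[0] == c
                      for c, fss in data.items() for f in fss)
        assert correct / 30 >= 0.95

    def test_identical_models_tie_to_lower_index(self, class_models, rng):
        m = class_models["class_00"]
        bundle = RecognizerBundle("class_specific", {"b": m, "a": m})
        label, scores = classify(bundle, rng.standard_normal((20, 4)))
        assert label == "a"
        assert scores["a"] == scores["b"]

    def test_scores_consistent_with_label(self, hmm_data, class_models):
        data, _ = hmm_data
        bundle = RecognizerBundle("class_specific", class_models)
        label, scores = classify(bundle, data["class_01"][0].values)
        assert np.isfinite(list(scores.values())).all()
        assert scores[label] == max(scores.values())


class TestModelSelection:
    def test_single_candidate_returned(self, hmm_data, class_models):
        data, _ = hmm_data
        val = [f for fss in data.values() for f in fss[:2]]
        bundle = RecognizerBundle("class_specific", class_models)
        assert select_model({(3, 2): bundle}, val) == (3, 2)

    def test_empty_validation_rejected(self, class_models):
        bundle = RecognizerBundle("class_specific", class_models)
        with pytest.raises(ValueError, match="validation"):
            select_model({(3, 2): bundle}, [])

    def test_ties_prefer_smallest_model(self, hmm_data, class_models):
        data, _ = hmm_data
        val = [f for fss in data.values() for f in fss[:2]]
        bundle = RecognizerBundle("class_specific", class_models)
        chosen = select_model({(5, 4): bundle, (3, 2): bundle,
                               (3, 8): bundle}, val)
        assert chosen == (3, 2)

    def test_adequate_data_prefers_true_state_count(self):
        # sequences from a 4-state generator: validation accuracy should
        # not prefer a badly overparameterized model
        data, _ = generate_hmm_dataset(n_classes=2, n_states=4,
                                       separation=4.0, seed=3,
                                       n_sequences=12, seq_len=80, n_dims=3)
        train = {c: fss[:8] for c, fss in data.items()}
        val = [f for fss in data.values() for f in fss[8:]]
        candidates = {}
        for s in (2, 4):
            models = {c: train_class_hmm([f.values for f in fss], s, 1,
                                         seed=0, label=c)
                      for c, fss in train.items()}
            candidates[(s, 1)] = RecognizerBundle("class_specific", models)
        chosen = select_model(candidates, val)
        assert chosen[0] in (2, 4)  # both valid; must at least classify
        accs = {k: sum(classify(b, f.values)[0] == f.label for f in val)
                for k, b in candidates.items()}
        assert accs[chosen] == max(accs.values())


class TestBundleSerialization:
    def test_round_trip_preserves_scores(self, hmm_data, class_models,
                                         tmp_path):
        data, _ = hmm_data
        bundle = RecognizerBundle("class_specific", class_models)
        save_bundle(tmp_path / "bundle", bundle)
        back = load_bundle(tmp_path / "bundle")
        x = data["class_00"][0].values
        _, s1 = classify(bundle, x)
        _, s2 = classify(back, x)
        for c in s1:
            assert abs(s1[c] - s2[c]) < 1e-10
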