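"""Stager tests: smoothed-marginal exactness, KDE emissions, MLP contracts."""

import numpy as np
import pytest

import sleepuq as s
from oracles import brute_force_marginals
from sleepuq.features import DEFAULT_BAND_EDGES
from sleepuq.stages import Hypnogram


def _features(matrix: np.ndarray) -> s.SpectralFeatures:
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    edges = DEFAULT_BAND_EDGES[: matrix.shape[1]]
    centers = np.array([(lo + hi) / 2 for lo, hi in edges])
    return s.SpectralFeatures(matrix=matrix, freq_bins=centers, band_edges=edges)


class TestFitHmm:
    def test_constant_n2_bigram_counts_with_pseudocounts(self):
        labels = Hypnogram(np.full(100, 3))
        feats = _features(np.random.default_rng(0).normal(size=(100, 2)))
        model = s.fit_hmm(feats, labels)
        # 99 observed N2->N2 bigrams + 1 pseudocount over a row total of 99 + 5
        expected_row = np.array([1, 1, 1, 100, 1]) / 104
        assert np.allclose(model.transition[3], expected_row)
        assert model.transition[3, 3] == max(model.transition[3])
        # rows never observed are uniform from pseudocounts alone
        assert np.allclose(model.transition[0], 0.2)

    def test_disjoint_clusters_score_their_own_centroid_higher(self):
        rng = np.random.default_rng(1)
        cluster_w = rng.normal(0.0, 0.5, size=(40, 2))
        cluster_rem = rng.normal(10.0, 0.5, size=(40, 2))
        feats = _features(np.vstack([cluster_w, cluster_rem]))
        labels = Hypnogram(np.array([0] * 40 + [1] * 40))
        model = s.fit_hmm(feats, labels)
        centroid_w, centroid_rem = cluster_w.mean(axis=0), cluster_rem.mean(axis=0)
        assert model.emissions[0].score_samples([centroid_w])[0] > \
            model.emissions[1].score_samples([centroid_w])[0]
        assert model.emissions[1].score_samples([centroid_rem])[0] > \
            model.emissions[0].score_samples([centroid_rem])[0]

    def test_single_epoch_training_gives_pseudocount_uniform_transitions(self):
        with pytest.warns(UserWarning, match="absent"):
            model = s.fit_hmm(_features([[1.0, 2.0]]), Hypnogram([2]))
        assert np.allclose(model.transition, 0.2)

    def test_length_mismatch_is_rejected(self):
        with pytest.raises(s.ValidationError, match="equal lengths"):
            s.fit_hmm(_features(np.zeros((3, 2))), Hypnogram([0, 1]))

    def test_absent_stage_gets_flat_fallback_with_warning(self):
        feats = _features(np.random.default_rng(2).normal(size=(50, 2)))
        labels = Hypnogram(np.array([0, 3] * 25))
        with pytest.warns(UserWarning, match="N3"):
            model = s.fit_hmm(feats, labels)
        assert model.emissions[4] is None
        # flat fallback still yields a valid posterior
        post = model.predict_posteriors(feats)
        assert np.allclose(post.probs.sum(axis=1), 1.0)


class TestForwardBackward:
    def test_single_epoch_posterior_is_scaled_prior_times_likelihood(self):
        initial = np.array([0.5, 0.2, 0.1, 0.1, 0.1])
        log_lik = np.log(np.array([[0.1, 0.4, 0.2, 0.2, 0.1]]))
        post = s.forward_backward(log_lik, np.full((5, 5), 0.2), initial)
        expected = initial * np.exp(log_lik[0])
        expected /= expected.sum()
        assert np.allclose(post.probs[0], expected)

    def test_fully_uniform_model_gives_uniform_posteriors(self):
        post = s.forward_backward(np.zeros((6, 5)), np.full((5, 5), 0.2), np.full(5, 0.2))
        assert np.allclose(post.probs, 0.2)

    def test_matches_exhaustive_path_enumeration(self, rng):
        """Smoothed marginals equal the brute-force oracle on 100 random models."""
        worst = 0.0
        for _ in range(100):
            T = int(rng.integers(1, 6))
            transition = rng.dirichlet(np.ones(5), size=5)
            initial = rng.dirichlet(np.ones(5))
            log_lik = np.log(rng.uniform(0.05, 1.0, size=(T, 5)))
            ours = s.forward_backward(log_lik, transition, initial).probs
            oracle = brute_force_marginals(log_lik, transition, initial)
            worst = max(worst, np.abs(ours - oracle).max())
        assert worst < 1e-10

    def test_zero_transition_row_is_rejected(self):
        transition = np.full((5, 5), 0.2)
        transition[1] = 0.0
        with pytest.raises(s.ValidationError, match="row 1"):
            s.forward_backward(np.zeros((3, 5)), transition, np.full(5, 0.2))


class TestEstimateHypnogram:
    def test_unique_maximum(self):
        post = s.PosteriorMatrix(np.array([[0.1, 0.6, 0.1, 0.1, 0.1]]))
        assert s.estimate_hypnogram(post).stages[0] == 1  # REM

    def test_tie_breaks_toward_lowest_code(self):
        post = s.PosteriorMatrix(np.array([[0.5, 0.5, 0.0, 0.0, 0.0]]))
        assert s.estimate_hypnogram(post).stages[0] == 0  # W

    def test_one_hot_posteriors_reproduce_the_hypnogram(self):
        stages = np.array([0, 2, 4, 1, 3, 3])
        probs = np.eye(5)[stages]
        est = s.estimate_hypnogram(s.PosteriorMatrix(probs))
        assert np.array_equal(est.stages, stages)


class TestMlp:
    def test_posterior_rows_sum_to_one(self, small_night):
        _, hyp, feats = small_night
        model = s.fit_mlp(feats, hyp, seed=0)
        post = model.predict_posteriors(feats)
        assert np.abs(post.probs.sum(axis=1) - 1.0).max() < 1e-6

    def test_separable_clusters_reach_training_accuracy(self):
        rng = np.random.default_rng(3)
        matrix = np.vstack([rng.normal(0, 1, (100, 2)), rng.normal(8, 1, (100, 2))])
        labels = Hypnogram(np.array([0] * 100 + [3] * 100))
        model = s.fit_mlp(_features(matrix), labels, seed=1)
        est = s.estimate_hypnogram(model.predict_posteriors(_features(matrix)))
        assert (est.stages == labels.stages).mean() >= 0.95

    def test_same_seed_is_bitwise_reproducible(self, small_night):
        _, hyp, feats = small_night
        a = s.fit_mlp(feats, hyp, seed=5).predict_posteriors(feats)
        b = s.fit_mlp(feats, hyp, seed=5).predict_posteriors(feats)
        assert np.array_equal(a.probs, b.probs)

    def test_single_class_training_is_rejected(self):
        with pytest.raises(s.ValidationError, match="at least two stages"):
            s.fit_mlp(_features(np.zeros((10, 2))), Hypnogram(np.full(10, 2)), seed=0)


def test_model_archive_round_trip(tmp_path, small_night):
    _, hyp, feats = small_night
    model = s.fit_hmm(feats, hyp)
    path = tmp_path / "model.bin"
    s.save_model(model, path)
    loaded = s.load_model(path)
    original = model.predict_posteriors(feats).probs
    assert np.allclose(loaded.predict_posteriors(feats).probs, original)
    with pytest.raises(s.FormatError):
        s.load_model(__file__)


def test_hmm_smoothing_beats_transition_free_decoding():
    """With a strongly diagonal chain, forward-backward smoothing outperforms
    per-epoch (naive Bayes) decoding on a held-out night."""
    train_cfg = s.SyntheticStudyConfig(n_epochs=500, seed=21)
    test_cfg = s.SyntheticStudyConfig(n_epochs=500, seed=22)
    train_hyp, train_feats = s.simulate_and_featurize(train_cfg)
    test_hyp, test_feats = s.simulate_and_featurize(test_cfg)
    model = s.fit_hmm(train_feats, train_hyp)
    hmm_est = s.estimate_hypnogram(model.predict_posteriors(test_feats))
    log_lik = model.log_likelihoods(test_feats)
    naive = np.argmax(log_lik + np.log(model.initial), axis=1)
    hmm_acc = (hmm_est.stages == test_hyp.stages).mean()
    naive_acc = (naive == test_hyp.stages).mean()
    assert hmm_acc > naive_acc


def test_end_to_end_staging_recovers_held_out_stages_above_chance(study):
    """Whole-pipeline accuracy far exceeds the 0.2 five-class chance level."""
    for night in study.nights:
        accuracy = (night.automated.stages == night.truth.stages).mean()
        assert accuracy > 0.6
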