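"""Time-delay embedding, PCA, HMM inference, and state metrics.

The forward-backward / Viterbi recursions are checked against an
exhaustive enumeration over all possible state paths on small instances,
and against hmmlearn as an independent implementation on a larger one.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

from brainstates import synth
from brainstates.containers import TrialSet
from brainstates.hmm import (StatePosterior, _gaussian_loglik, decode, fit_hmm,
                             forward_backward, state_metrics, viterbi_path,
                             save_model, load_model)
from brainstates.tde import embed, fit_pca


def _trialset(data, fs=250.0):
    n, _, c = data.shape
    return TrialSet(data, fs, tuple(f"ch{i}" for i in range(c)),
                    np.full(n, "BR_dom"), np.full(n, "S01"), np.full(n, 250))


class TestEmbed:
    def test_frame_count_default_window(self, rng):
        t = _trialset(rng.standard_normal((3, 275, 8)))
        e = embed(t, 60.0)
        assert e.n_lags == 15
        assert e.frames.shape == (3 * 261, 120)
        assert (e.trial_lengths == 261).all()

    def test_constant_input_gives_identical_rows(self):
        t = _trialset(np.full((1, 30, 2), 3.0))
        e = embed(t, 60.0)
        assert np.allclose(e.frames, e.frames[0])

    def test_channel_major_lag_order(self, rng):
        t = _trialset(rng.standard_normal((1, 40, 2)))
        e = embed(t, 60.0)
        w = e.half_window
        s = 20
        row = e.frames[s - w]
        np.testing.assert_array_equal(row[:15], t.data[0, s - w:s + w + 1, 0])
        np.testing.assert_array_equal(row[15:], t.data[0, s - w:s + w + 1, 1])

    def test_white_noise_embedding_nearly_uncorrelated(self, rng):
        t = _trialset(rng.standard_normal((400, 264, 1)))
        e = embed(t, 60.0)  # 100k frames, 15 dims
        corr = np.corrcoef(e.frames, rowvar=False)
        off = corr[~np.eye(15, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_window_longer_than_trial_rejected(self, rng):
        t = _trialset(rng.standard_normal((1, 10, 1)))
        with pytest.raises(ValueError, match="shorter"):
            embed(t, 60.0)


class TestPCA:
    def test_full_rank_explains_everything(self, rng):
        t = _trialset(rng.standard_normal((2, 100, 2)))
        e = embed(t, 60.0)
        pca = fit_pca(e, 30)
        assert pca.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-8)

    def test_exact_subspace_recovered(self, rng):
        from brainstates.tde import EmbeddedData
        basis = rng.standard_normal((3, 30))
        coords = rng.standard_normal((500, 3))
        frames = coords @ basis
        e = EmbeddedData(frames=frames, index=np.zeros((500, 2), dtype=int),
                         half_window=7, n_channels=2,
                         trial_lengths=np.array([500]))
        pca = fit_pca(e, 3)
        recon = pca.transform(frames) @ pca.loadings.T + pca.mean
        assert np.abs(recon - frames).max() < 1e-8

    def test_matches_independent_eigendecomposition(self, rng):
        t = _trialset(rng.standard_normal((5, 150, 4)))
        e = embed(t, 60.0)
        pca = fit_pca(e, 16)
        centred = e.frames - e.frames.mean(axis=0)
        cov = centred.T @ centred / (len(centred) - 1)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected_ratio = evals[:16] / evals.sum()
        np.testing.assert_allclose(pca.explained_variance_ratio, expected_ratio,
                                   atol=1e-8)

    def test_rank_deficient_request_rejected(self):
        from brainstates.tde import EmbeddedData
        frames = np.zeros((100, 10))
        frames[:, 0] = np.random.default_rng(0).standard_normal(100)
        e = EmbeddedData(frames=frames, index=np.zeros((100, 2), dtype=int),
                         half_window=1, n_channels=1,
                         trial_lengths=np.array([100]))
        with pytest.raises(ValueError, match="rank"):
            fit_pca(e, 5)


def brute_force_posterior(loglik, transition, initial):
    """Exhaustive enumeration over all K^T paths: gamma, best path, log Z."""
    T, K = loglik.shape
    log_probs = {}
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(initial[path[0]]) + loglik[0, path[0]]
        for t in range(1, T):
            lp += np.log(transition[path[t - 1], path[t]]) + loglik[t, path[t]]
        log_probs[path] = lp
    total = np.logaddexp.reduce(list(log_probs.values()))
    best_path = max(log_probs, key=log_probs.get)
    gamma = np.zeros((T, K))
    for path, lp in log_probs.items():
        w = np.exp(lp - total)
        for t in range(T):
            gamma[t, path[t]] += w
    return gamma, np.array(best_path), total


def _random_instance(rng, T, K):
    loglik = rng.normal(0, 2, size=(T, K))
    transition = rng.dirichlet(np.ones(K), size=K)
    initial = rng.dirichlet(np.ones(K))
    return loglik, transition, initial


class TestExactInference:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(2, 6), st.integers(2, 3), st.integers(0, 10_000))
    def test_forward_backward_and_viterbi_match_enumeration(self, T, K, seed):
        rng = np.random.default_rng(seed)
        loglik, transition, initial = _random_instance(rng, T, K)
        lengths = np.array([T])
        gamma, _, ll, _ = forward_backward(loglik, transition, initial, lengths)
        path = viterbi_path(loglik, transition, initial, lengths)
        bf_gamma, bf_path, bf_ll = brute_force_posterior(loglik, transition, initial)
        np.testing.assert_allclose(gamma, bf_gamma, atol=1e-10)
        assert ll == pytest.approx(bf_ll, abs=1e-10)
        np.testing.assert_array_equal(path, bf_path)

    def test_multi_trial_inference_equals_per_trial(self, rng):
        K = 3
        loglik = rng.normal(0, 1, size=(12, K))
        trans = rng.dirichlet(np.ones(K), size=K)
        init = rng.dirichlet(np.ones(K))
        joint_gamma, _, joint_ll, _ = forward_backward(
            loglik, trans, init, np.array([5, 7]))
        g1, _, ll1, _ = forward_backward(loglik[:5], trans, init, np.array([5]))
        g2, _, ll2, _ = forward_backward(loglik[5:], trans, init, np.array([7]))
        np.testing.assert_allclose(joint_gamma, np.vstack([g1, g2]), atol=1e-12)
        assert joint_ll == pytest.approx(ll1 + ll2, abs=1e-9)

    def test_agrees_with_hmmlearn(self, rng):
        from hmmlearn.hmm import GaussianHMM
        K, D, T = 3, 2, 400
        covs = np.stack([np.eye(D) * s for s in (0.5, 2.0, 8.0)])
        trans = rng.dirichlet(np.ones(K) * 5, size=K)
        init = rng.dirichlet(np.ones(K))
        X = rng.standard_normal((T, D)) * 1.5
        ref = GaussianHMM(n_components=K, covariance_type="full", init_params="")
        ref.startprob_ = init
        ref.transmat_ = trans
        ref.means_ = np.zeros((K, D))
        ref.covars_ = covs
        ref_gamma = ref.predict_proba(X)
        _, ref_path = ref.decode(X)
        loglik = _gaussian_loglik(X, covs)
        gamma, _, _, _ = forward_backward(loglik, trans, init, np.array([T]))
        path = viterbi_path(loglik, trans, init, np.array([T]))
        np.testing.assert_allclose(gamma, ref_gamma, atol=1e-8)
        np.testing.assert_array_equal(path, ref_path)

    def test_dead_state_gets_zero_posterior(self, rng):
        loglik = rng.normal(0, 1, size=(10, 2))
        loglik[:, 1] = -1e8
        trans = np.array([[0.5, 0.5], [0.5, 0.5]])
        init = np.array([0.5, 0.5])
        gamma, _, _, _ = forward_backward(loglik, trans, init, np.array([10]))
        assert gamma[:, 1].max() < 1e-6
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-10)


class TestFitHMM:
    def test_transition_recovery_two_states(self, rng):
        K, D = 2, 2
        true_trans = np.array([[0.9, 0.1], [0.2, 0.8]])
        covs = np.stack([np.eye(D) * 0.25, np.eye(D) * 9.0])
        chols = np.linalg.cholesky(covs)
        n_trials, T = 100, 500
        paths = synth.sample_state_paths(true_trans, [0.5, 0.5], n_trials, T,
                                         seed=1).paths
        X = np.einsum("ntij,ntj->nti", chols[paths],
                      rng.standard_normal((n_trials, T, D)))
        frames = X.reshape(-1, D)
        model = fit_hmm(frames, np.full(n_trials, T), 2, n_restarts=3, seed=0)
        # label matching by covariance scale
        order = np.argsort([np.trace(c) for c in model.covariances])
        est = model.transition[np.ix_(order, order)]
        assert np.abs(est - true_trans).max() < 0.05

    def test_single_state_model(self, rng):
        frames = rng.standard_normal((500, 3))
        model = fit_hmm(frames, np.array([500]), 1, n_restarts=1, seed=0)
        post = decode(model, frames, np.array([500]))
        np.testing.assert_allclose(post.gamma, 1.0)
        expected_ll = _gaussian_loglik(frames, model.covariances)[:, 0].sum()
        assert model.objective_trace[-1] == pytest.approx(expected_ll, rel=1e-8)

    def test_objective_monotone_nondecreasing(self, rng):
        frames = rng.standard_normal((2000, 3)) * np.array([1.0, 2.0, 0.5])
        model = fit_hmm(frames, np.full(4, 500), 2, n_restarts=2, seed=3)
        trace = model.objective_trace
        assert np.all(np.diff(trace) >= -1e-8 * np.abs(trace[:-1]))

    def test_dimension_mismatch_rejected(self, rng):
        frames = rng.standard_normal((200, 3))
        model = fit_hmm(frames, np.array([200]), 2, n_restarts=1, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            decode(model, rng.standard_normal((50, 4)), np.array([50]))

    def test_model_round_trip(self, rng, tmp_path):
        frames = rng.standard_normal((300, 2))
        model = fit_hmm(frames, np.array([300]), 2, n_restarts=1, seed=0)
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        np.testing.assert_array_equal(back.covariances, model.covariances)
        np.testing.assert_array_equal(back.transition, model.transition)


class TestStateMetrics:
    def test_hand_computed_example(self):
        post = StatePosterior(gamma=np.full((5, 2), 0.5),
                              viterbi=np.array([0, 0, 1, 1, 1]),
                              trial_lengths=np.array([5]))
        m = state_metrics(post, fs=250.0)
        np.testing.assert_allclose(m.fo[0], [0.4, 0.6])
        assert m.switching_rate[0] == pytest.approx(1 / (5 / 250.0))  # 50 Hz
        assert m.lifetimes[0][0] == [pytest.approx(2 / 250.0)]  # 8 ms

    def test_constant_path(self):
        post = StatePosterior(gamma=np.full((10, 3), 1 / 3),
                              viterbi=np.zeros(10, dtype=int),
                              trial_lengths=np.array([10]))
        m = state_metrics(post, fs=100.0, n_states=3)
        assert m.switching_rate[0] == 0.0
        np.testing.assert_allclose(m.fo[0], [1.0, 0.0, 0.0])
        assert m.lifetimes[0][0] == [pytest.approx(0.1)]

    def test_lifetimes_consistent_with_fo(self, rng):
        paths = rng.integers(0, 4, size=(20, 60))
        post = StatePosterior(gamma=np.full((20 * 60, 4), 0.25),
                              viterbi=paths.ravel(),
                              trial_lengths=np.full(20, 60))
        m = state_metrics(post, fs=250.0)
        for i in range(20):
            for k in range(4):
                assert sum(m.lifetimes[i][k]) == pytest.approx(
                    m.fo[i, k] * 60 / 250.0, abs=1e-9)
        np.testing.assert_allclose(m.fo.sum(axis=1), 1.0, atol=1e-10)


class TestGeneratorConsistency:
    def test_state_relabelling_changes_only_labels(self):
        spec = synth.default_state_spec()
        perm = np.array([2, 0, 3, 1])
        trans, init = synth.default_condition_dynamics(4)["BR_dom"]
        sp = synth.sample_state_paths(trans, init, 10, 275, seed=4)
        t_orig = synth.synthesize_signals(sp, spec, 250.0, seed=5)
        spec_perm = synth.StateSpec(
            components=[spec.components[j] for j in np.argsort(perm)],
            noise_std=spec.noise_std, pink_std=spec.pink_std)
        sp_perm = synth.StatePathTruth(paths=perm[sp.paths],
                                       transition=trans, initial=init)
        t_perm = synth.synthesize_signals(sp_perm, spec_perm, 250.0, seed=5)
        np.testing.assert_allclose(t_orig.data, t_perm.data)

    def test_backprojected_covariance_matches_generator(self, tiny_dataset):
        trialset, paths, _ = tiny_dataset
        e = embed(trialset, 60.0)
        pca = fit_pca(e, 16)
        X = pca.transform(e.frames)
        model = fit_hmm(X, e.trial_lengths, 4, n_restarts=2, seed=0)
        post = decode(model, X, e.trial_lengths)
        w = e.half_window
        true = paths.paths[:, w:-w].ravel()
        conf = np.zeros((4, 4))
        for a in range(4):
            for b in range(4):
                conf[a, b] = np.sum((true == a) & (post.viterbi == b))
        row, col = linear_sum_assignment(-conf)
        match = dict(zip(col, row))  # fitted -> true
        centred = e.frames - e.frames.mean(axis=0)
        for fitted_k in range(4):
            true_k = match[fitted_k]
            emp = np.cov(centred[true == true_k], rowvar=False)
            fit_cov = pca.backproject_covariance(model.covariances[fitted_k])
            # compare on the PCA subspace where the model lives
            proj = pca.loadings.T @ emp @ pca.loadings
            proj_back = pca.loadings @ proj @ pca.loadings.T
            rel = np.linalg.norm(fit_cov - proj_back) / np.linalg.norm(proj_back)
            assert rel < 0.2
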