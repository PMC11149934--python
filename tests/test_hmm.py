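"""Time-delay embedding, Baum-Welch EM (vs exhaustive-enumeration oracle),
binarization, burst-state selection, spectra and burst amplitude."""

import itertools

import numpy as np
import pytest
from scipy import signal

from opmbeta import hmm as bh
from opmbeta.hmm import _forward_backward


class TestEmbedding:
    def test_zero_lags_identity(self, rng):
        x = rng.normal(size=500)
        emb = bh.tde_embed(x, 100.0, lags=0, target_fs=100.0)
        assert emb.X.shape == (500, 1)
        assert np.allclose(emb.X[:, 0], emb.series)

    def test_row_indexing_matches_direct_slicing(self, rng):
        x = rng.normal(size=300)
        emb = bh.tde_embed(x, 100.0, lags=7, target_fs=100.0)
        assert emb.X.shape == (300 - 14, 15)
        s = emb.series
        for t in (0, 5, 100, 285):
            assert np.allclose(emb.X[t], s[t : t + 15])

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            bh.tde_embed(np.ones(500), 100.0, lags=7, target_fs=100.0)

    def test_low_target_fs_rejected(self, rng):
        with pytest.raises(ValueError):
            bh.tde_embed(rng.normal(size=500), 300.0, target_fs=80.0)


def _enumeration_oracle(x, pi, A, sigmas):
    """Posteriors by summing over all K^T state paths (zero-mean 1-D
    Gaussian emissions)."""
    K, T = len(pi), len(x)
    like = np.array(
        [np.exp(-0.5 * (x / s) ** 2) / (np.sqrt(2 * np.pi) * s) for s in sigmas]
    )  # (K, T)
    gamma = np.zeros((T, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = pi[path[0]] * like[path[0], 0]
        for t in range(1, T):
            p *= A[path[t - 1], path[t]] * like[path[t], t]
        total += p
        for t in range(T):
            gamma[t, path[t]] += p
    return gamma / total, np.log(total)


class TestForwardBackward:
    def test_matches_exhaustive_enumeration(self, rng):
        x = rng.normal(size=6)
        pi = np.array([0.7, 0.3])
        A = np.array([[0.9, 0.1], [0.2, 0.8]])
        sigmas = np.array([1.0, 3.0])
        g_oracle, ll_oracle = _enumeration_oracle(x, pi, A, sigmas)
        like = np.stack(
            [np.exp(-0.5 * (x / s) ** 2) / (np.sqrt(2 * np.pi) * s) for s in sigmas],
            axis=1,
        )
        gamma, xi_sum, ll = _forward_backward(like, A, pi)
        assert np.allclose(gamma, g_oracle, atol=1e-10)
        assert ll == pytest.approx(ll_oracle, abs=1e-10)

    def test_row_scaling_invariance_of_posteriors(self, rng):
        x = rng.normal(size=6)
        pi = np.array([0.5, 0.5])
        A = np.array([[0.8, 0.2], [0.3, 0.7]])
        like = np.abs(rng.normal(size=(6, 2))) + 0.1
        g1, _, _ = _forward_backward(like.copy(), A, pi)
        g2, _, _ = _forward_backward(like * rng.uniform(0.5, 2.0, size=(6, 1)), A, pi)
        assert np.allclose(g1, g2, atol=1e-12)


class TestFitHMM:
    def _switching_series(self, seed, dwell=20, n=4000):
        rng = np.random.default_rng(seed)
        states = np.repeat(rng.integers(0, 2, size=n // dwell), dwell)
        sigma = np.where(states == 0, 1.0, 3.0)
        return rng.normal(size=states.size) * sigma, states

    @pytest.mark.parametrize("seed", range(5))
    def test_two_state_variance_switching_recovery(self, seed):
        x, states = self._switching_series(seed)
        model = bh.fit_hmm(x[:, None], K=2, n_restarts=3, seed=seed, max_iter=200)
        hard = model.gamma.argmax(axis=1)
        acc = max((hard == states).mean(), (hard == 1 - states).mean())
        assert acc >= 0.90

    def test_log_likelihood_monotone_and_normalisation(self):
        x, _ = self._switching_series(1)
        model = bh.fit_hmm(x[:, None], K=2, n_restarts=2, seed=0, max_iter=100)
        lls = model.log_likelihoods
        assert np.all(np.diff(lls) >= -1e-6 * np.abs(lls[:-1]))
        assert np.allclose(model.gamma.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(model.transmat.sum(axis=1), 1.0, atol=1e-10)

    def test_matches_hmmlearn_posteriors_for_fixed_model(self, rng):
        """Cross-check the scaled forward-backward against hmmlearn for a
        fixed (not fitted) zero-mean model."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        x = rng.normal(size=(300, 1)) * np.where(
            np.arange(300) % 40 < 20, 1.0, 3.0
        )[:, None]
        pi = np.array([0.5, 0.5])
        A = np.array([[0.95, 0.05], [0.1, 0.9]])
        covs = np.array([[[1.0]], [[9.0]]])
        m = hmmlearn.GaussianHMM(n_components=2, covariance_type="full", init_params="")
        m.startprob_, m.transmat_ = pi, A
        m.means_ = np.zeros((2, 1))
        m.covars_ = covs
        ref = m.predict_proba(x)
        from opmbeta.hmm import _log_gauss_zero_mean

        logB = _log_gauss_zero_mean(x, covs.copy())
        B = np.exp(logB - logB.max(axis=1, keepdims=True))
        gamma, _, _ = _forward_backward(B, A, pi)
        assert np.allclose(gamma, ref, atol=1e-8)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            bh.fit_hmm(rng.normal(size=(50, 2)), K=3)


class TestBinarize:
    def test_threshold_cases(self):
        g = np.array([
            [0.70, 0.20, 0.10],
            [1 / 3, 1 / 3, 1 / 3],
            [2 / 3, 1 / 6, 1 / 6],
        ])
        b = bh.binarize_states(g)
        assert b[0].tolist() == [1, 0, 0]
        assert b[1].tolist() == [0, 0, 0]
        assert b[2].tolist() == [0, 0, 0]  # exact threshold maps to off

    def test_at_most_one_state_on(self, rng):
        g = rng.dirichlet(np.ones(3), size=500)
        assert bh.binarize_states(g).sum(axis=1).max() <= 1


class TestBurstSelection:
    def _trials(self, K=3, n_trials=12, fs=100.0):
        S = int(3.5 * fs)
        return np.zeros((n_trials, S, K), dtype=np.int8), fs

    def test_single_modulated_state_selected(self):
        b, fs = self._trials()
        post = slice(int(1.5 * fs), int(2.0 * fs))   # 1.0-1.5 s at t0 = -0.5
        b[:, post, 2] = 1
        assert bh.select_burst_state(b, fs, -0.5) == 2

    def test_tie_breaks_to_lowest_index(self):
        b, fs = self._trials()
        post = slice(int(1.5 * fs), int(2.0 * fs))
        b[:, post, 1] = 1
        b2 = b.copy()
        b2[:, post, 0] = 1
        b2[:, post, 1] = 0
        both = b.copy()
        both[:, post, 0] = 1   # states 0 and 1 identically modulated
        assert bh.select_burst_state(both, fs, -0.5) == 0

    def test_requires_ten_trials(self):
        b, fs = self._trials(n_trials=5)
        with pytest.raises(ValueError):
            bh.select_burst_state(b, fs, -0.5)


class TestBurstProbability:
    def test_always_on(self):
        fs = 100.0
        b = np.ones((8, int(3.5 * fs)), dtype=np.int8)
        res = bh.burst_probability(b, fs, -0.5)
        assert np.all(res.p == 1.0)
        assert res.delta_p == 0.0

    def test_full_modulation(self):
        fs = 100.0
        b = np.zeros((8, int(3.5 * fs)), dtype=np.int8)
        b[:, int(1.5 * fs) : int(2.0 * fs)] = 1   # on throughout post window
        res = bh.burst_probability(b, fs, -0.5)
        assert res.delta_p == pytest.approx(1.0)


class TestStateSpectra:
    def test_tone_peak_in_assigned_state(self):
        fs = 100.0
        t = np.arange(int(fs * 60)) / fs
        x = np.sin(2 * np.pi * 20 * t)
        gamma = np.zeros((t.size, 3))
        gamma[:, 1] = 1.0
        freqs, psd = bh.state_spectra(x, gamma, fs)
        assert freqs[np.nanargmax(psd[1])] == pytest.approx(20.0, abs=0.5)
        assert np.all(np.isnan(psd[0]))  # unoccupied state flagged undefined

    def test_white_noise_equal_occupancy_equal_flat_spectra(self, rng):
        fs = 100.0
        x = rng.normal(size=int(fs * 400))
        gamma = np.zeros((x.size, 2))
        half = np.arange(x.size) % 200 < 100
        gamma[half, 0] = 1.0
        gamma[~half, 1] = 1.0
        freqs, psd = bh.state_spectra(x, gamma, fs)
        ratio = psd[0].mean() / psd[1].mean()
        assert ratio == pytest.approx(1.0, abs=0.1)
        flatness = psd[0].std() / psd[0].mean()
        assert flatness < 0.25

    def test_parseval_integral_matches_variance(self, rng):
        fs = 100.0
        sos = signal.butter(4, [2, 40], btype="bandpass", fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, rng.normal(size=int(fs * 200)))
        gamma = np.ones((x.size, 1))
        freqs, psd = bh.state_spectra(x, gamma, fs, band=(1.0, 48.0))
        integral = np.trapezoid(psd[0], freqs)
        assert integral == pytest.approx(x.var(), rel=0.1)


class TestBurstAmplitude:
    def test_constant_tone_amplitude(self):
        fs = 100.0
        t = np.arange(int(fs * 60)) / fs
        x = 2.5 * np.sin(2 * np.pi * 15 * t)
        on = np.zeros(t.size, bool)
        on[int(5 * fs) : int(50 * fs)] = True
        assert bh.burst_amplitude(x, on, fs) == pytest.approx(2.5, rel=0.03)

    def test_linearity_and_zero_occupancy(self):
        fs = 100.0
        rng = np.random.default_rng(0)
        x = rng.normal(size=int(fs * 30))
        on = np.zeros(x.size, bool)
        on[100:900] = True
        a = bh.burst_amplitude(x, on, fs)
        assert bh.burst_amplitude(2 * x, on, fs) == pytest.approx(2 * a, rel=1e-10)
        assert np.isnan(bh.burst_amplitude(x, np.zeros(x.size, bool), fs))
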