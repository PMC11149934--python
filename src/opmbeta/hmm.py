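"""Three-state time-delay-embedded Gaussian HMM for pan-spectral burst
detection on the 1-48 Hz virtual electrode.

States have zero-mean Gaussian observation models over the embedded
(lag-matrix) space and are distinguished by their covariance, i.e. by
spectral content.  Inference is Baum-Welch EM with scaled forward-backward
recursions; the state whose occupancy modulates most with the task is the
burst state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from numba import njit
from scipy import signal
from scipy.linalg import solve_triangular
from scipy.signal import hilbert

from .preprocess import bandpass_filter

logger = logging.getLogger(__name__)

#: trial windows for burst-probability modulation (s, stimulus-locked)
WINDOW_STIM = (0.3, 0.8)
WINDOW_POST = (1.0, 1.5)
BINARIZE_THRESHOLD = 2.0 / 3.0


# ---------------------------------------------------------------- embedding

@dataclass
class EmbeddedSeries:
    """Lag-matrix representation of a resampled, 1-48 Hz filtered, unit
    variance source time course.

    Row ``t`` holds ``x[t], x[t+1], ..., x[t+2*lags]`` so that the centre
    sample of row ``t`` is resampled sample ``t + lags``; the ``lags``
    edge samples on each side have no row.
    """

    X: np.ndarray            # (n_rows, 2*lags + 1)
    lags: int
    fs: float                # after resampling
    n_samples: int           # length of the resampled series
    series: np.ndarray       # the filtered, standardized series itself

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


def _resample(x: np.ndarray, fs: float, target_fs: float, axis: int = -1) -> np.ndarray:
    frac = Fraction(target_fs / fs).limit_denominator(1000)
    return signal.resample_poly(x, frac.numerator, frac.denominator, axis=axis)


def tde_embed(
    x: np.ndarray,
    fs: float,
    lags: int = 7,
    target_fs: float = 100.0,
    band: tuple[float, float] = (1.0, 48.0),
) -> EmbeddedSeries:
    """Anti-alias resample, band-pass 1-48 Hz, standardize, build lag matrix."""
    if target_fs < 2 * band[1]:
        raise ValueError("target_fs must be at least twice the upper band edge")
    x = np.asarray(x, float).ravel()
    if np.ptp(x) == 0:
        raise ValueError("constant series cannot be embedded")
    if fs != target_fs:
        x = _resample(x, fs, target_fs)
    x = bandpass_filter(x, target_fs, band[0], band[1], max_frac=0.49)
    sd = x.std()
    if sd <= 0:
        raise ValueError("constant series cannot be embedded")
    x = (x - x.mean()) / sd
    w = 2 * lags + 1
    if x.size < w:
        raise ValueError("series shorter than the embedding window")
    X = np.lib.stride_tricks.sliding_window_view(x, w).copy()
    return EmbeddedSeries(X=X, lags=lags, fs=target_fs, n_samples=x.size, series=x)


# ------------------------------------------------------------------ the HMM

@njit(cache=True)
def _forward_backward(B, A, pi):  # pragma: no cover - exercised via fit_hmm
    """Scaled forward-backward. B holds per-row-rescaled likelihoods."""
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    tmp = pi * B[0]
    c[0] = tmp.sum()
    alpha[0] = tmp / c[0]
    for t in range(1, T):
        pred = alpha[t - 1] @ A
        tmp = pred * B[t]
        c[t] = tmp.sum()
        alpha[t] = tmp / c[t]
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    for t in range(T):
        gamma[t] /= gamma[t].sum()
    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        for i in range(K):
            for j in range(K):
                xi_sum[i, j] += (
                    alpha[t, i] * A[i, j] * B[t + 1, j] * beta[t + 1, j] / c[t + 1]
                )
    return gamma, xi_sum, np.log(c).sum()


def _log_gauss_zero_mean(X: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """(T, K) log N(x_t; 0, Sigma_k), via Cholesky; loads the diagonal and
    logs a warning if a state covariance has collapsed."""
    T, d = X.shape
    K = covs.shape[0]
    out = np.empty((T, K))
    for k in range(K):
        cov = covs[k]
        for attempt in range(3):
            try:
                Lc = np.linalg.cholesky(cov)
                break
            except np.linalg.LinAlgError:
                load = max(np.trace(cov) / d, 1e-12) * 10.0 ** (-6 + 3 * attempt)
                cov = cov + load * np.eye(d)
                logger.warning("state %d covariance collapsed; diagonal loading", k)
        else:  # pragma: no cover
            raise np.linalg.LinAlgError("covariance irreparably singular")
        covs[k] = cov
        sol = solve_triangular(Lc, X.T, lower=True)
        maha = (sol**2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(Lc)).sum()
        out[:, k] = -0.5 * (d * np.log(2 * np.pi) + logdet + maha)
    return out


@dataclass
class HMMModel:
    K: int
    pi: np.ndarray
    transmat: np.ndarray          # (K, K), rows sum to 1
    covs: np.ndarray              # (K, d, d)
    gamma: np.ndarray             # (T, K) posteriors
    log_likelihoods: np.ndarray   # per EM iteration
    converged: bool
    restart_seeds: list[int] = field(default_factory=list)

    @property
    def log_likelihood(self) -> float:
        return float(self.log_likelihoods[-1])


def _fit_once(X, K, rng, tol, max_iter):
    T, d = X.shape
    # init: random soft assignment -> weighted covariances
    gamma = rng.dirichlet(np.ones(K), size=T)
    pi = np.full(K, 1.0 / K)
    A = np.full((K, K), 0.1 / (K - 1)) + 0.8 * np.eye(K) if K > 1 else np.ones((1, 1))
    covs = np.empty((K, d, d))
    for k in range(K):
        w = gamma[:, k]
        covs[k] = (X.T * w) @ X / w.sum() + 1e-8 * np.eye(d)
    lls = []
    converged = False
    for it in range(max_iter):
        logB = _log_gauss_zero_mean(X, covs)
        shift = logB.max(axis=1)
        B = np.exp(logB - shift[:, None])
        gamma, xi_sum, log_c = _forward_backward(B, A, pi)
        ll = log_c + shift.sum()
        lls.append(ll)
        if it > 0 and abs(ll - lls[-2]) < tol * abs(lls[-2]):
            converged = True
            break
        # M-step
        pi = gamma[0] / gamma[0].sum()
        A = xi_sum / xi_sum.sum(axis=1, keepdims=True)
        for k in range(K):
            w = gamma[:, k]
            nk = w.sum()
            covs[k] = (X.T * w) @ X / max(nk, 1e-12)
    return gamma, pi, A, covs, np.asarray(lls), converged


def fit_hmm(
    X: np.ndarray | EmbeddedSeries,
    K: int = 3,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> HMMModel:
    """Baum-Welch EM for a zero-mean Gaussian HMM over the embedded space.

    Runs ``n_restarts`` randomly initialised fits (restart seeds derived
    from the master seed) and keeps the best by final log-likelihood.
    """
    if isinstance(X, EmbeddedSeries):
        X = X.X
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 50 * K:
        raise ValueError("too few observations for a stable HMM fit")
    master = np.random.default_rng(seed)
    restart_seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=n_restarts)]
    best = None
    for rs in restart_seeds:
        res = _fit_once(X, K, np.random.default_rng(rs), tol, max_iter)
        if best is None or res[4][-1] > best[4][-1]:
            best = res
    gamma, pi, A, covs, lls, converged = best
    logger.info(
        "HMM fit: K=%d, LL=%.2f, %d iterations, converged=%s (restart seeds %s)",
        K, lls[-1], len(lls), converged, restart_seeds,
    )
    return HMMModel(
        K=K, pi=pi, transmat=A, covs=covs, gamma=gamma,
        log_likelihoods=lls, converged=converged, restart_seeds=restart_seeds,
    )


# --------------------------------------------------------- burst extraction

def gamma_full(model_gamma: np.ndarray, embedded: EmbeddedSeries) -> np.ndarray:
    """Posteriors aligned to the resampled series: zero at the ``lags``
    edge samples each side that have no embedding row."""
    T, K = model_gamma.shape
    out = np.zeros((embedded.n_samples, K))
    out[embedded.lags : embedded.lags + T] = model_gamma
    return out


def binarize_states(gamma: np.ndarray, threshold: float = BINARIZE_THRESHOLD) -> np.ndarray:
    """State on iff its posterior strictly exceeds the threshold (2/3).

    With threshold > 1/2 at most one state can be on per sample; samples
    where no posterior clears the bar have no state on.
    """
    return (gamma > threshold).astype(np.int8)


def to_trials(values: np.ndarray, n_trials: int) -> np.ndarray:
    """Reshape a concatenated per-sample array to (n_trials, samples, ...)."""
    if values.shape[0] % n_trials:
        raise ValueError("sample count not divisible by trial count")
    return values.reshape(n_trials, values.shape[0] // n_trials, *values.shape[1:])


def _win_slice(window, t0, fs, n):
    i0 = int(round((window[0] - t0) * fs))
    i1 = int(round((window[1] - t0) * fs))
    if i0 < 0 or i1 > n:
        raise ValueError(f"window {window} outside epoch")
    return slice(i0, i1)


def select_burst_state(
    binary_trials: np.ndarray,
    fs: float,
    t0: float,
    window_stim: tuple[float, float] = WINDOW_STIM,
    window_post: tuple[float, float] = WINDOW_POST,
    weak_threshold: float = 0.02,
) -> int:
    """Index of the state whose occupancy modulates most with the task.

    Modulation is |mean occupancy in the post window - mean occupancy in
    the stimulus window|; ties break to the lowest index.
    """
    n_trials, S, K = binary_trials.shape
    if n_trials < 10:
        raise ValueError("need at least 10 trials to select the burst state")
    sl_s = _win_slice(window_stim, t0, fs, S)
    sl_p = _win_slice(window_post, t0, fs, S)
    occ_s = binary_trials[:, sl_s, :].mean(axis=(0, 1))
    occ_p = binary_trials[:, sl_p, :].mean(axis=(0, 1))
    mod = np.abs(occ_p - occ_s)
    if mod.max() < weak_threshold:
        logger.warning("weak modulation: max occupancy change %.4f", mod.max())
    return int(np.argmax(mod))


@dataclass
class BurstProbability:
    p: np.ndarray              # P(t), trial-averaged burst probability
    times: np.ndarray
    delta_p: float             # mean P[post] - mean P[stim]


def burst_probability(
    burst_trials: np.ndarray,
    fs: float,
    t0: float,
    window_stim: tuple[float, float] = WINDOW_STIM,
    window_post: tuple[float, float] = WINDOW_POST,
) -> BurstProbability:
    """Trial-averaged burst-state probability and its task modulation
    (post-stimulus minus stimulus window means, signed)."""
    n_trials, S = burst_trials.shape
    p = burst_trials.mean(axis=0).astype(float)
    sl_s = _win_slice(window_stim, t0, fs, S)
    sl_p = _win_slice(window_post, t0, fs, S)
    delta = float(p[sl_p].mean() - p[sl_s].mean())
    times = t0 + np.arange(S) / fs
    return BurstProbability(p=p, times=times, delta_p=delta)


def state_spectra(
    x: np.ndarray,
    gamma: np.ndarray,
    fs: float,
    band: tuple[float, float] = (1.0, 48.0),
    window_s: float = 2.0,
    nw: float = 4.0,
    n_tapers: int = 7,
    min_occupancy_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy-weighted multitaper PSD per state.

    The series is split into non-overlapping ``window_s`` windows; each
    window's Slepian-taper PSD enters each state's average weighted by the
    window's mean posterior.  States occupying less than
    ``min_occupancy_s`` in total get a NaN spectrum.
    Returns (freqs, psd) with psd shaped (K, n_freqs), in power density
    units so that the integral over the band approximates the variance.
    """
    T, K = gamma.shape
    if x.shape[0] != T:
        raise ValueError("gamma must be aligned to the series")
    n_win = int(round(window_s * fs))
    n_seg = T // n_win
    if n_seg < 1:
        raise ValueError("series shorter than one spectral window")
    tapers = signal.windows.dpss(n_win, nw, Kmax=n_tapers)  # unit-energy rows
    freqs = np.fft.rfftfreq(n_win, 1 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    psd_num = np.zeros((K, sel.sum()))
    weight = np.zeros(K)
    for s in range(n_seg):
        seg = x[s * n_win : (s + 1) * n_win]
        spec = np.fft.rfft(tapers * seg[None, :], axis=1)
        pxx = (np.abs(spec) ** 2).mean(axis=0) / fs
        pxx[1:-1] *= 2.0  # one-sided
        w = gamma[s * n_win : (s + 1) * n_win].mean(axis=0)
        psd_num += w[:, None] * pxx[sel][None, :]
        weight += w
    psd = np.full((K, sel.sum()), np.nan)
    occ_s = weight * n_win / fs
    for k in range(K):
        if occ_s[k] < min_occupancy_s:
            logger.warning("state %d occupies %.2f s < %.1f s; PSD undefined",
                           k, occ_s[k], min_occupancy_s)
            continue
        psd[k] = psd_num[k] / weight[k]
    return freqs[sel], psd


def burst_amplitude(
    x: np.ndarray,
    burst_on: np.ndarray,
    fs: float,
    band: tuple[float, float] = (1.0, 48.0),
) -> float:
    """Mean 1-48 Hz analytic-signal magnitude during burst-on samples."""
    on = np.asarray(burst_on, bool)
    if on.sum() == 0:
        logger.warning("zero burst occupancy; amplitude undefined")
        return float("nan")
    env = np.abs(hilbert(bandpass_filter(x, fs, band[0], band[1], max_frac=0.49)))
    return float(env[on].mean())
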