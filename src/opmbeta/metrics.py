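"""Hilbert-envelope time-frequency spectra, the beta modulation index and
the evoked M50 response, all computed on virtual-electrode epochs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .preprocess import bandpass_filter

#: analysis windows (s, stimulus-locked)
WINDOW_STIM = (0.3, 0.8)
WINDOW_POST = (1.0, 1.5)
WINDOW_BASELINE = (2.5, 3.0)
BETA_BAND = (13.0, 30.0)


def _window_slice(window: tuple[float, float], t0: float, fs: float, n: int) -> slice:
    i0 = int(round((window[0] - t0) * fs))
    i1 = int(round((window[1] - t0) * fs))
    if i0 < 0 or i1 > n:
        raise ValueError(f"window {window} outside epoch")
    return slice(i0, i1)


def hilbert_envelope(
    x: np.ndarray, fs: float, band: tuple[float, float], axis: int = -1
) -> np.ndarray:
    """Amplitude envelope: |analytic signal| of the band-passed input."""
    if band[1] >= fs / 2:
        raise ValueError(f"band edge {band[1]} Hz at or above Nyquist ({fs / 2} Hz)")
    xf = bandpass_filter(x, fs, band[0], band[1], axis=axis)
    return np.abs(hilbert(xf, axis=axis))


def _epochs_envelope(ve_epochs: np.ndarray, fs: float, band) -> np.ndarray:
    """Envelope per epoch, computed on the concatenated trial series.

    Stimulus-locked epochs of a continuous paradigm are contiguous, so
    filtering the concatenation avoids per-epoch filter and Hilbert edge
    transients (which would bias windows near the epoch boundaries, where
    the baseline window sits)."""
    ve_epochs = np.atleast_2d(ve_epochs)
    env = hilbert_envelope(ve_epochs.reshape(-1), fs, band)
    return env.reshape(ve_epochs.shape)


def _epochs_bandpass(ve_epochs: np.ndarray, fs: float, band) -> np.ndarray:
    ve_epochs = np.atleast_2d(ve_epochs)
    xf = bandpass_filter(ve_epochs.reshape(-1), fs, band[0], band[1])
    return xf.reshape(ve_epochs.shape)


def default_band_set(
    centers: np.ndarray | None = None, width: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Overlapping 4 Hz-wide bands, centres every 1 Hz from 3 to 46 Hz."""
    if centers is None:
        centers = np.arange(3.0, 47.0)
    centers = np.asarray(centers, float)
    edges = np.stack([np.maximum(centers - width / 2, 1.0), centers + width / 2], axis=1)
    return centers, edges


@dataclass
class TFSResult:
    """Time-frequency spectrum of fractional amplitude change.

    values[b, t] = (E_b(t) - mean E_b over baseline) / mean E_b over
    baseline, where E_b is the trial-averaged envelope in band b.  Each
    band's baseline-window mean is zero by construction.
    """

    centers: np.ndarray
    edges: np.ndarray
    times: np.ndarray
    values: np.ndarray          # (n_bands, n_samples)
    baseline: tuple[float, float]


def compute_tfs(
    ve_epochs: np.ndarray,
    fs: float,
    t0: float,
    band_set: tuple[np.ndarray, np.ndarray] | None = None,
    baseline: tuple[float, float] = WINDOW_BASELINE,
) -> TFSResult:
    """Trial-averaged Hilbert-envelope spectrogram, baseline-normalised."""
    ve_epochs = np.atleast_2d(ve_epochs)
    n = ve_epochs.shape[1]
    centers, edges = band_set if band_set is not None else default_band_set()
    if len(centers) < 2:
        raise ValueError("need at least 2 bands")
    sl = _window_slice(baseline, t0, fs, n)
    values = np.empty((len(centers), n))
    for b, (lo, hi) in enumerate(edges):
        env = _epochs_envelope(ve_epochs, fs, (lo, hi)).mean(axis=0)
        base = env[sl].mean()
        if base <= 0:
            raise ValueError("zero baseline envelope")
        values[b] = env / base - 1.0
        values[b] -= values[b, sl].mean()  # exact zero-mean baseline
    times = t0 + np.arange(n) / fs
    return TFSResult(centers=centers, edges=edges, times=times, values=values, baseline=baseline)


@dataclass
class BetaModulation:
    beta_stim: float
    beta_post: float
    beta_baseline: float

    @property
    def value(self) -> float:
        """(beta_post - beta_stim) / beta_baseline."""
        return (self.beta_post - self.beta_stim) / self.beta_baseline


def beta_modulation_index(
    ve_epochs: np.ndarray,
    fs: float,
    t0: float,
    band: tuple[float, float] = BETA_BAND,
    window_stim: tuple[float, float] = WINDOW_STIM,
    window_post: tuple[float, float] = WINDOW_POST,
    window_baseline: tuple[float, float] = WINDOW_BASELINE,
) -> BetaModulation:
    """Beta modulation index from the trial-averaged beta envelope.

    beta_mod = (betaPost - betaStim) / betaBaseline with window means taken
    over the stimulus (0.3-0.8 s), post-stimulus (1-1.5 s) and baseline
    (2.5-3 s) windows.  Scale-invariant in the overall VE amplitude.
    """
    ve_epochs = np.atleast_2d(ve_epochs)
    n = ve_epochs.shape[1]
    env = _epochs_envelope(ve_epochs, fs, band).mean(axis=0)
    means = {}
    for name, win in (
        ("stim", window_stim),
        ("post", window_post),
        ("base", window_baseline),
    ):
        means[name] = float(env[_window_slice(win, t0, fs, n)].mean())
    if means["base"] <= 0:
        raise ValueError("non-positive baseline envelope")
    return BetaModulation(
        beta_stim=means["stim"], beta_post=means["post"], beta_baseline=means["base"]
    )


@dataclass
class EvokedResult:
    evoked: np.ndarray
    times: np.ndarray
    m50: float


def evoked_m50(
    ve_epochs: np.ndarray,
    fs: float,
    t0: float,
    band: tuple[float, float] = (4.0, 40.0),
    latency: float = 0.050,
) -> EvokedResult:
    """Trial-averaged 4-40 Hz evoked response; M50 is the signed value at
    the sample nearest 50 ms post stimulus (no peak search)."""
    ve_epochs = np.atleast_2d(ve_epochs)
    if ve_epochs.shape[0] < 2:
        raise ValueError("need at least 2 trials for an evoked average")
    n = ve_epochs.shape[1]
    idx = int(round((latency - t0) * fs))
    if idx < 0 or idx >= n:
        raise ValueError("epoch does not cover the M50 latency")
    filt = _epochs_bandpass(ve_epochs, fs, band)
    evoked = filt.mean(axis=0)
    times = t0 + np.arange(n) / fs
    return EvokedResult(evoked=evoked, times=times, m50=float(evoked[idx]))
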