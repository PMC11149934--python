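"""Recording cleanup: bad channels, filters, homogeneous field correction,
epoching and high-variance trial rejection."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import EpochSet, Recording

logger = logging.getLogger(__name__)


class PipelineAbort(RuntimeError):
    """Unrecoverable data-quality failure."""


# ---------------------------------------------------------------- filtering

def bandpass_filter(
    data: np.ndarray,
    fs: float,
    lo: float,
    hi: float,
    order: int = 4,
    axis: int = -1,
    max_frac: float = 0.45,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass; the upper edge is clipped to
    ``max_frac * fs`` (with a warning) when the requested band does not
    fit below Nyquist."""
    hi_eff = hi
    if hi >= max_frac * fs:
        hi_eff = max_frac * fs
        warnings.warn(
            f"band edge {hi} Hz too close to Nyquist at fs={fs}; clipped to {hi_eff:.1f} Hz",
            stacklevel=2,
        )
    if lo <= 0 or lo >= hi_eff:
        raise ValueError(f"invalid band ({lo}, {hi}) at fs={fs}")
    sos = signal.butter(order, [lo, hi_eff], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, data, axis=axis)


def notch_filter(
    data: np.ndarray,
    fs: float,
    freqs: tuple[float, ...] = (50.0, 100.0, 150.0),
    q: float = 30.0,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase IIR notches at the line frequency and harmonics; notches
    at or above ~Nyquist are skipped with a warning."""
    out = data
    for f0 in freqs:
        if f0 >= 0.49 * fs:
            warnings.warn(f"notch at {f0} Hz skipped (fs={fs})", stacklevel=2)
            continue
        b, a = signal.iirnotch(f0, q, fs=fs)
        out = signal.filtfilt(b, a, out, axis=axis)
    return out


def apply_filters(
    recording: Recording,
    band: tuple[float, float] = (1.0, 150.0),
    notch_freqs: tuple[float, ...] = (50.0, 100.0, 150.0),
    notch_q: float = 30.0,
) -> tuple[Recording, dict]:
    """Notch (line + harmonics) then band-pass, both zero-phase.

    Returns the filtered recording and a provenance dict recording the
    band actually applied (clipped when fs is too low for the request).
    """
    hi_eff = min(band[1], 0.45 * recording.fs) if band[1] >= 0.45 * recording.fs else band[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data = notch_filter(recording.data, recording.fs, notch_freqs, notch_q)
        data = bandpass_filter(data, recording.fs, band[0], band[1])
    prov = {
        "band_requested": list(band),
        "band_applied": [band[0], hi_eff],
        "notch": [f for f in notch_freqs if f < 0.49 * recording.fs],
        "notch_q": notch_q,
    }
    if hi_eff != band[1]:
        logger.warning(
            "band edge clipped to %.1f Hz (fs=%.0f Hz)", hi_eff, recording.fs
        )
    return recording.copy_with(data=data), prov


# ------------------------------------------------------------ bad channels

@dataclass
class ChannelMask:
    keep: np.ndarray                       # bool per channel
    reasons: dict[int, str] = field(default_factory=dict)  # idx -> flat|noisy

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


def detect_bad_channels(
    recording: Recording,
    z_threshold: float = 3.0,
    band: tuple[float, float] = (1.0, 150.0),
) -> ChannelMask:
    """Flag flat channels (zero variance) and channels whose mean log-PSD
    over the analysis band is a > ``z_threshold`` outlier across channels.

    An automated stand-in for visual inspection of channel spectra: dead
    channels have no power at all, broken ones have excess broadband power.
    """
    data, fs = recording.data, recording.fs
    if recording.duration < 10.0:
        raise ValueError("need at least 10 s of data for channel statistics")
    var = data.var(axis=1)
    flat = var <= 1e-15 * max(var.max(), 1e-300)
    reasons = {int(i): "flat" for i in np.flatnonzero(flat)}

    nper = int(min(2.0 * fs, data.shape[1]))
    f, psd = signal.welch(data, fs=fs, nperseg=nper, axis=1)
    sel = (f >= band[0]) & (f <= min(band[1], 0.45 * fs))
    with np.errstate(divide="ignore"):
        logpsd = np.log10(np.maximum(psd[:, sel], 1e-300)).mean(axis=1)
    ref = logpsd[~flat]
    mu, sd = ref.mean(), ref.std(ddof=1)
    if sd > 0:
        z = (logpsd - mu) / sd
        for i in np.flatnonzero((z > z_threshold) & ~flat):
            reasons[int(i)] = "noisy"
    keep = np.ones(data.shape[0], dtype=bool)
    keep[list(reasons)] = False
    if keep.sum() < 3:
        raise PipelineAbort(
            f"only {int(keep.sum())} channels left after bad-channel detection"
        )
    if reasons:
        logger.info("flagged %d bad channels: %s", len(reasons), reasons)
    return ChannelMask(keep=keep, reasons=reasons)


def drop_channels(recording: Recording, mask: ChannelMask) -> Recording:
    geom = recording.geometry
    keep = mask.keep
    from .containers import ChannelGeometry

    new_geom = ChannelGeometry(
        positions=geom.positions[keep],
        orientations=geom.orientations[keep],
        labels=[l for l, k in zip(geom.labels, keep) if k],
    )
    return recording.copy_with(data=recording.data[keep], geometry=new_geom)


# --------------------------------------------- homogeneous field correction

def homogeneous_field_correction(recording: Recording) -> Recording:
    """Project out the spatially homogeneous field component.

    With S the (n_channels x 3) matrix of channel orientation components, a
    uniform field b(t) appears as S b(t) in the data; the corrected data is
    (I - S (S^T S)^-1 S^T) X, which exactly nulls that subspace.
    """
    S = recording.geometry.orientations
    if np.linalg.matrix_rank(S) < 3:
        raise ValueError("degenerate array: orientations span < 3 dimensions")
    # X' = X - S ((S^T S)^-1 (S^T X)) without forming the projector
    StX = S.T @ recording.data
    coeff = np.linalg.solve(S.T @ S, StX)
    return recording.copy_with(data=recording.data - S @ coeff)


# ------------------------------------------------------------------ epochs

def epoch(recording: Recording, window: tuple[float, float] = (-0.5, 3.0)) -> EpochSet:
    """Cut one epoch per stimulus onset; sample convention half-open
    [t0, t1).  Epochs that fall partly outside the recording are dropped."""
    onsets = recording.paradigm.onsets
    if onsets.size == 0:
        raise ValueError("paradigm has no stimulus onsets")
    fs = recording.fs
    n_samp = int(round((window[1] - window[0]) * fs))
    fingers = recording.paradigm.trial_fingers
    chunks, kept_fingers, kept_onsets, dropped = [], [], [], 0
    for onset, fing in zip(onsets, fingers):
        i0 = int(round((onset + window[0]) * fs))
        if i0 < 0 or i0 + n_samp > recording.n_samples:
            dropped += 1
            continue
        chunks.append(recording.data[:, i0 : i0 + n_samp])
        kept_fingers.append(fing)
        kept_onsets.append(onset)
    if dropped:
        logger.info("dropped %d partial epochs at recording edges", dropped)
    if not chunks:
        raise ValueError("no complete epochs inside the recording")
    data = np.stack(chunks)
    return EpochSet(
        data=data,
        fs=fs,
        window=window,
        fingers=kept_fingers,
        trial_keep=np.ones(len(chunks), dtype=bool),
        onsets=np.asarray(kept_onsets),
    )


def reject_high_variance_trials(epochs: EpochSet, n_sd: float = 3.0) -> EpochSet:
    """Mask trials whose variance exceeds mean + ``n_sd`` sample SDs.

    Per-trial variance is the per-channel variance averaged over channels;
    the threshold is applied in a single pass with a strict inequality.
    """
    if epochs.n_trials < 5:
        raise ValueError("need at least 5 trials for variance statistics")
    v = epochs.data.var(axis=2).mean(axis=1)
    thr = v.mean() + n_sd * v.std(ddof=1)
    keep = ~(v > thr)
    keep &= epochs.trial_keep
    n_rej = int((~keep).sum())
    if n_rej > 0.5 * epochs.n_trials:
        logger.warning("rejected %d/%d trials (>50%%)", n_rej, epochs.n_trials)
    out = EpochSet(
        data=epochs.data,
        fs=epochs.fs,
        window=epochs.window,
        fingers=epochs.fingers,
        trial_keep=keep,
        onsets=epochs.onsets,
    )
    return out


def preprocess_recording(
    recording: Recording,
    z_threshold: float = 3.0,
    band: tuple[float, float] = (1.0, 150.0),
    notch_freqs: tuple[float, ...] = (50.0, 100.0, 150.0),
    window: tuple[float, float] = (-0.5, 3.0),
    var_n_sd: float = 3.0,
) -> tuple[Recording, EpochSet, dict]:
    """Full cleanup chain: bad channels -> filters -> HFC -> epochs -> trials."""
    mask = detect_bad_channels(recording, z_threshold=z_threshold)
    rec = drop_channels(recording, mask)
    rec, filt_prov = apply_filters(rec, band=band, notch_freqs=notch_freqs)
    rec = homogeneous_field_correction(rec)
    ep = epoch(rec, window=window)
    ep = reject_high_variance_trials(ep, n_sd=var_n_sd)
    prov = {
        "bad_channels": mask.reasons,
        "n_channels_kept": mask.n_kept,
        "filters": filt_prov,
        "n_trials": ep.n_trials,
        "n_trials_kept": int(ep.trial_keep.sum()),
    }
    return rec, ep, prov
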