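"""Synthetic OPM-MEG cohort generator.

Generates multichannel somatosensory recordings with planted, recoverable
structure: a left-sensorimotor source emitting pan-spectral bursts whose
probability drops during stimulation (depth growing with age), an
age-dependent burst spectral tilt with a stable alpha peak, an age-constant
burst amplitude, a phase-locked M50, and a 78-region network whose envelope
coupling rises with age faster frontally than occipitally — plus line
noise, a homogeneous interference field, bad channels and high-variance
trials for the cleanup stages to find.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .connectivity import Parcellation
from .containers import (
    ChannelGeometry,
    GeometryError,
    HeadModel,
    Paradigm,
    Recording,
    SensorArray,
    channel_geometry,
)
from .forward import compute_leadfield, tangential_basis

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- geometry

def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    theta = np.pi * (3.0 - np.sqrt(5.0)) * i
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def make_sensor_array(
    n_sensors: int = 64,
    head_radius: float = 0.09,
    offset: float = 0.015,
    seed: int = 0,
) -> SensorArray:
    """Quasi-uniform triaxial array on a sphere of radius
    ``head_radius + offset``; each sensor measures one radial and two
    tangential field components (3 channels per sensor)."""
    if head_radius <= 0 or offset <= 0:
        raise GeometryError("head radius and offset must be positive")
    if n_sensors < 4:
        raise GeometryError("need at least 4 sensors")
    dirs = _fibonacci_sphere(n_sensors)
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    dirs = dirs @ q.T
    positions = (head_radius + offset) * dirs
    tang = tangential_basis(dirs)
    orientations = np.stack([dirs, tang[:, :, 0], tang[:, :, 1]], axis=1)
    labels = [
        f"S{i:02d}-{ax}" for i in range(n_sensors) for ax in ("rad", "tan1", "tan2")
    ]
    return SensorArray(positions=positions, orientations=orientations, labels=labels)


def make_parcellation(n_regions: int = 78, radius: float = 0.06) -> Parcellation:
    """Deterministic synthetic parcellation: centroids on an inner sphere
    with frontal (anterior), occipital (posterior) and other tags."""
    dirs = _fibonacci_sphere(n_regions)
    centroids = radius * dirs
    groups = np.where(
        centroids[:, 1] > 0.02, "frontal", np.where(centroids[:, 1] < -0.02, "occipital", "other")
    )
    labels = [f"R{i:02d}-{g}" for i, g in enumerate(groups)]
    return Parcellation(labels=labels, centroids=centroids, groups=groups)


# ------------------------------------------------------------ ground truth

@dataclass
class BurstGroundTruth:
    """Planted burst statistics for one subject."""

    baseline_rate: float = 1.8          # bursts / s
    modulation_depth: float = 0.5       # d in [0, 1]
    burst_duration_mean: float = 0.2    # s
    spectral_tilt: float = 1.0          # in-burst PSD ~ f**(-tilt) on 1-48 Hz
    alpha_peak_power: float = 0.5       # fixed alpha bump weight at 9 Hz
    burst_amplitude: float = 1.0        # in-burst RMS, source units
    floor_sigma: float = 0.15           # between-burst noise floor SD
    alpha_bg_amplitude: float = 0.5     # background alpha-texture RMS
    suppression_window: tuple[float, float] = (0.0, 0.8)  # s post-onset

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation depth must lie in [0, 1]")
        if self.baseline_rate < 0:
            raise ValueError("burst rate must be non-negative")


@dataclass
class TrendSpec:
    """Linear age trends used to draw per-subject planted parameters.

    Degree trends follow the reported developmental gradients: frontal
    node degree 0.27/year (intercept 0.26), occipital 0.10/year
    (intercept 2.92); modulation depth rises and spectral tilt falls with
    age, while burst amplitude and the alpha peak stay constant.
    """

    d_intercept: float = 0.10
    d_slope: float = 0.022              # / year
    d_sigma: float = 0.05
    tilt_intercept: float = 1.4
    tilt_slope: float = -0.025          # / year
    tilt_sigma: float = 0.05
    alpha_peak_power: float = 0.5
    burst_amplitude: float = 1.0
    amplitude_slope: float = 0.0        # / year; 0 = age-invariant default
    baseline_rate: float = 1.8
    burst_duration_mean: float = 0.2
    m50_amplitude: float = 0.5
    degree_frontal: tuple[float, float] = (0.26, 0.27)    # intercept, slope/yr
    degree_occipital: tuple[float, float] = (2.92, 0.10)
    degree_other: tuple[float, float] = (1.50, 0.18)
    network_amplitude: float = 0.12     # region-source RMS, source units

    def degree_target(self, group: str, age: float) -> float:
        b, m = {
            "frontal": self.degree_frontal,
            "occipital": self.degree_occipital,
        }.get(group, self.degree_other)
        return b + m * age


@dataclass
class NoiseSpec:
    white_sigma: float = 1.0            # sensor white-noise SD (channel units)
    line_amp: float = 1.0               # 50/100/150 Hz amplitude, x white_sigma
    drift_sigma: float = 5.0            # homogeneous field SD, x white_sigma
    drift_cutoff: float = 2.0           # Hz low-pass for the drift
    n_flat_channels: int = 1
    n_noisy_channels: int = 1
    noisy_factor: float = 10.0
    n_bad_trials: int = 2
    bad_trial_factor: float = 10.0


@dataclass
class CohortGroundTruth:
    """Everything the generator planted, for parameter-recovery tests."""

    ages: np.ndarray
    bursts: list[BurstGroundTruth]
    dipole_position: np.ndarray
    m50_amplitude: float
    trend: TrendSpec
    parcellation: Parcellation
    target_degree: np.ndarray            # (n_subjects, n_regions)
    bad_channels: list[dict[int, str]]   # per subject, planted idx -> kind
    bad_trials: list[list[int]]
    seeds: list[int]

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for i, (age, gt) in enumerate(zip(self.ages, self.bursts)):
            rows.append(
                {
                    "subject": f"S{i:03d}",
                    "age": age,
                    "modulation_depth": gt.modulation_depth,
                    "spectral_tilt": gt.spectral_tilt,
                    "alpha_peak_power": gt.alpha_peak_power,
                    "burst_amplitude": gt.burst_amplitude,
                    "baseline_rate": gt.baseline_rate,
                    "m50_amplitude": self.m50_amplitude,
                }
            )
        return pd.DataFrame(rows)


# ------------------------------------------------------------- burst train

def simulate_burst_train(
    paradigm: Paradigm,
    ground_truth: BurstGroundTruth,
    duration: float,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Non-overlapping inhomogeneous point process of (onset, duration).

    The onset rate is ``baseline_rate`` except inside the per-trial
    suppression window (0-0.8 s post-onset) where it is
    ``baseline_rate * (1 - d)``.  Candidates are drawn at a dead-time
    compensated rate and thinned, so empirical rates match the target.
    """
    gt = ground_truth
    rng = np.random.default_rng(seed)
    if gt.baseline_rate == 0:
        return []
    dead = gt.baseline_rate * gt.burst_duration_mean
    cand_rate = gt.baseline_rate / max(1.0 - dead, 0.5)
    onsets = paradigm.onsets
    lo, hi = gt.suppression_window
    bursts: list[tuple[float, float]] = []
    t = float(rng.exponential(1.0 / cand_rate))
    prev_end = -np.inf
    while t < duration:
        in_stim = np.any((onsets + lo <= t) & (t < onsets + hi))
        accept = rng.random() < (1.0 - gt.modulation_depth) if in_stim else True
        if accept and t >= prev_end:
            dur = float(rng.gamma(4.0, gt.burst_duration_mean / 4.0))
            dur = min(dur, duration - t)
            if dur > 0.02:
                bursts.append((t, dur))
                prev_end = t + dur
        t += float(rng.exponential(1.0 / cand_rate))
    return bursts


# ------------------------------------------------------------ source model

def _coloured_carrier(
    n: int,
    fs: float,
    tilt: float,
    alpha_peak_power: float,
    rng: np.random.Generator,
    band: tuple[float, float] = (1.0, 48.0),
    alpha_freq: float = 9.0,
    alpha_sigma: float = 1.5,
) -> np.ndarray:
    """Unit-variance noise with PSD ~ f**(-tilt) on the band plus a fixed
    Gaussian alpha bump at 9 Hz."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    S = np.zeros_like(freqs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    S[sel] = freqs[sel] ** (-tilt)
    if S[sel].sum() > 0:
        S[sel] /= S[sel].sum()
    bump = np.exp(-0.5 * ((freqs - alpha_freq) / alpha_sigma) ** 2)
    bump[~sel] = 0.0
    if bump.sum() > 0:
        S = S + alpha_peak_power * bump / bump.sum()
    spec = np.sqrt(S) * (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size))
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def synthesize_source(
    burst_train: list[tuple[float, float]],
    ground_truth: BurstGroundTruth,
    fs: float,
    duration: float,
    onsets: np.ndarray | None = None,
    m50_amplitude: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Source time course: noise floor + Tukey-windowed coloured-noise
    bursts (RMS = burst_amplitude) + a phase-locked Gaussian M50 bump
    (peak 50 ms post-onset, sigma 10 ms) per trial."""
    if fs < 100:
        raise ValueError("source sampling rate must be at least 100 Hz")
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n) * ground_truth.floor_sigma
    burst_on = np.zeros(n, dtype=bool)
    for onset, dur in burst_train:
        i0 = int(round(onset * fs))
        burst_on[i0 : i0 + int(round(dur * fs))] = True
    if ground_truth.alpha_bg_amplitude > 0:
        # task-unrelated background alternating between an alpha-band and a
        # weaker theta-band texture: ongoing activity is heterogeneous, so
        # non-burst time is shared between two recurrent regimes rather
        # than one monolithic floor; bursts interrupt the background
        switch = _smooth_noise(rng, n, fs, 0.7)[None].ravel() > 0
        amp = ground_truth.alpha_bg_amplitude
        for band_bg, mask, a in (
            ((8.0, 10.0), switch & ~burst_on, amp),
            ((3.0, 6.0), (~switch) & ~burst_on, 0.5 * amp),
        ):
            sos_bg = signal.butter(4, band_bg, btype="bandpass", fs=fs, output="sos")
            tex = signal.sosfiltfilt(sos_bg, rng.normal(size=n))
            rms = tex.std()
            if rms > 0 and mask.any():
                x[mask] += tex[mask] * (a / rms)
    if ground_truth.burst_amplitude > 0 and burst_train:
        carrier = _coloured_carrier(
            n, fs, ground_truth.spectral_tilt, ground_truth.alpha_peak_power, rng
        )
        for onset, dur in burst_train:
            i0 = int(round(onset * fs))
            nb = int(round(dur * fs))
            if nb < 4 or i0 + nb > n:
                continue
            seg = carrier[i0 : i0 + nb] * signal.windows.tukey(nb, 0.25)
            rms = np.sqrt(np.mean(seg**2))
            if rms > 0:
                x[i0 : i0 + nb] += seg * (ground_truth.burst_amplitude / rms)
    if m50_amplitude != 0.0 and onsets is not None:
        t = np.arange(n) / fs
        for onset in onsets:
            tp = onset + 0.050
            sl = slice(int((tp - 0.06) * fs), int((tp + 0.06) * fs))
            x[sl] += m50_amplitude * np.exp(-0.5 * ((t[sl] - tp) / 0.010) ** 2)
    return x


# ------------------------------------------------------- network envelopes

def _smooth_noise(rng, shape, fs, cutoff):
    z = rng.normal(size=shape)
    sos = signal.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    z = signal.sosfiltfilt(sos, z, axis=-1)
    sd = z.std(axis=-1, keepdims=True)
    return z / np.where(sd > 0, sd, 1.0)


def _nearest_corr(C: np.ndarray, floor: float = 1e-3) -> np.ndarray:
    evals, evecs = np.linalg.eigh(C)
    C2 = (evecs * np.maximum(evals, floor)) @ evecs.T
    d = np.sqrt(np.diag(C2))
    return C2 / np.outer(d, d)


def network_sources(
    target_corr: np.ndarray,
    duration: float,
    fs: float,
    seed: int = 0,
    amplitude: float = 1.0,
    band: tuple[float, float] = (13.0, 30.0),
    envelope_cutoff: float = 1.0,
) -> np.ndarray:
    """Beta-band region signals with planted envelope correlations.

    Each region is a constant-amplitude FM carrier wandering inside the
    beta band, amplitude-modulated by a smooth positive envelope; the
    envelopes are correlated Gaussians with the requested correlation
    matrix, so measured AEC recovers ``target_corr`` (up to clipping and
    sampling noise).
    """
    n = target_corr.shape[0]
    T = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    C = _nearest_corr(np.asarray(target_corr, float))
    L = np.linalg.cholesky(C)
    z = _smooth_noise(rng, (n, T), fs, envelope_cutoff)
    env = np.clip(3.0 + L @ z, 0.05, None)
    fdev = _smooth_noise(rng, (n, T), fs, 2.0)
    f_inst = 0.5 * (band[0] + band[1]) + 0.45 * (band[1] - band[0]) / 2 * np.tanh(fdev)
    phase = 2 * np.pi * np.cumsum(f_inst, axis=-1) / fs
    phase += rng.uniform(0, 2 * np.pi, size=(n, 1))
    x = env * np.cos(phase)
    rms = np.sqrt((x**2).mean(axis=-1, keepdims=True))
    return amplitude * x / np.where(rms > 0, rms, 1.0)


def target_aec_matrix(parcellation: Parcellation, age: float, trend: TrendSpec) -> np.ndarray:
    """Pairwise envelope-correlation targets whose node degrees follow the
    per-group degree-vs-age lines."""
    n = parcellation.n_regions
    cbar = np.array(
        [
            np.clip(trend.degree_target(g, age) / (n - 1), 0.005, 0.8)
            for g in parcellation.groups
        ]
    )
    C = 0.5 * (cbar[:, None] + cbar[None, :])
    np.fill_diagonal(C, 1.0)
    return C


# --------------------------------------------------------- sensor projection

@dataclass
class PlantedSource:
    position: np.ndarray
    moment: np.ndarray           # (3,) A m
    timecourse: np.ndarray       # (T,)


def tangential_moment(position: np.ndarray, head: HeadModel | None = None) -> np.ndarray:
    head = head or HeadModel()
    return tangential_basis(np.asarray(position, float), head.origin)[0, :, 0]


def project_to_sensors(
    sources: list[PlantedSource],
    array: SensorArray | ChannelGeometry,
    head: HeadModel,
    fs: float,
    noise: NoiseSpec | None = None,
    paradigm: Paradigm | None = None,
    seed: int = 0,
    subject_id: str = "S000",
    age: float = float("nan"),
) -> tuple[Recording, dict]:
    """Mix sources through the spherical forward model and add sensor-space
    nuisance: white noise, line harmonics, a slowly varying homogeneous
    interference field, flat / noisy channels and high-variance trials.

    Noiseless projection is exactly linear in the source time courses.
    Returns the recording and a dict of planted bad channels / trials.
    """
    geom = channel_geometry(array) if isinstance(array, SensorArray) else array
    noise = noise or NoiseSpec(white_sigma=0.0, line_amp=0.0, drift_sigma=0.0,
                               n_flat_channels=0, n_noisy_channels=0, n_bad_trials=0)
    rng = np.random.default_rng(seed)
    if sources:
        T = sources[0].timecourse.size
        for s in sources:
            if s.timecourse.size != T:
                raise ValueError("all sources must share a common length")
    else:
        if paradigm is None:
            raise ValueError("need sources or a paradigm to set the duration")
        T = int(round(paradigm.total_duration * fs))
    data = np.zeros((geom.n_channels, T))
    if sources:
        lf = compute_leadfield(
            np.stack([s.position for s in sources]), geom, head
        )
        gains = np.einsum("vcj,vj->cv", lf.L, np.stack([s.moment for s in sources]))
        data += gains @ np.stack([s.timecourse for s in sources])
    t = np.arange(T) / fs
    sig = noise.white_sigma
    if sig > 0:
        data += rng.normal(size=data.shape) * sig
        for f0 in (50.0, 100.0, 150.0):
            if f0 >= fs / 2:
                continue
            gain = rng.uniform(0.8, 1.2, size=geom.n_channels)
            phase = rng.uniform(0, 2 * np.pi)
            data += (noise.line_amp * sig) * gain[:, None] * np.sin(
                2 * np.pi * f0 * t + phase
            )[None, :]
        if noise.drift_sigma > 0:
            b = _smooth_noise(rng, (3, T), fs, noise.drift_cutoff)
            data += geom.orientations @ (noise.drift_sigma * sig * b)
    planted: dict = {"bad_channels": {}, "bad_trials": []}
    n_bad = noise.n_flat_channels + noise.n_noisy_channels
    if n_bad:
        bad = rng.choice(geom.n_channels, size=n_bad, replace=False)
        for i in bad[: noise.n_flat_channels]:
            data[i] = 0.0
            planted["bad_channels"][int(i)] = "flat"
        for i in bad[noise.n_flat_channels :]:
            data[i] += rng.normal(size=T) * sig * noise.noisy_factor
            planted["bad_channels"][int(i)] = "noisy"
    if noise.n_bad_trials and paradigm is not None:
        onsets = paradigm.onsets
        picks = rng.choice(len(onsets), size=noise.n_bad_trials, replace=False)
        good = np.setdiff1d(np.arange(geom.n_channels), list(planted["bad_channels"]))
        for k in sorted(picks):
            i0 = max(int((onsets[k] - 0.5) * fs), 0)
            i1 = min(int((onsets[k] + 3.0) * fs), T)
            data[np.ix_(good, range(i0, i1))] += (
                rng.normal(size=(good.size, i1 - i0)) * sig * noise.bad_trial_factor
            )
            planted["bad_trials"].append(int(k))
    if paradigm is None:
        paradigm = Paradigm(n_trials_per_finger=0)
    rec = Recording(
        data=data, fs=fs, geometry=geom, paradigm=paradigm,
        subject_id=subject_id, age=age,
    )
    return rec, planted


def source_sensor_rms(
    source: PlantedSource, array: SensorArray | ChannelGeometry, head: HeadModel
) -> float:
    """RMS of the strongest channel's noiseless projection of one source;
    used to set the white-noise level for a requested SNR."""
    geom = channel_geometry(array) if isinstance(array, SensorArray) else array
    lf = compute_leadfield(source.position[None, :], geom, head)
    g = lf.L[0] @ source.moment
    return float(np.abs(g).max() * source.timecourse.std())


# ------------------------------------------------------------------ cohort

def make_cohort(
    n_subjects: int = 30,
    age_range: tuple[float, float] = (2.0, 34.0),
    trend: TrendSpec | None = None,
    seed: int = 0,
    fs: float = 300.0,
    n_trials_per_finger: int = 42,
    n_sensors: int = 64,
    n_regions: int = 78,
    snr: float = 3.0,
    with_network: bool = True,
    dipole_position: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
) -> tuple[list[Recording], CohortGroundTruth]:
    """Generate a cohort of recordings with linear age trends planted.

    Ages are evenly spaced over ``age_range`` (deterministic coverage for
    trend recovery); per-subject seeds are ``seed + subject_index``.  The
    default 8 trials/finger keeps each recording near one minute; the
    full-length paradigm (42/finger) is available by argument.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    trend = trend or TrendSpec()
    head = HeadModel()
    array = make_sensor_array(n_sensors=n_sensors, seed=seed)
    parcellation = make_parcellation(n_regions=n_regions)
    if age_range[0] == age_range[1]:
        logger.warning("degenerate age range: all subjects share age %.1f", age_range[0])
        ages = np.full(n_subjects, float(age_range[0]))
    else:
        ages = np.linspace(age_range[0], age_range[1], n_subjects)
    if not (2.0 <= ages.min() and ages.max() <= 34.0):
        raise ValueError("ages must lie within [2, 34] years")
    dipole_position = (
        np.asarray(dipole_position, float)
        if dipole_position is not None
        else np.array([-0.045, 0.005, 0.040])
    )
    recordings, bursts, seeds_used = [], [], []
    bad_ch, bad_tr = [], []
    target_degree = np.zeros((n_subjects, parcellation.n_regions))
    for i in range(n_subjects):
        sub_seed = seed + i
        rng = np.random.default_rng(sub_seed)
        age = float(ages[i])
        d = float(np.clip(
            trend.d_intercept + trend.d_slope * age + rng.normal(0, trend.d_sigma),
            0.0, 0.95,
        ))
        tilt = float(
            trend.tilt_intercept + trend.tilt_slope * age + rng.normal(0, trend.tilt_sigma)
        )
        amp = trend.burst_amplitude + trend.amplitude_slope * age
        gt = BurstGroundTruth(
            baseline_rate=trend.baseline_rate,
            modulation_depth=d,
            burst_duration_mean=trend.burst_duration_mean,
            spectral_tilt=tilt,
            alpha_peak_power=trend.alpha_peak_power,
            burst_amplitude=amp,
        )
        paradigm = Paradigm(n_trials_per_finger=n_trials_per_finger)
        duration = paradigm.total_duration
        train = simulate_burst_train(paradigm, gt, duration, seed=sub_seed)
        src = synthesize_source(
            train, gt, fs, duration,
            onsets=paradigm.onsets, m50_amplitude=trend.m50_amplitude, seed=sub_seed,
        )
        sources = [PlantedSource(
            position=dipole_position,
            moment=tangential_moment(dipole_position, head),
            timecourse=src,
        )]
        if with_network:
            C = target_aec_matrix(parcellation, age, trend)
            net = network_sources(
                C, duration, fs, seed=sub_seed + 10_000,
                amplitude=trend.network_amplitude,
            )
            for r in range(parcellation.n_regions):
                pos = parcellation.centroids[r]
                sources.append(PlantedSource(
                    position=pos, moment=tangential_moment(pos, head), timecourse=net[r],
                ))
        target_degree[i] = [
            trend.degree_target(g, age) for g in parcellation.groups
        ]
        rms = source_sensor_rms(sources[0], array, head)
        nz = noise or NoiseSpec()
        nz = NoiseSpec(**{**nz.__dict__, "white_sigma": rms / snr})
        rec, planted = project_to_sensors(
            sources, array, head, fs, noise=nz, paradigm=paradigm,
            seed=sub_seed, subject_id=f"S{i:03d}", age=age,
        )
        recordings.append(rec)
        bursts.append(gt)
        seeds_used.append(sub_seed)
        bad_ch.append(planted["bad_channels"])
        bad_tr.append(planted["bad_trials"])
    truth = CohortGroundTruth(
        ages=ages,
        bursts=bursts,
        dipole_position=dipole_position,
        m50_amplitude=trend.m50_amplitude,
        trend=trend,
        parcellation=parcellation,
        target_degree=target_degree,
        bad_channels=bad_ch,
        bad_trials=bad_tr,
        seeds=seeds_used,
    )
    return recordings, truth
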