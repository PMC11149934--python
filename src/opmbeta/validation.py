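"""End-to-end validation computations: parameter-recovery studies on the
synthetic cohort and oracle checks for the core numerics.

Each function recomputes its quantity from scratch by running the package
on generated data; the same routines back the acceptance checks in the
test suite and the standalone acceptance script.  Problem sizes are the
package's validation defaults (documented in the methods note); every
stochastic step derives its seeds from the caller's master seed.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import signal, stats

from . import beamformer as bf
from . import connectivity as conn
from . import hmm as bh
from . import metrics as om
from . import preprocess as pp
from . import stats as gs
from . import synthetic as syn
from .containers import HeadModel, Paradigm, Recording, channel_geometry
from .forward import compute_leadfield, make_grid
from .pipeline import PipelineConfig, run_pipeline

DIPOLE = np.array([-0.045, 0.005, 0.040])


# ------------------------------------------------------ design constants

def paradigm_task_duration() -> float:
    """Total stimulated task time: 42 trials/finger x 2 fingers x 3.5 s."""
    return Paradigm().task_duration


def channel_count() -> int:
    """Channels delivered by the full 64-sensor triaxial array."""
    return syn.make_sensor_array(64).n_channels


# ------------------------------------------------------------ beamformer

def _suppressed_beta_recording(seed: int, snr: float = 1.0, tpf: int = 20):
    """Planted tangential dipole, 6 cm from origin, emitting beta-band
    noise whose power drops x0.25 during the active windows."""
    head = HeadModel()
    arr = syn.make_sensor_array(64, seed=0)
    fs = 300.0
    par = Paradigm(n_trials_per_finger=tpf)
    n = int(par.total_duration * fs)
    rng = np.random.default_rng(seed)
    sos = signal.butter(4, [13, 30], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.normal(size=n))
    x /= x.std()
    t = np.arange(n) / fs
    for on in par.onsets:
        x[(t >= on + 0.3) & (t < on + 0.8)] *= 0.5
    src = syn.PlantedSource(DIPOLE, syn.tangential_moment(DIPOLE, head), x)
    rms = syn.source_sensor_rms(src, arr, head)
    noise = syn.NoiseSpec(white_sigma=rms / snr, line_amp=1.0, drift_sigma=5.0)
    rec, _ = syn.project_to_sensors(
        [src], arr, head, fs, noise=noise, paradigm=par, seed=seed + 100
    )
    return rec, head


def localization_errors(n_seeds: int = 10, seed: int = 0) -> np.ndarray:
    """Peak-voxel error (mm) on a 4 mm grid for the planted suppressed
    beta dipole at sensor SNR 1, one value per seed."""
    errs = []
    for k in range(n_seeds):
        rec, head = _suppressed_beta_recording(seed + k)
        clean, epochs, _ = pp.preprocess_recording(rec)
        grid = make_grid(
            head, 0.004, center=DIPOLE + np.array([0.002, -0.003, 0.001]),
            half_extent=0.016,
        )
        lf = compute_leadfield(grid.points, clean.geometry, head)
        tmap = bf.pseudo_t_map(epochs, lf)
        errs.append(1000.0 * np.linalg.norm(tmap.peak_point - DIPOLE))
    return np.asarray(errs)


def unit_gain_and_qp_errors(n_instances: int = 20, seed: int = 0) -> tuple[float, float]:
    """Max |w^T L eta - 1| and max deviation from the constrained-QP
    (KKT) oracle over random 6-channel instances."""
    rng = np.random.default_rng(seed)
    worst_gain, worst_qp = 0.0, 0.0
    for _ in range(n_instances):
        A = rng.normal(size=(6, 6))
        C = A @ A.T + 6 * np.eye(6)
        L3 = rng.normal(size=(6, 3))
        cov = bf.CovarianceModel(C=C, mu=0.05)
        point = rng.uniform(-0.05, 0.05, size=3)
        vw = bf.lcmv_weights(L3, cov, point=point)
        if not vw.ok:
            continue
        worst_gain = max(worst_gain, abs(float(vw.w @ (L3 @ vw.eta)) - 1.0))
        g = L3 @ vw.eta
        n = len(g)
        kkt = np.zeros((n + 1, n + 1))
        kkt[:n, :n] = 2 * cov.C_reg
        kkt[:n, n] = -g
        kkt[n, :n] = g
        rhs = np.zeros(n + 1)
        rhs[n] = 1.0
        w_oracle = np.linalg.solve(kkt, rhs)[:n]
        worst_qp = max(
            worst_qp, float(np.abs(vw.w - w_oracle).max() / np.abs(w_oracle).max())
        )
    return worst_gain, worst_qp


# ------------------------------------------------------------------- HMM

def forward_backward_enumeration_error(seed: int = 0) -> float:
    """Max |posterior difference| between scaled forward-backward and the
    exhaustive sum over all 2^6 state paths."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=6)
    pi = np.array([0.7, 0.3])
    A = np.array([[0.9, 0.1], [0.2, 0.8]])
    sigmas = np.array([1.0, 3.0])
    like = np.stack(
        [np.exp(-0.5 * (x / s) ** 2) / (np.sqrt(2 * np.pi) * s) for s in sigmas],
        axis=1,
    )
    gamma_oracle = np.zeros((6, 2))
    total = 0.0
    for path in itertools.product(range(2), repeat=6):
        p = pi[path[0]] * like[0, path[0]]
        for t in range(1, 6):
            p *= A[path[t - 1], path[t]] * like[t, path[t]]
        total += p
        for t in range(6):
            gamma_oracle[t, path[t]] += p
    gamma_oracle /= total
    gamma, _, _ = bh._forward_backward(like, A, pi)
    return float(np.abs(gamma - gamma_oracle).max())


def hmm_recovery_accuracies(n_seeds: int = 5, seed: int = 0) -> np.ndarray:
    """State-sequence accuracy for a 2-state variance-switching process
    (sigma 1 vs 3, dwell 20 samples), best label alignment."""
    out = []
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + k)
        states = np.repeat(rng.integers(0, 2, size=200), 20)
        x = rng.normal(size=states.size) * np.where(states == 0, 1.0, 3.0)
        model = bh.fit_hmm(x[:, None], K=2, n_restarts=3, seed=seed + k, max_iter=200)
        hard = model.gamma.argmax(axis=1)
        out.append(max((hard == states).mean(), (hard == 1 - states).mean()))
    return np.asarray(out)


def hmm_loglik_monotone(seed: int = 0) -> float:
    """Largest per-iteration decrease of the EM log-likelihood (should be
    ~0 up to float rounding; positive values mean increases only)."""
    rng = np.random.default_rng(seed)
    states = np.repeat(rng.integers(0, 2, size=150), 20)
    x = rng.normal(size=states.size) * np.where(states == 0, 1.0, 3.0)
    model = bh.fit_hmm(x[:, None], K=2, n_restarts=2, seed=seed, max_iter=150)
    diffs = np.diff(model.log_likelihoods)
    return float(max(0.0, -diffs.min()))


# -------------------------------------------------------------- envelope

def tone_envelope_error(fs: float = 300.0) -> float:
    """Relative error of the Hilbert envelope of a 2-unit beta tone."""
    t = np.arange(int(fs * 20)) / fs
    x = 2.0 * np.sin(2 * np.pi * 20 * t)
    env = om.hilbert_envelope(x, fs, (13, 30))
    mid = env[int(2 * fs) : -int(2 * fs)]
    return float(np.abs(mid - 2.0).max() / 2.0)


def stationary_tfs_deviation(seed: int = 0) -> float:
    """Mean absolute per-band deviation of the TFS for stationary input
    (80 trials, no modulation planted)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(80, 1050))
    res = om.compute_tfs(x, 300.0, t0=-0.5)
    return float(np.abs(res.values.mean(axis=1)).mean())


def betamod_formula_cases() -> tuple[float, float]:
    """The two printed beta-modulation arithmetic cases."""
    return (
        om.BetaModulation(0.5, 1.5, 1.0).value,
        om.BetaModulation(0.7, 0.7, 2.0).value,
    )


# ---------------------------------------------------------- connectivity

def aec_checks(seed: int = 0) -> dict:
    """Leaked-copy zero, planted 0.6 recovery and connectome structure."""
    import warnings

    rng = np.random.default_rng(seed)
    sos = signal.butter(4, [13, 30], btype="bandpass", fs=300.0, output="sos")
    x = signal.sosfiltfilt(sos, rng.normal(size=9000))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        leaked = conn.aec(x, 1.7 * x, 300.0)
    C = np.array([[1.0, 0.6], [0.6, 1.0]])
    pair = syn.network_sources(C, 150.0, 300.0, seed=seed + 21)
    planted = conn.aec(pair[0], pair[1], 300.0)
    parc = syn.make_parcellation(6)
    C6 = np.full((6, 6), 0.3)
    np.fill_diagonal(C6, 1.0)
    x6 = syn.network_sources(C6, 60.0, 300.0, seed=seed + 2)
    cm = conn.build_connectome(x6, 300.0, parc)
    return {
        "leaked": leaked,
        "planted_0p6": planted,
        "asymmetry": float(np.abs(cm.A - cm.A.T).max()),
        "diag": float(np.abs(np.diag(cm.A)).max()),
        "max_abs": float(np.abs(cm.A).max()),
    }


# ------------------------------------------------------- cohort recovery

def cohort_recovery(seed: int = 1, config: PipelineConfig | None = None) -> dict:
    """Full-pipeline parameter recovery on the default 30-subject cohort.

    Returns the recovery correlations for beta modulation and burst
    probability modulation against the planted depths, the within-group
    cross-metric association, the connectivity/age fit, degree-slope
    group means and the per-frequency PSD-age correlations.
    """
    config = config or PipelineConfig(seed=seed)
    bundle = run_pipeline(config)
    truth, table = bundle["truth"], bundle["table"]
    d = np.array([b.modulation_depth for b in truth.bursts])
    out = {
        "r_betamod_depth": float(stats.pearsonr(d, table["beta_mod"])[0]),
        "r_deltap_depth": float(stats.pearsonr(d, table["delta_p"])[0]),
        "r_cross_metric": float(bundle["cross_metric"].r),
        "r2_connectivity_age": float(
            bundle["fits"].loc["global_connectivity", "r2"]
        ),
        "p_amplitude_age": float(bundle["fits"].loc["burst_amplitude", "p"]),
        "bundle": bundle,
    }
    df = bundle["degree_fits"]
    groups = [lbl.split("-")[1] for lbl in df.index]
    slopes = pd.Series(df["slope"].values, index=groups).groupby(level=0).mean()
    out["frontal_degree_slope"] = float(slopes["frontal"])
    out["occipital_degree_slope"] = float(slopes["occipital"])
    pa = bundle["psd_age"]
    for f in (3.0, 9.0, 37.0):
        i = int(np.argmin(np.abs(pa.index.values - f)))
        out[f"psd_age_r_{int(f)}hz"] = float(pa["r"].iloc[i])
        out[f"psd_age_flag_{int(f)}hz"] = bool(pa["flagged"].iloc[i])
    return out


def _source_level_burst_analysis(gt: syn.BurstGroundTruth, par: Paradigm,
                                 m50: float, seed: int, noise_sigma: float = 0.35):
    """Generator source + projection-level noise -> embed -> HMM -> burst
    metrics, at the source level (no sensor array), for replicate studies."""
    fs = 300.0
    dur = par.total_duration
    train = syn.simulate_burst_train(par, gt, dur, seed=seed)
    x = syn.synthesize_source(train, gt, fs, dur, onsets=par.onsets,
                              m50_amplitude=m50, seed=seed)
    rng = np.random.default_rng(seed + 999)
    x = x + rng.normal(size=x.size) * noise_sigma
    # epoch and resample as the pipeline does
    eps = np.stack([
        x[int(round((on - 0.5) * fs)) : int(round((on - 0.5) * fs)) + 1050]
        for on in par.onsets
    ])
    ve_rs = signal.resample_poly(eps, 1, 3, axis=-1)
    emb = bh.tde_embed(ve_rs.reshape(-1), 100.0, lags=5, target_fs=100.0)
    model = bh.fit_hmm(emb, K=3, n_restarts=2, seed=seed, max_iter=150)
    gam = bh.gamma_full(model.gamma, emb)
    binary = bh.binarize_states(gam)
    bt = bh.to_trials(binary, ve_rs.shape[0])
    k = bh.select_burst_state(bt, 100.0, -0.5)
    bp = bh.burst_probability(bt[:, :, k], 100.0, -0.5)
    freqs, psd = bh.state_spectra(emb.series, gam, 100.0)
    amp = bh.burst_amplitude(ve_rs.reshape(-1), binary[:, k].astype(bool), 100.0)
    psd_k = psd[k]
    if np.isfinite(psd_k).all():
        psd_k = psd_k / np.trapezoid(psd_k, freqs)
    return bp.delta_p, freqs, psd_k, amp


def deltap_depth_grid(depths=(0.0, 0.25, 0.5), n_seeds: int = 7, seed: int = 0) -> dict:
    """Median burst-probability modulation per planted depth through the
    full sensor-level pipeline, and the Spearman rho over the grid.

    Each depth gets ``n_seeds`` replicate subjects with fixed modulation
    depth (no age trend); the grid statistic is the per-depth median,
    which is robust to occasional burst-state mis-selections.
    """
    from .pipeline import analyse_subject

    cfg = PipelineConfig(seed=seed, compute_connectivity=False)
    grid_medians = []
    for j, d in enumerate(depths):
        trend = syn.TrendSpec(d_intercept=float(d), d_slope=0.0, d_sigma=0.0)
        recs, _ = syn.make_cohort(
            n_subjects=n_seeds, age_range=(10.0, 30.0), trend=trend,
            seed=seed + 100 * j, n_trials_per_finger=42,
        )
        vals = [analyse_subject(rec, cfg)["delta_p"] for rec in recs]
        grid_medians.append(float(np.median(vals)))
    rho = float(stats.spearmanr(depths, grid_medians).statistic)
    return {"depths": list(depths), "median_delta_p": grid_medians, "spearman": rho}


def replicate_burst_cohorts(n_seeds: int = 10, n_subjects: int = 10,
                            tpf: int = 10, seed: int = 0) -> dict:
    """Source-level replicate cohorts for the seed-fraction checks:
    alpha (9 Hz) stability and the burst-amplitude age null.

    Each replicate draws a fresh cohort with the default age trends
    (amplitude age-invariant, alpha fixed), runs the burst chain and fits
    the age regressions.
    """
    trend = syn.TrendSpec()
    par = Paradigm(n_trials_per_finger=tpf)
    ages = np.linspace(2.0, 34.0, n_subjects)
    alpha_flags, amp_ps = [], []
    for s in range(n_seeds):
        psds, amps = [], []
        freqs = None
        for i, age in enumerate(ages):
            rng = np.random.default_rng(seed + 1000 * s + i)
            d = float(np.clip(
                trend.d_intercept + trend.d_slope * age + rng.normal(0, trend.d_sigma),
                0.0, 0.95,
            ))
            tilt = float(trend.tilt_intercept + trend.tilt_slope * age
                         + rng.normal(0, trend.tilt_sigma))
            gt = syn.BurstGroundTruth(
                modulation_depth=d, spectral_tilt=tilt,
                alpha_peak_power=trend.alpha_peak_power,
                burst_amplitude=trend.burst_amplitude,
            )
            _, freqs, psd_k, amp = _source_level_burst_analysis(
                gt, par, trend.m50_amplitude, seed + 1000 * s + i
            )
            psds.append(psd_k)
            amps.append(amp)
        psds = np.asarray(psds)
        ok = np.isfinite(psds).all(axis=1) & np.isfinite(amps)
        pa = gs.psd_age_correlation(psds[ok], ages[ok], freqs)
        i9 = int(np.argmin(np.abs(pa.index.values - 9.0)))
        alpha_flags.append(bool(pa["flagged"].iloc[i9]))
        amp_ps.append(gs.pearson_fit(ages[ok], np.asarray(amps)[ok]).p)
    return {
        "alpha_unflagged_fraction": float(np.mean([not f for f in alpha_flags])),
        "amplitude_null_fraction": float(np.mean([p >= 0.01 for p in amp_ps])),
        "amplitude_ps": amp_ps,
    }


def degree_ordering_fraction(n_seeds: int = 10, n_subjects: int = 12,
                             duration: float = 60.0, seed: int = 0) -> float:
    """Fraction of replicate cohorts in which the fitted frontal degree
    slope exceeds the occipital one (region-time-course level)."""
    trend = syn.TrendSpec()
    parc = syn.make_parcellation(78)
    hits = 0
    for s in range(n_seeds):
        ages = np.linspace(2.0, 34.0, n_subjects)
        degrees = []
        for i, age in enumerate(ages):
            C = syn.target_aec_matrix(parc, age, trend)
            x = syn.network_sources(C, duration, 300.0, seed=seed + 997 * s + i)
            cm = conn.build_connectome(x, 300.0, parc)
            degrees.append(cm.degree)
        df = pd.DataFrame(degrees, columns=parc.labels)
        fits = gs.degree_age_slopes(df, ages)
        groups = [lbl.split("-")[1] for lbl in fits.index]
        slopes = pd.Series(fits["slope"].values, index=groups).groupby(level=0).mean()
        hits += bool(slopes["frontal"] > slopes["occipital"])
    return hits / n_seeds


# ---------------------------------------------------------- preprocessing

def preprocessing_checks(seed: int = 0) -> dict:
    """HFC nulling, the 84-trial variance-rejection example and the notch
    residual, recomputed from scratch."""
    rng = np.random.default_rng(seed)
    arr = syn.make_sensor_array(16, seed=1)
    geom = channel_geometry(arr)
    S = geom.orientations
    field = rng.normal(size=(3, 5000))
    rec = Recording(data=S @ field, fs=300.0, geometry=geom,
                    paradigm=Paradigm(n_trials_per_finger=1))
    out = pp.homogeneous_field_correction(rec)
    hfc_residual = float(np.abs(out.data).max() / np.abs(rec.data).max())

    from .containers import EpochSet

    v = np.array([1.0] * 83 + [5.0])
    data = rng.normal(size=(84, 4, 200)) * np.sqrt(v)[:, None, None]
    ep = EpochSet(data=data, fs=300.0, window=(-0.5, 3.0), fingers=["D2"] * 84,
                  trial_keep=np.ones(84, bool), onsets=np.arange(84) * 3.5)
    ep = pp.reject_high_variance_trials(ep)
    rejected = sorted(int(i) for i in np.flatnonzero(~ep.trial_keep))

    fs = 600.0
    t = np.arange(int(fs * 20)) / fs
    tone = np.tile(np.sin(2 * np.pi * 50 * t), (geom.n_channels, 1))
    rec2 = Recording(data=tone, fs=fs, geometry=geom,
                     paradigm=Paradigm(n_trials_per_finger=2))
    filtered, _ = pp.apply_filters(rec2)
    notch_residual = float(np.abs(filtered.data[0, 2000:-2000]).max())
    return {
        "hfc_residual": hfc_residual,
        "rejected_trials": rejected,
        "notch_residual": notch_residual,
    }
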