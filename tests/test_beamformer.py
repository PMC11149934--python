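"""Covariance regularisation, LCMV weights (vs a constrained-QP oracle),
pseudo-T maps and virtual electrodes."""

import numpy as np
import pytest
from scipy import signal

from opmbeta import beamformer as bf
from opmbeta.containers import EpochSet, HeadModel, Paradigm, channel_geometry
from opmbeta.forward import compute_leadfield, make_grid, tangential_basis
from opmbeta.synthetic import (
    NoiseSpec,
    PlantedSource,
    make_sensor_array,
    project_to_sensors,
    tangential_moment,
)
from opmbeta.preprocess import epoch


class TestCovariance:
    def test_regularisation_shifts_eigenvalues(self):
        C = np.diag([10.0, 1.0])
        model = bf.CovarianceModel(C=C, mu=0.05)
        assert np.allclose(np.linalg.eigvalsh(model.C_reg), [1.5, 10.5])

    def test_identity_becomes_1p05_identity(self):
        model = bf.CovarianceModel(C=np.eye(4), mu=0.05)
        assert np.allclose(model.C_reg, 1.05 * np.eye(4))

    def test_white_noise_epochs_give_identity(self, rng):
        n_tr, n_ch, n_s = 20, 6, 2000
        ep = EpochSet(data=rng.normal(size=(n_tr, n_ch, n_s)), fs=300.0,
                      window=(-0.5, 3.0), fingers=["D2"] * n_tr,
                      trial_keep=np.ones(n_tr, bool), onsets=np.arange(n_tr) * 3.5)
        cov = bf.regularized_covariance(ep)
        assert np.allclose(cov.C, np.eye(n_ch), atol=0.02)


def _qp_oracle(L3, eta, C_reg):
    """Constrained minimisation of w^T C w s.t. w^T (L eta) = 1, by KKT."""
    g = L3 @ eta
    n = len(g)
    kkt = np.zeros((n + 1, n + 1))
    kkt[:n, :n] = 2 * C_reg
    kkt[:n, n] = -g
    kkt[n, :n] = g
    rhs = np.zeros(n + 1)
    rhs[n] = 1.0
    sol = np.linalg.solve(kkt, rhs)
    return sol[:n]


class TestLCMV:
    def _instance(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(6, 6))
        C = A @ A.T + 6 * np.eye(6)
        L3 = rng.normal(size=(6, 3))
        point = np.array([-0.03, 0.01, 0.04])
        return L3, bf.CovarianceModel(C=C, mu=0.05), point

    @pytest.mark.parametrize("seed", range(5))
    def test_weights_match_qp_oracle(self, seed):
        L3, cov, point = self._instance(seed)
        vw = bf.lcmv_weights(L3, cov, point=point)
        w_oracle = _qp_oracle(L3, vw.eta, cov.C_reg)
        assert np.allclose(vw.w, w_oracle, atol=1e-8 * np.abs(w_oracle).max())

    @pytest.mark.parametrize("seed", range(5))
    def test_unit_gain(self, seed):
        L3, cov, point = self._instance(seed)
        vw = bf.lcmv_weights(L3, cov, point=point)
        assert float(vw.w @ (L3 @ vw.eta)) == pytest.approx(1.0, abs=1e-8)

    def test_identity_covariance_closed_form(self):
        rng = np.random.default_rng(3)
        L3 = rng.normal(size=(6, 3))
        cov = bf.CovarianceModel(C=np.eye(6), mu=0.0)
        point = np.array([0.0, 0.0, 0.05])
        vw = bf.lcmv_weights(L3, cov, point=point)
        g = L3 @ vw.eta
        assert np.allclose(vw.w, g / (g @ g), atol=1e-10)

    def test_orientation_maximises_output_power(self):
        L3, cov, point = self._instance(7)
        vw = bf.lcmv_weights(L3, cov, point=point)
        basis = tangential_basis(point)[0]

        def out_power(eta):
            w = _qp_oracle(L3, eta, cov.C_reg)
            return w @ cov.C_reg @ w

        best = out_power(vw.eta)
        sweep = max(
            out_power(basis @ np.array([np.cos(t), np.sin(t)]))
            for t in np.linspace(0, np.pi, 181)
        )
        assert best >= sweep * (1 - 1e-6)

    def test_origin_voxel_unlocalizable(self):
        cov = bf.CovarianceModel(C=np.eye(6), mu=0.05)
        vw = bf.lcmv_weights(np.zeros((6, 3)), cov, point=np.zeros(3))
        assert not vw.ok


def _suppressed_beta_recording(seed, snr=1.0, n_trials_per_finger=20):
    """Continuous beta source whose power drops x0.25 in active windows."""
    head = HeadModel()
    arr = make_sensor_array(64, seed=0)
    fs = 300.0
    par = Paradigm(n_trials_per_finger=n_trials_per_finger)
    n = int(par.total_duration * fs)
    rng = np.random.default_rng(seed)
    sos = signal.butter(4, [13, 30], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.normal(size=n))
    x /= x.std()
    t = np.arange(n) / fs
    for on in par.onsets:
        x[(t >= on + 0.3) & (t < on + 0.8)] *= 0.5
    dip = np.array([-0.045, 0.005, 0.040])
    src = PlantedSource(dip, tangential_moment(dip, head), x)
    from opmbeta.synthetic import source_sensor_rms

    rms = source_sensor_rms(src, arr, head)
    noise = NoiseSpec(white_sigma=rms / snr, line_amp=1.0, drift_sigma=5.0)
    rec, _ = project_to_sensors([src], arr, head, fs, noise=noise,
                                paradigm=par, seed=seed + 100)
    return rec, dip, head


class TestPseudoT:
    def test_formula_value(self):
        # P_a = 0.5, P_c = 1.5 -> T = -0.5 by the normalised contrast
        assert (0.5 - 1.5) / (0.5 + 1.5) == pytest.approx(-0.5)

    def test_identical_windows_give_near_zero_map(self, head, rng):
        arr = make_sensor_array(8, seed=0)
        par = Paradigm(n_trials_per_finger=500)  # statistics need large n
        fs = 300.0
        data = rng.normal(size=(arr.n_channels, int(par.total_duration * fs)))
        from opmbeta.containers import Recording

        rec = Recording(data=data, fs=fs, geometry=channel_geometry(arr),
                        paradigm=par)
        ep = epoch(rec)
        grid = make_grid(head, 0.04)
        lf = compute_leadfield(grid.points, rec.geometry, head)
        tmap = bf.pseudo_t_map(ep, lf)
        assert np.nanmax(np.abs(tmap.t)) < 0.05

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_suppression_localises_source(self, seed):
        from opmbeta.preprocess import preprocess_recording

        rec, dip, head = _suppressed_beta_recording(seed)
        clean, ep, _ = preprocess_recording(rec)
        grid = make_grid(head, 0.004, center=dip + np.array([0.002, -0.003, 0.001]),
                         half_extent=0.016)
        lf = compute_leadfield(grid.points, clean.geometry, head)
        tmap = bf.pseudo_t_map(ep, lf)
        err = np.linalg.norm(tmap.peak_point - dip)
        assert err <= 2 * grid.spacing
        assert tmap.t[tmap.peak_index] < 0  # suppression: active < control


class TestVirtualElectrode:
    def test_noiseless_source_reconstructed(self, head, rng):
        arr = make_sensor_array(32, seed=1)
        par = Paradigm(n_trials_per_finger=4)
        fs = 300.0
        n = int(par.total_duration * fs)
        sos = signal.butter(4, [5, 40], btype="bandpass", fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, rng.normal(size=n))
        dip = np.array([-0.04, 0.0, 0.03])
        src = PlantedSource(dip, tangential_moment(dip, head), x)
        rec, _ = project_to_sensors([src], arr, head, fs, paradigm=par)
        ep = epoch(rec)
        cov = bf.regularized_covariance(ep)
        lf = compute_leadfield(dip[None, :], rec.geometry, head)
        ve = bf.virtual_electrode(ep, lf.L[0], dip, cov, origin=head.origin)
        i0 = int(round((par.onsets[0] - 0.5) * fs))
        src_cat = np.concatenate(
            [x[int(round((on - 0.5) * fs)):int(round((on - 0.5) * fs)) + ep.n_samples]
             for on in ep.onsets]
        )
        r = np.corrcoef(ve.concatenated, src_cat)[0, 1]
        assert abs(r) > 0.99

    def test_zero_data_zero_ve_and_linearity(self, head, rng):
        arr = make_sensor_array(16, seed=2)
        par = Paradigm(n_trials_per_finger=2)
        fs = 300.0
        data = rng.normal(size=(arr.n_channels, int(par.total_duration * fs)))
        from opmbeta.containers import Recording

        geom = channel_geometry(arr)
        rec = Recording(data=data, fs=fs, geometry=geom, paradigm=par)
        ep = epoch(rec)
        cov = bf.regularized_covariance(ep)
        dip = np.array([-0.04, 0.0, 0.03])
        lf = compute_leadfield(dip[None, :], geom, head)
        ve = bf.virtual_electrode(ep, lf.L[0], dip, cov, origin=head.origin)
        ep2 = EpochSet(data=2 * ep.data, fs=fs, window=ep.window, fingers=ep.fingers,
                       trial_keep=ep.trial_keep, onsets=ep.onsets)
        ve2 = bf.virtual_electrode(ep2, lf.L[0], dip, cov, origin=head.origin)
        assert np.allclose(ve2.epochs, 2 * ve.epochs, rtol=1e-10)
        ep0 = EpochSet(data=0 * ep.data, fs=fs, window=ep.window, fingers=ep.fingers,
                       trial_keep=ep.trial_keep, onsets=ep.onsets)
        ve0 = bf.virtual_electrode(ep0, lf.L[0], dip, cov, origin=head.origin)
        assert np.all(ve0.epochs == 0.0)
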