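"""Synthetic cohort generator: geometry, burst statistics, source spectra,
sensor projection and planted cohort trends."""

import numpy as np
import pytest
from scipy import signal

from opmbeta.containers import GeometryError, HeadModel, Paradigm, channel_geometry
from opmbeta.synthetic import (
    BurstGroundTruth,
    NoiseSpec,
    PlantedSource,
    TrendSpec,
    make_cohort,
    make_parcellation,
    make_sensor_array,
    network_sources,
    project_to_sensors,
    simulate_burst_train,
    synthesize_source,
    tangential_moment,
    target_aec_matrix,
)


class TestSensorArray:
    def test_64_sensors_give_192_channels(self):
        arr = make_sensor_array(64)
        assert arr.n_channels == 192

    def test_triads_orthonormal(self):
        arr = make_sensor_array(16, seed=3)
        gram = np.einsum("nij,nkj->nik", arr.orientations, arr.orientations)
        assert np.max(np.abs(gram - np.eye(3))) < 1e-10

    def test_spherical_placement(self):
        arr = make_sensor_array(6, head_radius=0.08, offset=0.02)
        assert np.allclose(np.linalg.norm(arr.positions, axis=1), 0.10)

    @pytest.mark.parametrize("kwargs", [
        {"head_radius": -0.1}, {"offset": 0.0}, {"n_sensors": 3},
    ])
    def test_invalid_geometry(self, kwargs):
        with pytest.raises(GeometryError):
            make_sensor_array(**{"n_sensors": 8, **kwargs})


class TestParadigm:
    def test_task_duration_42_trials_two_fingers(self):
        par = Paradigm()
        assert par.n_trials == 84
        assert par.task_duration == pytest.approx(294.0)

    def test_onsets_increasing_and_alternating(self):
        par = Paradigm(n_trials_per_finger=4)
        assert np.all(np.diff(par.onsets) > 0)
        assert par.trial_fingers[:4] == ["D2", "D5", "D2", "D5"]


class TestBurstTrain:
    def test_stationary_rate_recovery(self, paradigm):
        gt = BurstGroundTruth(modulation_depth=0.0)
        train = simulate_burst_train(paradigm, gt, 500.0, seed=7)
        rate = len(train) / 500.0
        se = np.sqrt(gt.baseline_rate * 500.0) / 500.0
        assert abs(rate - gt.baseline_rate) < 3 * se

    def test_full_suppression_empties_stim_windows(self, paradigm):
        gt = BurstGroundTruth(modulation_depth=1.0)
        train = simulate_burst_train(paradigm, gt, paradigm.total_duration, seed=2)
        onsets = paradigm.onsets
        lo, hi = gt.suppression_window
        inside = [
            t for t, _ in train if np.any((onsets + lo <= t) & (t < onsets + hi))
        ]
        assert inside == []

    def test_half_suppression_rate_ratio(self):
        # low occupancy (rate x duration << 1) so the non-overlap dead
        # time does not distort the onset-rate ratio
        par = Paradigm(n_trials_per_finger=400)
        gt = BurstGroundTruth(modulation_depth=0.5, baseline_rate=0.5,
                              burst_duration_mean=0.05)
        train = simulate_burst_train(par, gt, par.total_duration, seed=11)
        onsets = np.asarray(par.onsets)
        lo, hi = gt.suppression_window
        n_stim = n_rest = 0
        for t, _ in train:
            if np.any((onsets + lo <= t) & (t < onsets + hi)):
                n_stim += 1
            else:
                n_rest += 1
        stim_time = len(onsets) * (hi - lo)
        rest_time = par.total_duration - stim_time
        ratio = (n_stim / stim_time) / (n_rest / rest_time)
        # binomial noise on ~1000 events: 3 sigma around the planted 0.5
        assert 0.4 < ratio < 0.6

    def test_bursts_do_not_overlap(self, paradigm):
        gt = BurstGroundTruth()
        train = simulate_burst_train(paradigm, gt, 200.0, seed=1)
        ends = np.array([t + d for t, d in train])
        starts = np.array([t for t, _ in train])
        assert np.all(starts[1:] >= ends[:-1] - 1e-12)

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            BurstGroundTruth(modulation_depth=1.2)


def _multitaper_psd(x, fs, nw=4, k=7):
    freqs, psd = signal.welch(x, fs=fs, nperseg=int(2 * fs))
    return freqs, psd


class TestSourceModel:
    def test_degenerate_floor_only(self):
        gt = BurstGroundTruth(burst_amplitude=0.0, alpha_bg_amplitude=0.0)
        x = synthesize_source([], gt, 300.0, 50.0, seed=5)
        assert x.var() == pytest.approx(gt.floor_sigma**2, rel=0.05)

    def test_spectral_tilt_orders_low_and_high_frequencies(self, paradigm):
        fs, dur = 300.0, 120.0
        psds = {}
        for tilt in (1.4, 0.6):
            gt = BurstGroundTruth(spectral_tilt=tilt, alpha_bg_amplitude=0.0,
                                  floor_sigma=0.01)
            train = simulate_burst_train(paradigm, gt, dur, seed=3)
            x = synthesize_source(train, gt, fs, dur, seed=3)
            on = np.zeros(int(dur * fs), bool)
            for t, d in train:
                on[int(t * fs) : int((t + d) * fs)] = True
            freqs, psd = signal.welch(x[on], fs=fs, nperseg=512)
            psd /= psd.sum()
            psds[tilt] = (psd[np.argmin(np.abs(freqs - 3))],
                          psd[np.argmin(np.abs(freqs - 37))])
        assert psds[1.4][0] > psds[0.6][0]   # young: more power at 3 Hz
        assert psds[1.4][1] < psds[0.6][1]   # old: more power at 37 Hz

    def test_alpha_peak_independent_of_tilt(self, paradigm):
        """9 Hz in-burst power stays put while the tilt varies (stable alpha)."""
        fs, dur = 300.0, 100.0
        ratios = []
        for i, tilt in enumerate(np.linspace(1.4, 0.6, 10)):
            gt = BurstGroundTruth(spectral_tilt=tilt, alpha_bg_amplitude=0.0)
            train = simulate_burst_train(paradigm, gt, dur, seed=20 + i)
            x = synthesize_source(train, gt, fs, dur, seed=20 + i)
            freqs, psd = signal.welch(x, fs=fs, nperseg=1024)
            band = psd[(freqs >= 8.2) & (freqs <= 9.8)].mean()
            flank = psd[(freqs >= 11.5) & (freqs <= 12.5)].mean()
            ratios.append(band / flank)
        assert np.all(np.array(ratios) > 1.2)  # alpha bump present throughout

    def test_m50_bump_is_planted(self):
        par = Paradigm(n_trials_per_finger=5)
        gt = BurstGroundTruth(burst_amplitude=0.0, alpha_bg_amplitude=0.0,
                              floor_sigma=1e-6)
        x = synthesize_source([], gt, 300.0, par.total_duration,
                              onsets=par.onsets, m50_amplitude=2.0, seed=0)
        i = int(round((par.onsets[0] + 0.05) * 300))
        assert x[i] == pytest.approx(2.0, rel=0.01)


class TestSensorProjection:
    def test_zero_sources_zero_noise(self, small_array, head):
        par = Paradigm(n_trials_per_finger=2)
        rec, _ = project_to_sensors([], small_array, head, 300.0, paradigm=par)
        assert np.all(rec.data == 0.0)

    def test_homogeneous_drift_lies_in_orientation_span(self, small_array, head):
        par = Paradigm(n_trials_per_finger=2)
        noise = NoiseSpec(white_sigma=1.0, line_amp=0.0, drift_sigma=4.0,
                          n_flat_channels=0, n_noisy_channels=0, n_bad_trials=0)
        rec, _ = project_to_sensors([], small_array, head, 300.0, noise=noise,
                                    paradigm=par, seed=4)
        S = rec.geometry.orientations
        # remove the white part is impossible; instead check that the drift
        # subspace projection removes most of the low-frequency variance
        proj = S @ np.linalg.solve(S.T @ S, S.T @ rec.data)
        resid = rec.data - proj
        sos = signal.butter(2, 1.0, btype="lowpass", fs=300.0, output="sos")
        lo_before = signal.sosfiltfilt(sos, rec.data, axis=1).var()
        lo_after = signal.sosfiltfilt(sos, resid, axis=1).var()
        assert lo_after < 0.2 * lo_before

    def test_projection_linearity(self, small_array, head, rng):
        par = Paradigm(n_trials_per_finger=2)
        pos = np.array([-0.04, 0.01, 0.03])
        x = rng.normal(size=int(par.total_duration * 300))
        mk = lambda s: [PlantedSource(pos, tangential_moment(pos, head), s)]
        rec1, _ = project_to_sensors(mk(x), small_array, head, 300.0, paradigm=par)
        rec3, _ = project_to_sensors(mk(3 * x), small_array, head, 300.0, paradigm=par)
        assert np.allclose(rec3.data, 3 * rec1.data, rtol=1e-10)

    def test_variance_bookkeeping(self, small_array, head, rng):
        """Sensor variance equals the analytic sum of parts within 2%."""
        par = Paradigm(n_trials_per_finger=3)
        T = int(par.total_duration * 300)
        pos = np.array([-0.04, 0.01, 0.03])
        x = rng.normal(size=T)
        src = PlantedSource(pos, tangential_moment(pos, head), x)
        noise = NoiseSpec(white_sigma=0.5, line_amp=0.0, drift_sigma=0.0,
                          n_flat_channels=0, n_noisy_channels=0, n_bad_trials=0)
        rec, _ = project_to_sensors([src], small_array, head, 300.0,
                                    noise=noise, paradigm=par, seed=9)
        clean, _ = project_to_sensors([src], small_array, head, 300.0, paradigm=par)
        expected = clean.data.var(axis=1).mean() + 0.25
        assert rec.data.var(axis=1).mean() == pytest.approx(expected, rel=0.02)


class TestCohort:
    def test_planted_depth_increases_with_age(self, fixture_cohort):
        recs, truth = fixture_cohort
        d = [b.modulation_depth for b in truth.bursts]
        assert d[-1] > d[0]
        assert np.all((truth.ages >= 2.0) & (truth.ages <= 34.0))

    def test_flat_trends_remove_age_dependence(self):
        trend = TrendSpec(d_slope=0.0, d_sigma=0.0, tilt_slope=0.0, tilt_sigma=0.0)
        recs, truth = make_cohort(n_subjects=3, seed=0, trend=trend,
                                  n_trials_per_finger=2, n_sensors=8,
                                  n_regions=6, with_network=False)
        d = [b.modulation_depth for b in truth.bursts]
        assert len(set(np.round(d, 12))) == 1

    def test_frontal_degree_target_slope_exceeds_occipital(self):
        trend = TrendSpec()
        assert trend.degree_frontal[1] == pytest.approx(0.27)
        assert trend.degree_occipital[1] == pytest.approx(0.10)
        parc = make_parcellation(30)
        lo = target_aec_matrix(parc, 5.0, trend)
        hi = target_aec_matrix(parc, 30.0, trend)
        front = parc.groups == "frontal"
        occ = parc.groups == "occipital"
        gain_front = hi[np.ix_(front, front)].mean() - lo[np.ix_(front, front)].mean()
        gain_occ = hi[np.ix_(occ, occ)].mean() - lo[np.ix_(occ, occ)].mean()
        assert gain_front > gain_occ

    def test_parcellation_tags_and_uniqueness(self):
        parc = make_parcellation(78)
        assert parc.n_regions == 78
        assert set(np.unique(parc.groups)) == {"frontal", "occipital", "other"}
        assert len(set(parc.labels)) == 78


class TestNetworkSources:
    def test_planted_envelope_correlation_is_recovered(self):
        from opmbeta.connectivity import aec

        C = np.array([[1.0, 0.6], [0.6, 1.0]])
        x = network_sources(C, 120.0, 300.0, seed=8)
        val = aec(x[0], x[1], 300.0)
        assert val == pytest.approx(0.6, abs=0.1)

    def test_independent_regions_uncorrelated(self):
        # smooth (~1 Hz) envelopes over 300 s give ~600 effective samples;
        # the bound is about 3 standard errors
        from opmbeta.connectivity import aec

        C = np.eye(2)
        x = network_sources(C, 300.0, 300.0, seed=9)
        assert abs(aec(x[0], x[1], 300.0)) < 0.125
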