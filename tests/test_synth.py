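import numpy as np
import pytest

from segepi import encoding, metrics, recon, synth
from segepi.synth import (
    NoiseSpec,
    PhantomSpec,
    PhaseModel,
    group_mean_times,
    harmonic_basis,
    make_coil_maps,
    make_phantom,
    phase_map_at,
    simulate_pair,
    simulate_timeseries,
    snr_calibrate,
)


class TestPhantom:
    def test_default_max_magnitude_one(self, phantom48):
        assert np.abs(phantom48).max() == pytest.approx(1.0)
        assert phantom48.shape == (48, 48)

    def test_zero_phase_spec_is_real(self, phantom48):
        assert np.all(phantom48.imag == 0)

    def test_deterministic(self):
        a = make_phantom(PhantomSpec())
        b = make_phantom(PhantomSpec())
        np.testing.assert_array_equal(a, b)

    def test_baseline_phase_applied(self):
        ph = make_phantom(PhantomSpec(phase_coeffs=(0.5, 0.0, 0.0, 0.0)))
        sup = np.abs(ph) > 0.1
        np.testing.assert_allclose(np.angle(ph[sup]), 0.5, atol=1e-12)

    def test_support_strictly_inside(self, phantom48):
        assert np.abs(phantom48[0]).max() == 0
        assert np.abs(phantom48[-1]).max() == 0
        assert np.abs(phantom48[:, 0]).max() == 0
        assert np.abs(phantom48[:, -1]).max() == 0

    def test_smooth_blobs_variant(self):
        ph = make_phantom(PhantomSpec(structure="smooth_blobs"))
        assert np.abs(ph).max() == pytest.approx(1.0)

    def test_bad_structure(self):
        with pytest.raises(ValueError):
            PhantomSpec(structure="brain")


class TestCoilMaps:
    def test_single_coil_constant_magnitude(self):
        maps = make_coil_maps(1, (16, 16), seed=0)
        np.testing.assert_allclose(np.abs(maps[0]), 1.0, atol=1e-12)

    def test_rss_unity(self, maps8):
        rss = np.sqrt((np.abs(maps8) ** 2).sum(axis=0))
        assert rss.min() > 0.99
        assert rss.max() <= 1.0 + 1e-12

    def test_deterministic_under_seed(self):
        a = make_coil_maps(4, (12, 12), seed=7)
        b = make_coil_maps(4, (12, 12), seed=7)
        np.testing.assert_array_equal(a, b)
        c = make_coil_maps(4, (12, 12), seed=8)
        assert not np.allclose(a, c)

    def test_rejects_zero_coils(self):
        with pytest.raises(ValueError):
            make_coil_maps(0, (8, 8))


class TestPhaseModel:
    def test_zero_amplitudes_zero_map(self):
        model = PhaseModel()
        np.testing.assert_array_equal(phase_map_at(1.23, model, (8, 8)), 0.0)

    def test_constant_term_uniform(self):
        model = PhaseModel(amplitudes=(0.7, 0, 0, 0, 0, 0))
        t = 0.9
        m = phase_map_at(t, model, (6, 6))
        np.testing.assert_allclose(m, 0.7 * model.trace(t), atol=1e-14)

    def test_basis_closure_refit(self, rng):
        """Any generated map is exactly in the span of the 6 basis maps."""
        amp = tuple(rng.uniform(-1, 1, 6))
        model = PhaseModel(amplitudes=amp)
        m = phase_map_at(0.37, model, (20, 24))
        basis = harmonic_basis((20, 24)).reshape(6, -1).T
        coef, *_ = np.linalg.lstsq(basis, m.ravel(), rcond=None)
        resid = np.linalg.norm(basis @ coef - m.ravel())
        assert resid < 1e-10

    def test_trace_components(self):
        model = PhaseModel(freq_hz=0.5, drift_per_s=0.1)
        assert model.trace(0.0) == pytest.approx(0.0)
        assert model.trace(0.5) == pytest.approx(np.sin(np.pi * 0.5) + 0.05)

    def test_jitter_deterministic_and_zero_mean_scale(self):
        m1 = PhaseModel(jitter_std=0.3, jitter_seed=5)
        m2 = PhaseModel(jitter_std=0.3, jitter_seed=5)
        t = np.linspace(0, 200, 4001)
        np.testing.assert_array_equal(m1.trace(t), m2.trace(t))
        jitter = m1.trace(t) - PhaseModel().trace(t)
        assert np.std(jitter) == pytest.approx(0.3, rel=0.25)

    def test_amplitude_length_checked(self):
        with pytest.raises(ValueError):
            PhaseModel(amplitudes=(1.0, 2.0))


class TestSimulate:
    def test_noiseless_zero_phase_full_sampling_recovers(self, phantom48, maps8, std_schedule):
        vols = simulate_timeseries(phantom48, maps8, std_schedule, PhaseModel(), NoiseSpec(), 1)
        k = encoding.coil_combine_kspace(vols[0].y.sum(axis=0), maps8)
        img = encoding.ifft2c(k)
        err = np.linalg.norm(img - phantom48) / np.linalg.norm(phantom48)
        assert err < 1e-8

    def test_grid_mismatch(self, maps8, std_schedule):
        with pytest.raises(ValueError, match="grid"):
            simulate_timeseries(np.zeros((8, 8)), maps8, std_schedule, PhaseModel(), NoiseSpec(), 1)

    def test_data_zero_off_mask(self, phantom48, maps8, seg_schedule_g2):
        vols = simulate_timeseries(
            phantom48, maps8, seg_schedule_g2, PhaseModel(), NoiseSpec(sigma=0.01), 1
        )
        assert vols[0].check_off_mask_zero()

    def test_paired_reference_identical_noise(self, phantom48, maps8, seg_schedule_g2, resp_phase_model):
        noise = NoiseSpec(sigma=0.005, seed=11)
        corrupted, reference = simulate_pair(
            phantom48, maps8, seg_schedule_g2, resp_phase_model, noise, n_volumes=2
        )
        # difference between the pairs is exactly the phase modulation of the
        # signal: subtracting the noiseless signals must cancel the noise
        sig_c = simulate_timeseries(phantom48, maps8, seg_schedule_g2, resp_phase_model, NoiseSpec(), 2)
        sig_r = simulate_timeseries(phantom48, maps8, seg_schedule_g2, resp_phase_model.zeroed(), NoiseSpec(), 2)
        for t in range(2):
            noise_c = corrupted[t].y - sig_c[t].y
            noise_r = reference[t].y - sig_r[t].y
            np.testing.assert_allclose(noise_c, noise_r, atol=1e-12)

    def test_continuous_time_across_volumes(self, phantom48, maps8, std_schedule):
        model = PhaseModel(amplitudes=(0.3, 0, 0, 0, 0, 0), freq_hz=0.03, shot_tr=0.05)
        two = simulate_timeseries(phantom48, maps8, std_schedule, model, NoiseSpec(), 2)
        second = simulate_timeseries(
            phantom48, maps8, std_schedule, model, NoiseSpec(), 1, start_volume=1
        )
        np.testing.assert_allclose(two[1].y, second[0].y, atol=1e-12)
        assert not np.allclose(two[0].y, two[1].y)

    def test_ghosting_energy_with_respiration(self, phantom48, maps8, std_schedule, resp_phase_model):
        """Phase-corrupted shot-combined recon ghosts along kz: background
        energy well above the zero-phase case."""
        def background_energy(model):
            vols = simulate_timeseries(phantom48, maps8, std_schedule, model, NoiseSpec(), 1)
            img = recon.sense_baseline(vols[0].y.sum(axis=0), maps8, vols[0].masks.any(axis=0))
            bg = ~metrics.support_mask(np.abs(phantom48), 0.02)
            return float((np.abs(img)[bg] ** 2).sum())

        corrupted = background_energy(resp_phase_model)
        clean = background_energy(resp_phase_model.zeroed())
        assert corrupted > 5 * clean


class TestSnrCalibrate:
    def test_doubling_target_halves_sigma(self, phantom48):
        a = snr_calibrate(50.0, phantom48)
        b = snr_calibrate(100.0, phantom48)
        assert a.sigma == pytest.approx(2 * b.sigma)

    def test_zero_sigma_allowed_semantics(self):
        assert NoiseSpec(sigma=0.0).sigma == 0.0
        with pytest.raises(ValueError):
            snr_calibrate(0.0, np.ones((4, 4)))

    @pytest.mark.parametrize("target", [97.0, 43.0])
    def test_measured_snr_matches_target(self, phantom48, maps8, std_schedule, target):
        """Monte-Carlo over 20 seeds: measured support SNR of the direct
        recon within 5% of the calibration target."""
        sup = metrics.support_mask(np.abs(phantom48), 0.1)
        bg = ~metrics.support_mask(np.abs(phantom48), 0.02)
        measured = []
        for seed in range(20):
            noise = snr_calibrate(target, phantom48, seed=seed)
            vols = simulate_timeseries(
                phantom48, maps8, std_schedule, PhaseModel(), noise, 1
            )
            img = encoding.ifft2c(
                encoding.coil_combine_kspace(vols[0].y.sum(axis=0), maps8)
            )
            noise_std = np.sqrt(
                np.var(img.real[bg]) + np.var(img.imag[bg])
            )
            measured.append(np.abs(img)[sup].mean() / noise_std)
        assert np.mean(measured) == pytest.approx(target, rel=0.05)


class TestCoherencePremise:
    def test_within_group_spread_small_vs_across_volume(self, phantom48, seg_schedule_g2):
        """With shot TR << respiratory period, phase maps within one shot
        group spread far less than across the whole series."""
        model = PhaseModel(
            amplitudes=(0.24, 0.2, 0.16, 0.08, 0.08, 0.12),
            freq_hz=0.25,
            shot_tr=0.008,
        )
        assert model.shot_tr <= 0.1 / model.freq_hz
        grid = (48, 48)
        n_shots = len(seg_schedule_g2.shots)

        def rms(m):
            return np.sqrt((m**2).mean())

        # max pairwise RMS within one group of volume 0
        within = 0.0
        for g in range(seg_schedule_g2.n_groups):
            shots = seg_schedule_g2.shots_in_group(g)
            maps_g = [
                phase_map_at(synth.shot_time(s.timestamp, model, 0, n_shots), model, grid)
                for s in shots
            ]
            for a in range(len(maps_g)):
                for b in range(a + 1, len(maps_g)):
                    within = max(within, rms(maps_g[a] - maps_g[b]))
        # across-volume spread: max pairwise RMS between volume-start maps
        vols = [
            phase_map_at(synth.shot_time(0, model, v, n_shots), model, grid)
            for v in range(40)
        ]
        across = max(
            rms(vols[a] - vols[b]) for a in range(0, 40, 3) for b in range(a + 1, 40, 3)
        )
        assert within <= 0.2 * across

    def test_group_mean_times_ordered(self, seg_schedule_g2):
        model = PhaseModel(shot_tr=0.01)
        times = group_mean_times(seg_schedule_g2, model)
        assert times.shape == (2,)
        assert times[1] > times[0]
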