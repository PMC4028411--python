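"""Generator contracts: planted effects match requested parameters."""

import numpy as np
import pytest

from thetacoupling import SimConfig, plv, simulate_coupled_phases, simulate_pac_source, simulate_subject
from thetacoupling.synth import bessel_ratio, make_source_model, null_config

from conftest import small_config


class TestCoupledPhases:
    def test_rigid_lock_gives_unit_plv(self, rng):
        a, b = simulate_coupled_phases(1e6, 0.0, 5000, rng)
        assert plv(a, b) == pytest.approx(1.0, abs=1e-3)

    def test_zero_kappa_gives_uniform_null(self, rng):
        a, b = simulate_coupled_phases(0.0, 0.0, 100_000, rng)
        # null PLV scale for n iid uniform differences is ~ 1/sqrt(n)
        assert plv(a, b) < 0.02

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0, 4.0])
    def test_sample_plv_matches_bessel_ratio(self, kappa, rng):
        # oracle: mean resultant of von Mises(kappa) = I1(kappa)/I0(kappa)
        n = 100_000
        a, b = simulate_coupled_phases(kappa, 0.7, n, rng)
        r = float(bessel_ratio(kappa))
        mc_se = np.sqrt((1 - r**2) / n) + 1e-4
        assert plv(a, b) == pytest.approx(r, abs=3 * mc_se)

    def test_outputs_are_wrapped(self, rng):
        a, b = simulate_coupled_phases(2.0, 1.0, 1000, rng)
        for p in (a, b):
            assert p.max() <= np.pi and p.min() > -np.pi

    def test_negative_kappa_rejected(self, rng):
        with pytest.raises(ValueError, match="kappa"):
            simulate_coupled_phases(-1.0, 0.0, 100, rng)


class TestPacSource:
    def test_depth_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError, match="depth"):
            simulate_pac_source(6, 75, 1.5, 1000, 480.0, rng)

    def test_carrier_above_nyquist_rejected(self, rng):
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_pac_source(6, 300, 0.5, 1000, 480.0, rng)

    @pytest.mark.parametrize("m", [0.2, 0.5, 0.9])
    def test_planted_modulation_depth_recoverable(self, m, rng):
        # noiseless envelope is amplitude * (1 + m cos phi): regressing the
        # rectified series' envelope on cos(phi) recovers m
        s, ph = simulate_pac_source(6, 75, m, 50_000, 480.0, rng, noise_sd=0.0)
        env_proxy = np.abs(s) * np.pi / 2  # E|cos| = 2/pi
        x = np.cos(ph)
        b = np.cov(env_proxy, x)[0, 1] / np.var(x)
        a = env_proxy.mean()
        assert b / a == pytest.approx(m, abs=0.05)


class TestSimulateSubject:
    def test_same_seed_is_bit_reproducible(self):
        cfg = small_config(rng_seed=3)
        r1 = simulate_subject(cfg, 0)
        r2 = simulate_subject(cfg, 0)
        assert np.array_equal(r1.epochs.data, r2.epochs.data)
        assert r1.truth.seed_voxel == r2.truth.seed_voxel
        assert np.array_equal(r1.truth.artifact_variance, r2.truth.artifact_variance)

    def test_different_subjects_differ(self):
        cfg = small_config(rng_seed=3)
        r1 = simulate_subject(cfg, 0)
        r2 = simulate_subject(cfg, 1)
        assert not np.array_equal(r1.epochs.data, r2.epochs.data)

    def test_shapes_and_ground_truth_recording(self):
        cfg = small_config()
        rec = simulate_subject(cfg, 2)
        assert rec.epochs.data.shape == (cfg.n_trials_per_condition, cfg.n_sensors, cfg.n_times)
        assert rec.model.leadfield.shape == (cfg.n_sensors, cfg.n_voxels)
        t = rec.truth
        assert t.power_ratio == cfg.power_ratio
        assert t.kappa_cue == cfg.kappa_cue
        assert t.pac_depth_cue == cfg.pac_depth_cue
        assert len(t.artifact_variance) == cfg.n_trials_per_condition
        assert len(t.eye_variance_rows) == 2 * cfg.n_trials_per_condition
        lo, hi = cfg.artifact_variance_range
        assert np.all((t.artifact_variance >= lo) & (t.artifact_variance <= hi))

    def test_seed_displaced_at_most_20mm_from_reference(self):
        cfg = small_config()
        coords = cfg.voxel_coords()
        ref = coords[cfg.voxel_index("seed")]
        for sid in range(10):
            rec = simulate_subject(cfg, sid)
            d = np.linalg.norm(coords[rec.truth.seed_voxel] - ref)
            assert d <= cfg.seed_scatter_mm

    def test_out_of_grid_source_rejected(self):
        with pytest.raises(ValueError, match="outside grid"):
            small_config(source_positions={"seed": (0, 0, 0), "coupled": (5, 0, 0), "pac": (1, 1, 1)})

    def test_planted_pair_plv_tracks_kappa(self):
        # window-averaged PLV of the noiseless seed/coupled sources matches
        # the requested concentration's Bessel ratio
        cfg = small_config(kappa_baseline=0.8, kappa_cue=2.0, n_trials_per_condition=30)
        rec = simulate_subject(cfg, 0, keep_sources=True)
        from thetacoupling import THETA, analytic, bandpass

        slices = cfg.windows.sample_slices(cfg.tmin, cfg.fs, cfg.n_times)
        vals = {}
        for cond in ("baseline", "cue"):
            sl = slices[cond]
            ph = [
                (analytic(bandpass(rec.truth.source_series[k], THETA, cfg.fs), THETA, cfg.fs).phase)
                for k in (0, 1)
            ]
            vals[cond] = np.mean([
                plv(ph[0][i, sl], ph[1][i, sl]) for i in range(cfg.n_trials_per_condition)
            ])
        assert vals["cue"] > vals["baseline"] + 0.05
        # window-level PLV carries a positive finite-sample bias, so the
        # planted concentration's Bessel ratio is a lower bound
        assert vals["baseline"] > float(bessel_ratio(0.8)) - 0.05

    def test_coupled_source_power_independent_of_kappa(self):
        # the phase-jitter model must not turn a coupling change into a
        # band-power change, or power regressors would absorb real effects
        from thetacoupling import THETA, band_power

        powers = {}
        for kappa in (0.5, 2.5):
            cfg = small_config(kappa_baseline=kappa, kappa_cue=kappa, amplitude_jitter=0.0)
            rec = simulate_subject(cfg, 0, keep_sources=True)
            powers[kappa] = np.mean([
                band_power(tr, THETA, cfg.fs, window=(480, 1440))
                for tr in rec.truth.source_series[1]
            ])
        # a 5x concentration change may move band power by at most ~25%,
        # far less than the ~2x PLV change it produces
        assert powers[2.5] == pytest.approx(powers[0.5], rel=0.25)


class TestConfigValidation:
    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            SimConfig(theta_band=(4, 35), low_gamma_band=(30, 45))

    def test_power_ratio_below_one_rejected(self):
        with pytest.raises(ValueError, match="power_ratio"):
            SimConfig(power_ratio=0.5)

    def test_bad_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            SimConfig(pac_depth_cue=1.2)

    def test_null_config_removes_all_contrasts(self):
        cfg = null_config(SimConfig())
        assert cfg.power_ratio == 1.0
        assert cfg.kappa_cue == cfg.kappa_baseline
        assert cfg.pac_depth_cue == cfg.pac_depth_baseline

    def test_leadfield_deterministic_given_seed(self):
        cfg = small_config(rng_seed=9)
        m1, m2 = make_source_model(cfg), make_source_model(cfg)
        assert np.array_equal(m1.leadfield, m2.leadfield)
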