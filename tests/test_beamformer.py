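"""LCMV beamformer contracts: unit gain, minimum variance, recovery."""

import numpy as np
import pytest
from scipy.optimize import minimize

from thetacoupling import (
    THETA,
    ConditionWindows,
    Epochs,
    SourceModel,
    compute_weights,
    power_contrast_map,
    virtual_electrode,
)
from thetacoupling.beamformer import sensor_covariance
from thetacoupling.pipeline import subject_weights

from conftest import small_config


def single_voxel_model(leadfield_col):
    lf = np.asarray(leadfield_col, dtype=float)[:, None]
    return SourceModel(voxel_coords=np.zeros((1, 3)), leadfield=lf, grid_shape=(1, 1, 1))


class TestComputeWeights:
    def test_identity_covariance_unit_leadfield(self):
        # C = I, l = e1: the beamformer reduces to the lead field itself
        model = single_voxel_model([1.0, 0.0, 0.0])
        w = compute_weights(np.eye(3), model, reg_fraction=0.05)
        assert np.allclose(w.weights, [[1.0, 0.0, 0.0]], atol=1e-12)

    def test_unit_gain_identity(self, small_cohort):
        rec = small_cohort.subjects[0]
        for reg in (0.0, 0.05, 0.5):
            cov = sensor_covariance(rec.epochs, ConditionWindows())
            w = compute_weights(cov, rec.model, reg_fraction=reg)
            gains = np.einsum("vs,sv->v", w.weights, rec.model.leadfield)
            assert np.allclose(gains, 1.0, atol=1e-6)

    def test_asymmetric_covariance_rejected(self):
        model = single_voxel_model([1.0, 0.0, 0.0])
        c = np.eye(3)
        c[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            compute_weights(c, model)

    def test_indefinite_covariance_rejected(self):
        model = single_voxel_model([1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="definite"):
            compute_weights(np.diag([1.0, 1.0, -1.0]), model)

    def test_minimum_variance_among_unit_gain_filters(self, rng):
        # brute-force check on a 3-sensor toy: no unit-gain filter has
        # lower output variance than the closed-form LCMV weights
        c = np.array([[2.0, 0.5, 0.1], [0.5, 1.5, 0.3], [0.1, 0.3, 1.0]])
        l = np.array([0.8, 0.5, -0.2])
        model = single_voxel_model(l)
        w = compute_weights(c, model, reg_fraction=0.0).weights[0]
        c_r = c  # no regularization: compare against the exact criterion

        def variance(x):
            return x @ c_r @ x

        res = minimize(variance, x0=rng.standard_normal(3),
                       constraints={"type": "eq", "fun": lambda x: x @ l - 1.0})
        assert variance(w) <= res.fun + 1e-9
        assert w @ l == pytest.approx(1.0, abs=1e-9)


class TestVirtualElectrode:
    def test_identity_weights_return_input(self, rng):
        epochs = Epochs(data=rng.standard_normal((3, 4, 100)), fs=480.0, tmin=0.0)
        out = virtual_electrode(np.eye(4), epochs)
        assert np.allclose(out.data, epochs.data)

    def test_noiseless_single_source_recovered_exactly(self, rng):
        # unit gain: with the exact lead field and no noise, the virtual
        # electrode reproduces the source series to numerical precision
        l = np.array([0.9, 0.4, -0.3, 0.2])
        s = rng.standard_normal((5, 2000))
        epochs = Epochs(data=l[None, :, None] * s[:, None, :], fs=480.0, tmin=0.0)
        cov = sensor_covariance(epochs)
        w = compute_weights(cov, single_voxel_model(l), reg_fraction=1e-6)
        ve = virtual_electrode(w, epochs)
        assert np.allclose(ve.data[:, 0, :], s, atol=1e-6)

    def test_dimension_mismatch_rejected(self, rng):
        epochs = Epochs(data=rng.standard_normal((2, 4, 50)), fs=480.0, tmin=0.0)
        with pytest.raises(ValueError, match="sensors"):
            virtual_electrode(np.eye(3), epochs)

    def test_two_sources_separated(self, rng):
        # each voxel's virtual electrode tracks its own planted source
        n_sens, n_t = 12, 12_000
        lf = np.abs(rng.standard_normal((n_sens, 2))) + 0.2
        lf[:6, 1] *= 0.05
        lf[6:, 0] *= 0.05
        s = rng.standard_normal((2, n_t))
        data = (lf @ s + 0.05 * rng.standard_normal((n_sens, n_t)))[None]
        epochs = Epochs(data=data, fs=480.0, tmin=0.0)
        model = SourceModel(voxel_coords=np.array([[0.0, 0, 0], [10.0, 0, 0]]),
                            leadfield=lf, grid_shape=(2, 1, 1))
        w = compute_weights(sensor_covariance(epochs), model, reg_fraction=0.001)
        ve = virtual_electrode(w, epochs).data[0]
        for k in range(2):
            own = np.corrcoef(ve[k], s[k])[0, 1]
            other = np.corrcoef(ve[k], s[1 - k])[0, 1]
            assert own > 0.95
            assert abs(other) < 0.2


class TestPowerContrast:
    def test_identical_windows_give_zero_contrast(self, rng):
        # a 240-sample-periodic signal makes the two analysis windows see
        # identical steady-state content, so the contrast must vanish
        cfg = small_config()
        tmin, n = -5.0, int(10.0 * cfg.fs)  # wide margins: edge transients decayed
        t = tmin + np.arange(n) / cfg.fs
        periodic = sum(np.cos(2 * np.pi * f * t + p) for f, p in [(4, 0.3), (6, 1.1), (8, 2.0)])
        gains = rng.standard_normal((4, cfg.n_sensors))
        epochs = Epochs(data=gains[:, :, None] * periodic, fs=cfg.fs, tmin=tmin)
        from thetacoupling.synth import make_source_model

        model = make_source_model(cfg)
        # rank-deficient tone covariance: supply the noise floor explicitly
        w = compute_weights(sensor_covariance(epochs, ConditionWindows()), model, noise_power=1.0)
        out = power_contrast_map(w, epochs, THETA, ConditionWindows())
        assert np.all(np.abs(out["contrast"]) < 1e-5 * out["baseline"])

    def test_gain_scaling_leaves_argmax_unchanged(self, small_cohort):
        rec = small_cohort.subjects[0]
        windows = ConditionWindows()

        def argmax_for(scale):
            epochs = Epochs(data=scale * rec.epochs.data, fs=rec.epochs.fs, tmin=rec.epochs.tmin)
            model = SourceModel(voxel_coords=rec.model.voxel_coords,
                                leadfield=scale * rec.model.leadfield,
                                grid_shape=rec.model.grid_shape)
            w = compute_weights(sensor_covariance(epochs, windows), model)
            return int(np.argmax(power_contrast_map(w, epochs, THETA, windows)["contrast"]))

        assert argmax_for(1.0) == argmax_for(2.0)

    def test_planted_power_ratio_recovered(self, small_cohort):
        # cue/baseline theta power at the planted seed voxel ~ power_ratio
        ratios = []
        for rec in small_cohort.subjects:
            w = subject_weights(rec, ConditionWindows(), 0.05)
            out = power_contrast_map(w, rec.epochs, THETA, ConditionWindows())
            sv = rec.truth.seed_voxel
            ratios.append(out["cue"][sv] / out["baseline"][sv])
        assert np.mean(ratios) == pytest.approx(small_cohort.config.power_ratio, rel=0.15)

    def test_zero_noise_power_rejected(self, small_cohort):
        rec = small_cohort.subjects[0]
        w = subject_weights(rec, ConditionWindows(), 0.05)
        w.noise_power = 0.0
        with pytest.raises(ValueError, match="noise"):
            power_contrast_map(w, rec.epochs, THETA, ConditionWindows())
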