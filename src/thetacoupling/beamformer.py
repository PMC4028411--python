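"""LCMV scalar beamformer: weights, virtual electrodes, power contrasts.

The linearly constrained minimum variance (LCMV) spatial filter maps
sensor data to each source-grid voxel with unit gain on that voxel's lead
field while minimising total output variance, i.e. for voxel ``n`` with
lead-field column ``l_n`` and (regularised) sensor covariance ``C``::

    w_n = (l_n' C^-1 l_n)^-1  C^-1 l_n          w_n' l_n = 1

Band-power maps are normalised by the projected sensor white-noise power
``noise_power * w_n' w_n`` so that depth-dependent weight amplification
does not masquerade as source power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import Epochs
from .spectral import BandDefinition, ConditionWindows, bandpass


@dataclass
class SourceModel:
    """Source grid plus forward model.

    voxel_coords : (n_voxels, 3) mm coordinates on a 10-mm grid.
    leadfield : (n_sensors, n_voxels) scalar (fixed-orientation) lead
        fields; column ``n`` is the sensor pattern of unit activity at
        voxel ``n``.
    grid_shape : 3-tuple, the voxel grid dimensions; voxels are stored in
        C order of this shape.
    """

    voxel_coords: np.ndarray
    leadfield: np.ndarray
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=float)
        self.leadfield = np.asarray(self.leadfield, dtype=float)
        if self.voxel_coords.shape != (self.leadfield.shape[1], 3):
            raise ValueError("voxel_coords must be (n_voxels, 3) matching leadfield columns")
        if int(np.prod(self.grid_shape)) != self.n_voxels:
            raise ValueError("grid_shape inconsistent with number of voxels")
        norms = np.linalg.norm(self.leadfield, axis=0)
        if np.any(norms == 0):
            raise ValueError("leadfield contains all-zero columns")
        if len(np.unique(self.voxel_coords, axis=0)) != self.n_voxels:
            raise ValueError("voxel coordinates must be unique")

    @property
    def n_sensors(self) -> int:
        return self.leadfield.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.leadfield.shape[1]


@dataclass
class BeamformerWeights:
    """LCMV weights, one row per voxel; satisfies w_n' l_n = 1."""

    weights: np.ndarray  # (n_voxels, n_sensors)
    regularization: float
    noise_power: float

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[0]

    def projected_noise(self) -> np.ndarray:
        """Projected sensor white-noise power per voxel: noise_power * ||w_n||^2."""
        return self.noise_power * np.sum(self.weights**2, axis=1)


def sensor_covariance(epochs: Epochs, windows: ConditionWindows | None = None) -> np.ndarray:
    """Sensor covariance from the concatenated analysis windows of all trials.

    Using one covariance over both conditions (a "common filter") keeps
    condition differences out of the weights themselves.  When ``windows``
    is None the full epochs are used.
    """
    if windows is None:
        segments = epochs.data
    else:
        slices = windows.sample_slices(epochs.tmin, epochs.fs, epochs.n_times)
        segments = np.concatenate(
            [epochs.data[:, :, slices["baseline"]], epochs.data[:, :, slices["cue"]]], axis=2
        )
    x = segments.transpose(1, 0, 2).reshape(epochs.n_channels, -1)
    x = x - x.mean(axis=1, keepdims=True)
    return x @ x.T / (x.shape[1] - 1)


def compute_weights(covariance: np.ndarray, model: SourceModel,
                    reg_fraction: float = 0.05,
                    noise_power: float | None = None) -> BeamformerWeights:
    """LCMV weights from sensor covariance and lead fields.

    The covariance is Tikhonov-regularised by ``reg_fraction`` of its mean
    diagonal.  ``noise_power`` (sensor white-noise variance used for the
    projected-noise normalisation) defaults to the smallest eigenvalue of
    the unregularised covariance.
    """
    c = np.asarray(covariance, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("covariance must be square")
    if c.shape[0] != model.n_sensors:
        raise ValueError("covariance size does not match number of sensors")
    if not np.allclose(c, c.T, rtol=1e-8, atol=1e-10 * max(1.0, float(np.abs(c).max()))):
        raise ValueError("covariance must be symmetric")
    eigvals = np.linalg.eigvalsh(c)
    if eigvals[0] < -1e-8 * max(eigvals[-1], 1.0):
        raise ValueError("covariance must be positive semi-definite")
    if noise_power is None:
        noise_power = float(max(eigvals[0], 0.0))

    c_r = c + reg_fraction * np.mean(np.diag(c)) * np.eye(c.shape[0])
    try:
        x = np.linalg.solve(c_r, model.leadfield)  # C_r^-1 L, (n_sensors, n_voxels)
    except np.linalg.LinAlgError as err:
        raise ValueError("regularized covariance is singular; increase reg_fraction") from err
    denom = np.einsum("sv,sv->v", model.leadfield, x)  # l_n' C_r^-1 l_n
    if np.any(denom <= 0):
        raise ValueError("regularized covariance is singular along some lead field")
    weights = (x / denom).T
    return BeamformerWeights(weights=weights, regularization=reg_fraction, noise_power=noise_power)


def project(weights: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Apply a (voxels, sensors) matrix to (trials, sensors, times) data.

    Works for real or complex data (one BLAS gemm on the flattened array).
    """
    w = np.asarray(weights)
    t, s, n = data.shape
    if w.shape[1] != s:
        raise ValueError(f"weights expect {w.shape[1]} sensors but data have {s} channels")
    flat = data.transpose(1, 0, 2).reshape(s, t * n)
    if np.iscomplexobj(flat) and not np.iscomplexobj(w):
        w = w.astype(flat.dtype)
    out = w @ flat
    return out.reshape(w.shape[0], t, n).transpose(1, 0, 2)


def virtual_electrode(weights: BeamformerWeights | np.ndarray, epochs: Epochs) -> Epochs:
    """Project sensor epochs through beamformer weights to source space."""
    w = weights.weights if isinstance(weights, BeamformerWeights) else np.asarray(weights)
    return Epochs(data=project(w, epochs.data), fs=epochs.fs, tmin=epochs.tmin)


def power_contrast_map(weights: BeamformerWeights, epochs: Epochs, band: BandDefinition,
                       windows: ConditionWindows) -> dict[str, np.ndarray]:
    """Noise-normalised band-power contrast (cue - baseline) per voxel.

    Each trial's epoch is band-passed in full (sensor level -- filtering
    and the linear beamformer projection commute), projected to source
    space, and the mean square over each condition's window is divided by
    the projected sensor white-noise power of that voxel.  Per-condition
    values are trial means; the contrast is their difference.

    Returns a dict with per-voxel arrays ``contrast``, ``cue``,
    ``baseline`` and per-trial matrices ``cue_trials``, ``baseline_trials``
    of shape (n_trials, n_voxels).
    """
    if epochs.n_trials < 1:
        raise ValueError("need at least one trial")
    noise = weights.projected_noise()
    if np.any(noise <= 0):
        raise ValueError("projected noise power must be positive; set a positive noise_power")
    filtered = bandpass(epochs.data, band, epochs.fs, axis=-1)
    source = project(weights.weights, filtered)
    slices = windows.sample_slices(epochs.tmin, epochs.fs, epochs.n_times)
    base = np.mean(source[:, :, slices["baseline"]] ** 2, axis=2) / noise
    cue = np.mean(source[:, :, slices["cue"]] ** 2, axis=2) / noise
    return {
        "baseline_trials": base,
        "cue_trials": cue,
        "baseline": base.mean(axis=0),
        "cue": cue.mean(axis=0),
        "contrast": cue.mean(axis=0) - base.mean(axis=0),
    }
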