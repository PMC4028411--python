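"""Phase-coupling metrics: PLV, PLI, and envelope-phase PAC.

All three statistics live in [0, 1] and are computed per trial within each
analysis window, then averaged per condition before second-level testing.

* PLV (phase locking value): resultant vector length of the phase
  differences over time -- 1 for a perfectly consistent phase relation,
  near 0 for random differences.
* PLI (phase lag index): absolute mean sign of the wrapped phase
  difference.  Zero-lag (volume-conducted) coupling produces symmetric
  phase differences around 0, so the PLI discounts it.
* PAC (theta-phase -> gamma-amplitude): the gamma-band envelope is itself
  theta-band filtered, Hilbert-transformed a second time, and the phase of
  that envelope is compared with the seed theta phase by PLV.

Note: at 1-s windows (480 samples) the PLV has a positive finite-sample
bias.  It is identical in the two conditions because the windows are
equally long, so it cancels in the cue-minus-baseline contrast and is not
corrected here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import Epochs
from .spectral import BandDefinition, ConditionWindows, analytic, bandpass

METRICS = ("plv", "pli", "pac")


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(phi)))


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"phase series length mismatch: {a.shape} vs {b.shape}")
    if a.shape[-1] < 2:
        raise ValueError("need at least 2 samples")
    return a, b


def plv(phase_a: np.ndarray, phase_b: np.ndarray, axis: int = -1) -> np.ndarray:
    """Phase locking value |mean_t exp(i (phase_a - phase_b))|."""
    a, b = _check_pair(phase_a, phase_b)
    return np.abs(np.mean(np.exp(1j * (a - b)), axis=axis))


def pli(phase_a: np.ndarray, phase_b: np.ndarray, axis: int = -1) -> np.ndarray:
    """Phase lag index |mean_t sign(wrap(phase_a - phase_b))|, sign(0) = 0."""
    a, b = _check_pair(phase_a, phase_b)
    return np.abs(np.mean(np.sign(wrap_phase(a - b)), axis=axis))


def pac_envelope_phase(seed_theta_phase: np.ndarray, target_series: np.ndarray,
                       gamma_band: BandDefinition, theta_band: BandDefinition,
                       fs: float, window: slice | tuple[int, int] | None = None) -> float:
    """Theta-phase -> gamma-amplitude coupling by double-Hilbert PLV.

    Pipeline: band-pass ``target_series`` at ``gamma_band`` -> analytic
    amplitude (envelope) -> band-pass the envelope at ``theta_band`` ->
    analytic phase -> PLV against ``seed_theta_phase``.

    Both inputs must cover the full epoch so filter transients fall
    outside the analysis ``window`` (half-open sample range), which is
    cropped only at the final PLV step.  The envelope's theta-band
    filtering removes its DC; no further detrending is applied.
    """
    target = np.asarray(target_series, dtype=float)
    seed_phase = np.asarray(seed_theta_phase, dtype=float)
    if target.shape != seed_phase.shape:
        raise ValueError("seed phase and target series must cover the same samples")
    env = np.abs(analytic(bandpass(target, gamma_band, fs), gamma_band, fs).values)
    env_phase = analytic(bandpass(env, theta_band, fs), theta_band, fs).phase
    if window is not None:
        if isinstance(window, tuple):
            window = slice(*window)
        env_phase = env_phase[..., window]
        seed_phase = seed_phase[..., window]
        if env_phase.shape[-1] < 2:
            raise ValueError("analysis window too short after cropping")
    return plv(seed_phase, env_phase)


@dataclass
class CouplingMap:
    """Seed-to-all-voxels coupling values, per trial and condition.

    values : (n_voxels, n_rows) array where each column is one
        trial-window (rows of the confound table): column ``2k`` is trial
        ``k``'s baseline window and column ``2k+1`` its cue window, as
        labelled by ``conditions`` ("baseline"/"cue" per column).
    """

    metric: str
    seed: int
    values: np.ndarray
    conditions: np.ndarray

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        if np.any(self.values < -1e-6) or np.any(self.values > 1 + 1e-6):
            raise ValueError("coupling values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    def condition_mean(self, condition: str) -> np.ndarray:
        """Per-voxel mean over that condition's trials."""
        mask = self.conditions == condition
        if not mask.any():
            raise ValueError(f"no rows with condition {condition!r}")
        return self.values[:, mask].mean(axis=1)

    def contrast(self) -> np.ndarray:
        """Per-voxel mean cue coupling minus mean baseline coupling."""
        return self.condition_mean("cue") - self.condition_mean("baseline")


def _analytic_phasors(data: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Unit phasors exp(i*phase) of the band-limited analytic signal."""
    z = analytic(bandpass(data, band, fs), band, fs).values
    mag = np.abs(z)
    mag[mag == 0] = 1.0
    return z / mag


def map_from_phasors(seed_phasor: np.ndarray, target_phasor: np.ndarray, metric: str,
                     slices: dict[str, slice], seed: int) -> CouplingMap:
    """Assemble a CouplingMap from unit phasors.

    ``seed_phasor`` is (n_trials, n_times) and ``target_phasor``
    (n_trials, n_voxels, n_times); both must be unit-magnitude complex
    series (exp(i*phase)).  Values are computed inside each trial's
    baseline and cue windows separately; trial-window columns interleave
    as (trial0 baseline, trial0 cue, trial1 baseline, ...).
    """
    n_trials, n_vox = target_phasor.shape[0], target_phasor.shape[1]
    values = np.empty((n_vox, 2 * n_trials))
    conditions = np.empty(2 * n_trials, dtype=object)
    for k, cond in enumerate(("baseline", "cue")):
        sl = slices[cond]
        d = seed_phasor[:, None, sl].conj() * target_phasor[:, :, sl]
        if metric == "pli":
            vals = np.abs(np.mean(np.sign(np.angle(d)), axis=2))
        else:
            vals = np.abs(np.mean(d, axis=2))
        values[:, k::2] = vals.T
        conditions[k::2] = cond
    return CouplingMap(metric=metric, seed=seed, values=values,
                       conditions=np.asarray(conditions, dtype=object))


def seed_coupling_map(epochs: Epochs, seed: int, metric: str, windows: ConditionWindows,
                      theta_band: BandDefinition, gamma_band: BandDefinition | None = None,
                      ) -> CouplingMap:
    """Coupling between one seed voxel and every voxel, per trial window.

    ``epochs`` are source-space (virtual-electrode) trials covering the
    full epoch; filtering uses that full context and the metric is then
    computed inside each trial's baseline and cue windows separately.
    For ``metric="pac"`` the seed's theta phase is compared against the
    theta-filtered ``gamma_band`` envelope phase of every voxel.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if not 0 <= seed < epochs.n_channels:
        raise ValueError(f"seed voxel {seed} outside 0..{epochs.n_channels - 1}")
    slices = windows.sample_slices(epochs.tmin, epochs.fs, epochs.n_times)

    seed_phasor = _analytic_phasors(epochs.data[:, seed, :], theta_band, epochs.fs)

    if metric == "pac":
        if gamma_band is None:
            raise ValueError("pac metric needs a gamma_band")
        env = np.abs(analytic(bandpass(epochs.data, gamma_band, epochs.fs), gamma_band, epochs.fs).values)
        target_phasor = _analytic_phasors(env, theta_band, epochs.fs)
    else:
        target_phasor = _analytic_phasors(epochs.data, theta_band, epochs.fs)

    return map_from_phasors(seed_phasor, target_phasor, metric, slices, seed)
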