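"""Synthetic multi-subject MEG recordings with planted coupling effects.

Every effect the analysis pipeline is meant to detect is planted at a
known voxel with a known magnitude, so the pipeline is validated by
parameter recovery instead of by comparison with undeposited recordings:

* a frontal-midline-like *seed* source whose 4-8 Hz theta power rises in
  the cue window (``power_ratio``),
* a *coupled* source whose theta phase tracks the seed phase with a fixed
  lag plus von Mises jitter (concentration ``kappa``, higher during cue),
* a *pac* source whose 65-85 Hz gamma amplitude is modulated by the seed
  theta phase (depth ``m``, higher during cue),
* a trial-varying low-frequency eye-movement-like artifact with its own
  sensor topography, and
* iid Gaussian sensor noise.

Sources are scalar (fixed orientation) and mixed into sensors through
smooth Gaussian-profile lead fields, so neighbouring voxels receive
correlated signal -- the synthetic analogue of volume conduction.  Each
trial's epoch contains both analysis windows (pre-cue fixation and the
post-cue segment); cue-condition parameters apply inside the cue window
only.  All randomness derives from one top-level seed, with per-subject
streams seeded by ``(rng_seed, subject_id)``; regeneration is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .beamformer import SourceModel
from .containers import Epochs
from .spectral import ConditionWindows

_LEADFIELD_STREAM = 999_983  # fixed sub-stream tags, distinct from subject ids
_ARTIFACT_STREAM = 999_979


@dataclass
class SimConfig:
    """Study-condition constants and planted effect sizes.

    Defaults mirror the retrieval experiment the generator emulates:
    17 subjects, 36 retrieval trials each (one baseline and one cue window
    per trial), 480 Hz sampling, theta 4-8 Hz, low gamma 30-45 Hz, high
    gamma 65-85 Hz, 10-mm source grid.  Sensor count, grid extent, source
    depths/amplitudes and noise level are not reported for the original
    recordings; the defaults here are chosen once to give a realistic
    moderate-SNR regime in which recovery is feasible (see the methods
    note) and are deliberately not tuned per experiment.
    """

    n_subjects: int = 17
    n_trials_per_condition: int = 36
    fs: float = 480.0
    trial_duration: float = 3.5
    tmin: float = -1.5
    n_sensors: int = 32
    grid_shape: tuple[int, int, int] = (4, 4, 4)
    grid_spacing: float = 10.0
    source_positions: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: {"seed": (0, 1, 2), "coupled": (3, 2, 1), "pac": (2, 3, 3)}
    )
    theta_band: tuple[float, float] = (4.0, 8.0)
    low_gamma_band: tuple[float, float] = (30.0, 45.0)
    high_gamma_band: tuple[float, float] = (65.0, 85.0)
    power_ratio: float = 2.0
    kappa_baseline: float = 0.8
    kappa_cue: float = 1.6
    coupling_lag: float = np.pi / 4
    pac_depth_baseline: float = 0.15
    pac_depth_cue: float = 0.6
    artifact_variance_range: tuple[float, float] = (0.5, 1.5)
    artifact_condition_gain: float = 1.0
    sensor_noise_sd: float = 1.0
    seed_amplitude: float = 3.0
    coupled_amplitude: float = 1.5
    pac_amplitude: float = 1.5
    amplitude_jitter: float = 0.35
    seed_scatter_mm: float = 20.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        bands = [self.theta_band, self.low_gamma_band, self.high_gamma_band]
        for lo, hi in bands:
            if not 0 < lo < hi < self.fs / 2:
                raise ValueError(f"band ({lo}, {hi}) must satisfy 0 < low < high < fs/2={self.fs / 2}")
        for (_, a_hi), (b_lo, _) in zip(bands, bands[1:]):
            if b_lo <= a_hi:
                raise ValueError("bands must be ordered and non-overlapping")
        if self.kappa_baseline < 0 or self.kappa_cue < 0:
            raise ValueError("kappa must be >= 0")
        for m in (self.pac_depth_baseline, self.pac_depth_cue):
            if not 0 <= m <= 1:
                raise ValueError(f"modulation depth m={m} must be in [0, 1]")
        if self.power_ratio < 1:
            raise ValueError("power_ratio must be >= 1 (cue/baseline theta power at the seed)")
        if self.artifact_variance_range[0] > self.artifact_variance_range[1] or self.artifact_variance_range[0] < 0:
            raise ValueError("artifact_variance_range must be a non-negative (low, high) pair")
        for name, idx in self.source_positions.items():
            if len(idx) != 3 or any(not 0 <= i < s for i, s in zip(idx, self.grid_shape)):
                raise ValueError(f"source {name!r} index {idx} outside grid {self.grid_shape}")
        n_win = round(self.fs * 1.0)
        if self.tmin > -1.0 or self.tmin + self.trial_duration < 1.5:
            raise ValueError("epoch must cover the baseline [-1, 0] and cue [0.5, 1.5] windows")
        if n_win < 2:
            raise ValueError("fs too low")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def n_times(self) -> int:
        return int(round(self.trial_duration * self.fs))

    @property
    def windows(self) -> ConditionWindows:
        return ConditionWindows()

    def voxel_index(self, name: str) -> int:
        return int(np.ravel_multi_index(self.source_positions[name], self.grid_shape))

    def voxel_coords(self) -> np.ndarray:
        """Centered mm coordinates of the grid voxels, C order."""
        axes = [
            (np.arange(n) - (n - 1) / 2) * self.grid_spacing for n in self.grid_shape
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([m.ravel() for m in mesh])


@dataclass
class SubjectGroundTruth:
    """Exact planted values for one simulated subject."""

    subject_id: int
    seed_voxel: int
    coupled_voxel: int
    pac_voxel: int
    power_ratio: float
    kappa_baseline: float
    kappa_cue: float
    pac_depth_baseline: float
    pac_depth_cue: float
    artifact_variance: np.ndarray       # planted per-trial variance (n_trials,)
    eye_variance_rows: np.ndarray       # realized artifact variance per trial-window (2*n_trials,)
    source_series: np.ndarray | None = None  # (3, n_trials, n_times) seed/coupled/pac, optional
    seed_theta_phase: np.ndarray | None = None  # (n_trials, n_times) planted seed phase


@dataclass
class GroundTruth:
    """Planted values for a whole simulated cohort."""

    subjects: list[SubjectGroundTruth]
    config: SimConfig

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append({
                "subject_id": s.subject_id,
                "seed_voxel": s.seed_voxel,
                "coupled_voxel": s.coupled_voxel,
                "pac_voxel": s.pac_voxel,
                "power_ratio": s.power_ratio,
                "kappa_baseline": s.kappa_baseline,
                "kappa_cue": s.kappa_cue,
                "pac_depth_baseline": s.pac_depth_baseline,
                "pac_depth_cue": s.pac_depth_cue,
                "mean_artifact_variance": float(np.mean(s.artifact_variance)),
            })
        return pd.DataFrame(rows)


@dataclass
class SubjectRecording:
    """One subject's simulated sensor epochs plus forward model and truth."""

    epochs: Epochs
    model: SourceModel
    truth: SubjectGroundTruth


@dataclass
class Dataset:
    config: SimConfig
    subjects: list[SubjectRecording]

    @property
    def truth(self) -> GroundTruth:
        return GroundTruth(subjects=[s.truth for s in self.subjects], config=self.config)


# ---------------------------------------------------------------------------
# elementary generators


def _smooth_noise(n: int, fs: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Ornstein-Uhlenbeck (AR(1)) noise, correlation time tau (s)."""
    from scipy.signal import lfilter

    alpha = np.exp(-1.0 / (fs * tau))
    w = rng.standard_normal(n) * np.sqrt(1 - alpha**2)
    x0 = rng.standard_normal()  # stationary start
    out, _ = lfilter([1.0], [1.0, -alpha], w, zi=np.array([alpha * x0]))
    return out


def _smooth_jitter(n: int, fs: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Differentiable unit-variance noise path (twice-smoothed AR(1)).

    A plain Ornstein-Uhlenbeck path is nowhere differentiable, so using it
    as phase jitter leaks oscillatory power far outside the band; a second
    smoothing pass bounds the instantaneous-frequency excursion, keeping a
    phase-jittered oscillation narrowband at any jitter size.
    """
    from scipy.signal import lfilter

    alpha = np.exp(-1.0 / (fs * tau))
    x = _smooth_noise(n, fs, tau, rng)
    y, _ = lfilter([1.0], [1.0, -alpha], x, zi=np.array([alpha * x[0]]))
    sd = y.std()
    return y / (sd if sd > 0 else 1.0)


def _oscillator_phase(n: int, fs: float, rng: np.random.Generator, f0: float,
                      f_jitter: float = 0.8, tau: float = 0.2) -> np.ndarray:
    """Unwrapped phase of a frequency-jittered oscillator around f0 Hz."""
    f_inst = f0 + f_jitter * _smooth_noise(n, fs, tau, rng)
    phi0 = rng.uniform(0, 2 * np.pi)
    return phi0 + 2 * np.pi * np.cumsum(f_inst) / fs


def bessel_ratio(kappa: np.ndarray | float) -> np.ndarray | float:
    """Mean resultant length I1(kappa)/I0(kappa) of a von Mises distribution."""
    from scipy.special import i0e, i1e

    return i1e(kappa) / i0e(kappa)


def _jitter_sigma(kappa: np.ndarray) -> np.ndarray:
    """Wrapped-normal sd with the same circular variance as von Mises(kappa).

    A wrapped normal with sd sigma has mean resultant exp(-sigma^2/2);
    matching it to the Bessel ratio of von Mises(kappa) makes the planted
    pair PLV equal I1(kappa)/I0(kappa) regardless of the jitter's temporal
    correlation.
    """
    r = np.asarray(bessel_ratio(np.maximum(kappa, 1e-3)))
    return np.sqrt(-2.0 * np.log(np.clip(r, 1e-12, 1.0)))


def simulate_coupled_phases(kappa: float, lag: float, n: int, rng: np.random.Generator,
                            fs: float = 480.0, freq: float = 6.0) -> tuple[np.ndarray, np.ndarray]:
    """A pair of wrapped phase series with a planted phase relation.

    ``phase_b(t) = phase_a(t) + lag + eps(t)`` with iid
    ``eps ~ von Mises(0, kappa)``.  The sample PLV of the pair converges
    to the Bessel ratio I1(kappa)/I0(kappa) as n grows; ``kappa = 0``
    gives uniform phase differences (PLV -> 0) and large kappa a rigid
    lock (PLV -> 1).  ``phase_a`` itself is a frequency-jittered theta
    oscillator around ``freq``.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    phase_a = _oscillator_phase(n, fs, rng, freq)
    eps = rng.vonmises(0.0, kappa, size=n) if kappa > 0 else rng.uniform(-np.pi, np.pi, size=n)
    phase_b = phase_a + lag + eps
    wrap = lambda p: np.angle(np.exp(1j * p))  # noqa: E731
    return wrap(phase_a), wrap(phase_b)


def simulate_pac_source(f_theta: float, f_gamma: float, m: float, n: int, fs: float,
                        rng: np.random.Generator, amplitude: float = 1.0,
                        noise_sd: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Gamma oscillation whose amplitude is modulated by theta phase.

    ``s(t) = amplitude * (1 + m cos(phi_theta(t))) * cos(phi_gamma(t)) +
    noise``; returns the series and the exact wrapped ``phi_theta`` used,
    as ground truth for PAC-metric validation.
    """
    if not 0 <= m <= 1:
        raise ValueError(f"modulation depth m={m} must be in [0, 1]")
    if f_gamma >= fs / 2:
        raise ValueError("gamma carrier must lie below Nyquist")
    phi_theta = _oscillator_phase(n, fs, rng, f_theta)
    phi_gamma = _oscillator_phase(n, fs, rng, f_gamma, f_jitter=2.0)
    s = amplitude * (1 + m * np.cos(phi_theta)) * np.cos(phi_gamma)
    s = s + noise_sd * rng.standard_normal(n)
    return s, np.angle(np.exp(1j * phi_theta))


# ---------------------------------------------------------------------------
# forward model


def _sensor_positions(n_sensors: int, radius: float = 50.0) -> np.ndarray:
    """Fibonacci-spiral points on the upper hemisphere (mm)."""
    i = np.arange(n_sensors)
    golden = (1 + np.sqrt(5)) / 2
    z = (i + 0.5) / n_sensors          # upper hemisphere only
    theta = 2 * np.pi * i / golden
    r = np.sqrt(1 - z**2)
    return radius * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def make_source_model(config: SimConfig) -> SourceModel:
    """Gaussian-profile scalar lead fields on the voxel grid.

    Column ``n`` falls off as a Gaussian of the sensor-voxel distance
    (scale 25 mm), plus a small fixed random component that breaks exact
    collinearity between neighbouring columns.  Neighbouring voxels still
    project to strongly overlapping sensor patterns, which is what makes
    zero-lag leakage (volume conduction) testable downstream.  The model
    is shared by all subjects of a cohort and is deterministic given
    ``rng_seed``.
    """
    rng = np.random.default_rng([config.rng_seed, _LEADFIELD_STREAM])
    sensors = _sensor_positions(config.n_sensors)
    coords = config.voxel_coords()
    d = np.linalg.norm(sensors[:, None, :] - coords[None, :, :], axis=2)
    profile = np.exp(-(d**2) / (2 * 25.0**2))
    jitter = 0.05 * rng.standard_normal(profile.shape) * profile.mean()
    return SourceModel(voxel_coords=coords, leadfield=profile + jitter, grid_shape=config.grid_shape)


# ---------------------------------------------------------------------------
# subject simulation


def _window_gate(config: SimConfig, ramp: float = 0.05) -> np.ndarray:
    """Smooth 0..1 gate over the cue window, with half-cosine ramps (s)."""
    t = config.tmin + np.arange(config.n_times) / config.fs
    t0, t1 = config.windows.cue
    gate = np.zeros(config.n_times)
    gate[(t >= t0) & (t < t1)] = 1.0
    up = (t >= t0 - ramp) & (t < t0)
    gate[up] = 0.5 * (1 + np.cos(np.pi * (t0 - t[up]) / ramp))
    down = (t >= t1) & (t < t1 + ramp)
    gate[down] = 0.5 * (1 + np.cos(np.pi * (t[down] - t1) / ramp))
    return gate


def _seed_candidates(config: SimConfig) -> np.ndarray:
    coords = config.voxel_coords()
    ref = coords[config.voxel_index("seed")]
    dist = np.linalg.norm(coords - ref, axis=1)
    return np.flatnonzero(dist <= config.seed_scatter_mm)


def simulate_subject(config: SimConfig, subject_id: int,
                     keep_sources: bool = False) -> SubjectRecording:
    """Simulate one subject's sensor-level trials.

    The subject's seed source is displaced up to ``seed_scatter_mm`` from
    the group reference voxel (uniformly over in-radius grid voxels),
    emulating between-subject variability in frontal-midline theta source
    location; the coupled and pac sources stay at their reference voxels.
    Per-subject randomness comes from the stream ``(rng_seed, subject_id)``.

    With ``keep_sources`` the noiseless source series and the seed theta
    phase are stored in the ground truth (memory permitting) for direct
    recovery checks.
    """
    config.validate()
    rng = np.random.default_rng([config.rng_seed, int(subject_id)])
    model = make_source_model(config)

    n_tr, n_t = config.n_trials_per_condition, config.n_times
    gate = _window_gate(config)
    kappa_t = config.kappa_baseline + (config.kappa_cue - config.kappa_baseline) * gate
    m_t = config.pac_depth_baseline + (config.pac_depth_cue - config.pac_depth_baseline) * gate
    amp_t = config.seed_amplitude * np.sqrt(1 + (config.power_ratio - 1) * gate)
    art_gain_t = 1 + (config.artifact_condition_gain - 1) * gate

    seed_voxel = int(rng.choice(_seed_candidates(config)))
    coupled_voxel = config.voxel_index("coupled")
    pac_voxel = config.voxel_index("pac")

    f_theta = float(np.mean(config.theta_band))
    f_gamma = float(np.mean(config.high_gamma_band))

    sources = np.empty((3, n_tr, n_t))
    seed_phase = np.empty((n_tr, n_t))
    artifact = np.empty((n_tr, n_t))
    art_var = rng.uniform(*config.artifact_variance_range, size=n_tr)
    sigma_t = _jitter_sigma(kappa_t)
    tiny_kappa = kappa_t < 1e-3
    # per-trial amplitude variability (log-normal) decouples oscillatory
    # power from the condition label, as in real trial-varying rhythms
    scales = np.exp(config.amplitude_jitter * rng.standard_normal((n_tr, 3)))
    pac_norm = np.sqrt(1 + m_t**2 / 2)  # keeps gamma power independent of m
    for i in range(n_tr):
        phi_a = _oscillator_phase(n_t, config.fs, rng, f_theta)
        seed_phase[i] = np.angle(np.exp(1j * phi_a))
        sources[0, i] = scales[i, 0] * amp_t * np.cos(phi_a)
        # slowly varying wrapped-normal phase jitter whose circular variance
        # matches von Mises(kappa): long-run PLV of the pair = I1(k)/I0(k)
        eps = sigma_t * _smooth_jitter(n_t, config.fs, tau=0.25, rng=rng)
        if tiny_kappa.any():
            eps[tiny_kappa] = rng.uniform(-np.pi, np.pi, size=int(tiny_kappa.sum()))
        sources[1, i] = scales[i, 1] * config.coupled_amplitude * np.cos(
            phi_a + config.coupling_lag + eps)
        phi_g = _oscillator_phase(n_t, config.fs, rng, f_gamma, f_jitter=2.0)
        sources[2, i] = scales[i, 2] * config.pac_amplitude * (
            (1 + m_t * np.cos(phi_a)) / pac_norm) * np.cos(phi_g)
        slow = _smooth_noise(n_t, config.fs, tau=0.3, rng=rng)
        artifact[i] = np.sqrt(art_var[i]) * art_gain_t * slow / slow.std()

    art_rng = np.random.default_rng([config.rng_seed, _ARTIFACT_STREAM, int(subject_id)])
    topo = art_rng.standard_normal(config.n_sensors)
    topo = topo / np.linalg.norm(topo) * float(np.linalg.norm(model.leadfield, axis=0).mean())

    mixing = model.leadfield[:, [seed_voxel, coupled_voxel, pac_voxel]]
    data = np.einsum("sk,ktn->tsn", mixing, sources)
    data += topo[None, :, None] * artifact[:, None, :]
    data += config.sensor_noise_sd * rng.standard_normal(data.shape)

    slices = config.windows.sample_slices(config.tmin, config.fs, n_t)
    eye_rows = np.empty(2 * n_tr)
    eye_rows[0::2] = artifact[:, slices["baseline"]].var(axis=1, ddof=1)
    eye_rows[1::2] = artifact[:, slices["cue"]].var(axis=1, ddof=1)

    truth = SubjectGroundTruth(
        subject_id=int(subject_id),
        seed_voxel=seed_voxel,
        coupled_voxel=coupled_voxel,
        pac_voxel=pac_voxel,
        power_ratio=config.power_ratio,
        kappa_baseline=config.kappa_baseline,
        kappa_cue=config.kappa_cue,
        pac_depth_baseline=config.pac_depth_baseline,
        pac_depth_cue=config.pac_depth_cue,
        artifact_variance=art_var,
        eye_variance_rows=eye_rows,
        source_series=sources if keep_sources else None,
        seed_theta_phase=seed_phase if keep_sources else None,
    )
    epochs = Epochs(data=data, fs=config.fs, tmin=config.tmin)
    return SubjectRecording(epochs=epochs, model=model, truth=truth)


def simulate_dataset(config: SimConfig, keep_sources: bool = False) -> Dataset:
    """Simulate the whole cohort (``config.n_subjects`` subjects)."""
    subjects = [simulate_subject(config, sid, keep_sources=keep_sources)
                for sid in range(config.n_subjects)]
    return Dataset(config=config, subjects=subjects)


def null_config(config: SimConfig | None = None, **overrides) -> SimConfig:
    """A copy of ``config`` with every planted condition difference removed."""
    base = config if config is not None else SimConfig()
    return replace(
        base,
        power_ratio=1.0,
        kappa_cue=base.kappa_baseline,
        pac_depth_cue=base.pac_depth_baseline,
        artifact_condition_gain=1.0,
        **overrides,
    )
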