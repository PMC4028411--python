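"""End-to-end group analyses: power contrasts and seed-based coupling.

Each analysis runs per subject (beamform -> band-limit -> per-trial
measure -> confound residualisation), collects one contrast map per
subject, and enters those into the group-level one-sample t test with
cluster-extent thresholding and sign-flip permutation FWE correction.

Implementation note: band-pass filtering and the Hilbert transform are
linear and time-invariant, and the beamformer projection is linear, so
sensor-level filtering followed by complex projection equals filtering the
virtual electrodes directly; with more voxels than sensors this halves the
filtering cost and is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import coupling as _coupling
from .beamformer import BeamformerWeights, SourceModel, compute_weights, project, sensor_covariance
from .confound import residualize_map
from .containers import Epochs
from .coupling import CouplingMap
from .groupstats import StatMap, cluster_fwe_permutation, select_seed
from .spectral import (
    HIGH_GAMMA,
    LOW_GAMMA,
    THETA,
    BandDefinition,
    ConditionWindows,
    analytic,
    bandpass,
)
from .synth import Dataset, SubjectRecording


@dataclass
class PipelineConfig:
    """Settings of the group pipeline.

    Defaults follow the retrieval analysis: voxel threshold p < 0.001
    (uncorrected, one-sided), minimum cluster extent 10 voxels, cluster
    FWE alpha 0.05, seed search radius 20 mm around the group theta peak.
    """

    windows: ConditionWindows = field(default_factory=ConditionWindows)
    theta_band: BandDefinition = THETA
    low_gamma_band: BandDefinition = LOW_GAMMA
    high_gamma_band: BandDefinition = HIGH_GAMMA
    seed_radius: float = 20.0
    p_voxel: float = 0.001
    min_extent: int = 10
    cluster_alpha: float = 0.05
    n_perm: int = 1000
    reg_fraction: float = 0.05
    residualize: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name, p in (("p_voxel", self.p_voxel), ("cluster_alpha", self.cluster_alpha)):
            if not 0 < p < 1:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class SubjectPower:
    """Per-subject per-trial band power and contrast at every voxel."""

    rows: np.ndarray          # (n_voxels, 2*n_trials) noise-normalised window power
    conditions: np.ndarray    # (2*n_trials,) labels
    contrast_raw: np.ndarray  # (n_voxels,)
    contrast: np.ndarray      # (n_voxels,) after residualisation (== raw if disabled)


@dataclass
class PowerResult:
    band: BandDefinition
    subject_contrasts: np.ndarray       # (n_subjects, n_voxels), residualised
    subject_contrasts_raw: np.ndarray   # (n_subjects, n_voxels)
    stat_map: StatMap
    group_peak_voxel: int

    def significant(self, alpha: float = 0.05) -> bool:
        return self.stat_map.significant_clusters(alpha).size > 0


@dataclass
class CouplingResult:
    metric: str
    seeds: np.ndarray                   # per-subject seed voxel
    group_peak_voxel: int               # theta-power group peak used for seed search
    subject_contrasts: np.ndarray       # (n_subjects, n_voxels), residualised
    subject_contrasts_raw: np.ndarray
    stat_map: StatMap
    seed_adjacent: np.ndarray           # bool mask: voxel within seed_radius of group peak
    condition_means: np.ndarray         # (n_subjects, n_voxels, 2) [baseline, cue] raw means

    def significant(self, alpha: float = 0.05) -> bool:
        return self.stat_map.significant_clusters(alpha).size > 0

    def consistency(self, voxel: int) -> int:
        """Number of subjects whose raw cue - baseline difference at a voxel is positive."""
        return int(np.sum(self.subject_contrasts_raw[:, voxel] > 0))


# ---------------------------------------------------------------------------
# shared per-subject machinery


def subject_weights(rec: SubjectRecording, windows: ConditionWindows,
                    reg_fraction: float) -> BeamformerWeights:
    """Common-filter LCMV weights from this subject's analysis windows."""
    cov = sensor_covariance(rec.epochs, windows)
    return compute_weights(cov, rec.model, reg_fraction=reg_fraction)


def _source_analytic(weights: BeamformerWeights, epochs: Epochs,
                     band: BandDefinition) -> np.ndarray:
    """Analytic signal of band-passed virtual electrodes, (trials, vox, times).

    Filter and Hilbert-transform at sensor level, then project the complex
    analytic signal (all three operations are linear, so the order is
    immaterial; this ordering is cheapest).
    """
    filtered = bandpass(epochs.data, band, epochs.fs, axis=-1)
    z = analytic(filtered, band, epochs.fs, axis=-1).values
    return project(weights.weights, z)


def _power_rows(source_z: np.ndarray, noise: np.ndarray, slices: dict[str, slice]
                ) -> tuple[np.ndarray, np.ndarray]:
    """Noise-normalised per-trial-window band power rows from analytic source series."""
    n_trials, n_vox = source_z.shape[0], source_z.shape[1]
    rows = np.empty((n_vox, 2 * n_trials))
    conditions = np.empty(2 * n_trials, dtype=object)
    for k, cond in enumerate(("baseline", "cue")):
        sl = slices[cond]
        p = np.mean(source_z.real[:, :, sl] ** 2, axis=2) / noise
        rows[:, k::2] = p.T
        conditions[k::2] = cond
    return rows, conditions


def _contrast_from_rows(rows: np.ndarray, conditions: np.ndarray) -> np.ndarray:
    cue = rows[:, conditions == "cue"].mean(axis=1)
    base = rows[:, conditions == "baseline"].mean(axis=1)
    return cue - base


def subject_band_power(rec: SubjectRecording, band: BandDefinition, cfg: PipelineConfig,
                       weights: BeamformerWeights | None = None,
                       eye_variance: np.ndarray | None = None) -> SubjectPower:
    """One subject's noise-normalised band-power rows and contrast map.

    When ``eye_variance`` (one value per trial-window row) is given and
    residualisation is enabled, the eye covariate is regressed out of the
    per-trial power rows before the condition contrast.
    """
    if weights is None:
        weights = subject_weights(rec, cfg.windows, cfg.reg_fraction)
    slices = cfg.windows.sample_slices(rec.epochs.tmin, rec.epochs.fs, rec.epochs.n_times)
    source_z = _source_analytic(weights, rec.epochs, band)
    rows, conditions = _power_rows(source_z, weights.projected_noise(), slices)
    contrast_raw = _contrast_from_rows(rows, conditions)
    if cfg.residualize and eye_variance is not None:
        resid = residualize_map(rows, eye_variance)
        contrast = _contrast_from_rows(resid, conditions)
    else:
        contrast = contrast_raw
    return SubjectPower(rows=rows, conditions=conditions, contrast_raw=contrast_raw, contrast=contrast)


# ---------------------------------------------------------------------------
# group analyses


def run_power_analysis(dataset: Dataset, band: BandDefinition, cfg: PipelineConfig | None = None,
                       ) -> PowerResult:
    """Group band-power contrast: per-subject maps -> t map -> cluster FWE."""
    cfg = cfg or PipelineConfig()
    contrasts, contrasts_raw = [], []
    for rec in dataset.subjects:
        sp = subject_band_power(rec, band, cfg, eye_variance=rec.truth.eye_variance_rows)
        contrasts.append(sp.contrast)
        contrasts_raw.append(sp.contrast_raw)
    contrasts = np.asarray(contrasts)
    contrasts_raw = np.asarray(contrasts_raw)
    grid = dataset.subjects[0].model.grid_shape
    rng = np.random.default_rng([cfg.rng_seed, 1])
    stat_map = cluster_fwe_permutation(contrasts, grid, cfg.p_voxel, cfg.min_extent,
                                       cfg.n_perm, rng)
    # the group peak is the maximum of the group-average contrast map (the
    # t map is reserved for inference; its argmax can sit on low-variance
    # leakage voxels far from any source)
    peak = int(np.argmax(contrasts_raw.mean(axis=0)))
    return PowerResult(band=band, subject_contrasts=contrasts, subject_contrasts_raw=contrasts_raw,
                       stat_map=stat_map, group_peak_voxel=peak)


def run_coupling_analysis(dataset: Dataset, metric: str, cfg: PipelineConfig | None = None,
                          ) -> CouplingResult:
    """Group seed-based coupling contrast for one metric (plv | pli | pac).

    Stages: per-subject theta power contrast -> group theta peak ->
    per-subject seed voxel (max theta increase within ``seed_radius`` mm
    of the group peak) -> per-trial coupling of seed to every voxel ->
    residualisation against eye variance, seed theta power, and per-voxel
    source power -> per-subject condition contrast -> group cluster
    statistics.  Voxels within the seed search radius of the group peak
    are flagged ``seed_adjacent``: effects there are hard to distinguish
    from leakage of the seed itself.
    """
    cfg = cfg or PipelineConfig()
    if metric not in _coupling.METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    model: SourceModel = dataset.subjects[0].model
    grid = model.grid_shape
    windows = cfg.windows

    # stage 1: weights, theta analytic (cached in single precision -- it is
    # reused for the coupling maps), per-trial theta power, seed selection
    weights_list, theta_zs, theta_rows, theta_contrasts = [], [], [], []
    for rec in dataset.subjects:
        w = subject_weights(rec, windows, cfg.reg_fraction)
        slices = windows.sample_slices(rec.epochs.tmin, rec.epochs.fs, rec.epochs.n_times)
        theta_z = _source_analytic(w, rec.epochs, cfg.theta_band).astype(np.complex64)
        rows, conditions = _power_rows(theta_z, w.projected_noise(), slices)
        weights_list.append(w)
        theta_zs.append(theta_z)
        theta_rows.append(rows)
        theta_contrasts.append(_contrast_from_rows(rows, conditions))
    group_peak = int(np.argmax(np.mean(theta_contrasts, axis=0)))
    seeds = np.array([
        select_seed(c, model.voxel_coords, model.voxel_coords[group_peak], cfg.seed_radius)
        for c in theta_contrasts
    ])

    # stage 2: per-trial coupling maps and confound residualisation
    gamma = cfg.high_gamma_band
    contrasts, contrasts_raw, cond_means = [], [], []
    for rec, w, theta_z, rows, seed in zip(dataset.subjects, weights_list, theta_zs,
                                           theta_rows, seeds):
        slices = windows.sample_slices(rec.epochs.tmin, rec.epochs.fs, rec.epochs.n_times)
        seed_z = theta_z[:, seed, :]
        seed_phasor = seed_z / np.where(np.abs(seed_z) == 0, 1.0, np.abs(seed_z))

        if metric == "pac":
            gamma_z = _source_analytic(w, rec.epochs, gamma)
            env = np.abs(gamma_z)
            env_z = analytic(bandpass(env, cfg.theta_band, rec.epochs.fs), cfg.theta_band,
                             rec.epochs.fs).values
            target_phasor = env_z / np.where(np.abs(env_z) == 0, 1.0, np.abs(env_z))
            source_rows, _ = _power_rows(gamma_z, w.projected_noise(), slices)
        else:
            target_phasor = theta_z / np.where(np.abs(theta_z) == 0, 1.0, np.abs(theta_z))
            source_rows = rows
        cmap: CouplingMap = _coupling.map_from_phasors(seed_phasor, target_phasor, metric,
                                                       slices, int(seed))
        raw = cmap.contrast()
        base_mean = cmap.condition_mean("baseline")
        cue_mean = cmap.condition_mean("cue")
        if cfg.residualize:
            resid = residualize_map(cmap.values, eye_variance=rec.truth.eye_variance_rows,
                                    seed_power=rows[seed], source_power=source_rows)
            contrast = _contrast_from_rows(resid, cmap.conditions)
        else:
            contrast = raw
        contrasts.append(contrast)
        contrasts_raw.append(raw)
        cond_means.append(np.stack([base_mean, cue_mean], axis=-1))

    contrasts = np.asarray(contrasts)
    contrasts_raw = np.asarray(contrasts_raw)
    rng = np.random.default_rng([cfg.rng_seed, 2])
    stat_map = cluster_fwe_permutation(contrasts, grid, cfg.p_voxel, cfg.min_extent,
                                       cfg.n_perm, rng)
    dist = np.linalg.norm(model.voxel_coords - model.voxel_coords[group_peak], axis=1)
    return CouplingResult(
        metric=metric, seeds=seeds, group_peak_voxel=group_peak,
        subject_contrasts=contrasts, subject_contrasts_raw=contrasts_raw,
        stat_map=stat_map, seed_adjacent=dist <= cfg.seed_radius,
        condition_means=np.asarray(cond_means),
    )
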