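"""Group-level statistics on the voxel grid.

Per-subject contrast maps are combined with a one-sample t test per voxel,
thresholded at an uncorrected voxel-wise p (one-sided, testing increases),
grouped into connected clusters (6-connectivity on the 10-mm grid) with a
minimum extent, and the surviving clusters are assigned family-wise-error
corrected p-values by sign-flip permutation of the subject maps: under
the null of symmetrically distributed subject effects, flipping the sign
of whole subject maps is an exchangeability-preserving transformation, and
the maximal null cluster extent across the brain controls FWE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats


@dataclass
class StatMap:
    """Voxel-wise group statistics with cluster annotations.

    t, z : (n_voxels,) statistic maps (z is the standard-normal deviate
        matching the t's upper-tail probability, clipped at |z| = 8).
    df : degrees of freedom (n_subjects - 1).
    cluster_labels : (n_voxels,) int array; 0 = sub-threshold, clusters
        numbered from 1 in decreasing size order.
    cluster_sizes / cluster_pvalues : per-cluster extent (voxels) and
        permutation FWE p (NaN when permutation was not run).
    """

    t: np.ndarray
    z: np.ndarray
    df: int
    grid_shape: tuple[int, int, int]
    p_voxel: float | None = None
    min_extent: int | None = None
    cluster_labels: np.ndarray | None = None
    cluster_sizes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    cluster_pvalues: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    def significant_clusters(self, alpha: float = 0.05) -> np.ndarray:
        """Labels (1-based) of clusters with FWE p below alpha."""
        if self.cluster_pvalues.size == 0:
            return np.array([], dtype=int)
        return np.flatnonzero(self.cluster_pvalues < alpha) + 1


def select_seed(contrast_map: np.ndarray, voxel_coords: np.ndarray,
                group_peak_coord: np.ndarray, radius: float = 20.0) -> int:
    """Subject seed voxel: maximal contrast within ``radius`` mm of the group peak.

    Ties are broken by smaller distance to the group peak, then by lower
    voxel index, so the choice is deterministic.
    """
    coords = np.asarray(voxel_coords, dtype=float)
    contrast = np.asarray(contrast_map, dtype=float)
    dist = np.linalg.norm(coords - np.asarray(group_peak_coord, dtype=float), axis=1)
    inside = np.flatnonzero(dist <= radius)
    if inside.size == 0:
        raise ValueError(f"no voxel within {radius} mm of {group_peak_coord}")
    order = np.lexsort((inside, dist[inside], -contrast[inside]))
    return int(inside[order[0]])


def one_sample_t_map(subject_maps: np.ndarray, grid_shape: tuple[int, int, int]) -> StatMap:
    """Voxel-wise one-sample t test across subjects (mean against zero).

    Voxels with zero variance across subjects have no defined t and are
    masked to NaN with a warning.
    """
    maps = np.asarray(subject_maps, dtype=float)
    if maps.ndim != 2:
        raise ValueError("subject_maps must be (n_subjects, n_voxels)")
    n = maps.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if maps.shape[1] != int(np.prod(grid_shape)):
        raise ValueError("grid_shape does not match number of voxels")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance voxels masked (t undefined)", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, np.nan, mean / (sd / np.sqrt(n)))
    df = n - 1
    z = t_to_z(t, df)
    return StatMap(t=t, z=z, df=df, grid_shape=tuple(grid_shape))


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Standard-normal deviate with the same upper-tail probability as t.

    Clipped at |z| = 8 to avoid infinities far in the tails.
    """
    t = np.asarray(t, dtype=float)
    with np.errstate(invalid="ignore"):
        z = stats.norm.isf(stats.t.sf(t, df))
    return np.clip(z, -8.0, 8.0)


#: faces-only neighbourhood on the 3-D grid
SIX_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)


def cluster_threshold(stat_map: StatMap, p_voxel: float = 0.001, min_extent: int = 10) -> StatMap:
    """Label supra-threshold clusters (one-sided, positive effects).

    Voxels with ``P(T > t) < p_voxel`` are grouped into 6-connected
    components on the grid; components smaller than ``min_extent`` voxels
    are discarded.  Returns the same StatMap with cluster annotations
    filled in (labels renumbered from 1 in decreasing size order).
    """
    if not 0 < p_voxel < 1:
        raise ValueError("p_voxel must be in (0, 1)")
    t_crit = stats.t.isf(p_voxel, stat_map.df)
    supra = np.nan_to_num(stat_map.t, nan=-np.inf) > t_crit
    labels, sizes = _label_clusters(supra.reshape(stat_map.grid_shape), min_extent)
    stat_map.p_voxel = p_voxel
    stat_map.min_extent = min_extent
    stat_map.cluster_labels = labels.ravel()
    stat_map.cluster_sizes = sizes
    stat_map.cluster_pvalues = np.full(len(sizes), np.nan)
    return stat_map


def _label_clusters(supra: np.ndarray, min_extent: int) -> tuple[np.ndarray, np.ndarray]:
    """Connected components of a boolean grid, size-filtered and renumbered."""
    raw, n_raw = ndimage.label(supra, structure=SIX_CONNECTIVITY)
    if n_raw == 0:
        return np.zeros_like(raw), np.array([], dtype=int)
    sizes = np.bincount(raw.ravel())[1:]
    keep = np.flatnonzero(sizes >= min_extent)
    order = keep[np.argsort(-sizes[keep], kind="stable")]
    relabel = np.zeros(n_raw + 1, dtype=int)
    relabel[order + 1] = np.arange(1, len(order) + 1)
    return relabel[raw], sizes[order]


def _max_null_extent(flipped_maps: np.ndarray, t_crit: float, grid_shape: tuple[int, int, int]) -> int:
    n = flipped_maps.shape[0]
    mean = flipped_maps.mean(axis=0)
    sd = flipped_maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd == 0, 0.0, mean / (sd / np.sqrt(n)))
    supra = (t > t_crit).reshape(grid_shape)
    raw, n_raw = ndimage.label(supra, structure=SIX_CONNECTIVITY)
    if n_raw == 0:
        return 0
    return int(np.bincount(raw.ravel())[1:].max())


def cluster_fwe_permutation(subject_maps: np.ndarray, grid_shape: tuple[int, int, int],
                            p_voxel: float = 0.001, min_extent: int = 10,
                            n_perm: int = 1000, rng: np.random.Generator | None = None) -> StatMap:
    """Cluster-level FWE p-values by sign-flip permutation.

    Each permutation flips the sign of whole subject maps, recomputes the
    t map and records the maximal supra-threshold cluster extent anywhere
    on the grid.  An observed cluster's FWE p is
    ``(1 + #{null max extent >= observed extent}) / (n_perm + 1)``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low; p-value resolution is 1/{n_perm + 1}", stacklevel=2)
    maps = np.asarray(subject_maps, dtype=float)
    stat_map = cluster_threshold(one_sample_t_map(maps, grid_shape), p_voxel, min_extent)
    t_crit = stats.t.isf(p_voxel, stat_map.df)
    null_max = np.empty(n_perm, dtype=int)
    n_subj = maps.shape[0]
    for p in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=n_subj)
        null_max[p] = _max_null_extent(maps * flips[:, None], t_crit, tuple(grid_shape))
    pvals = np.array([
        (1 + np.count_nonzero(null_max >= s)) / (n_perm + 1) for s in stat_map.cluster_sizes
    ])
    stat_map.cluster_pvalues = pvals
    return stat_map
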