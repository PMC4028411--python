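"""Per-trial covariate normalisation and confound residualisation.

Coupling estimates are biased by anything that changes the signal-to-noise
ratio between conditions (notably oscillatory power), and frontal sensors
pick up eye movements.  The control strategy: build a table of per-trial
covariates over all 72 trial-windows (36 baseline + 36 cue), z-score each
covariate, and regress it out of the per-trial response by ordinary least
squares, keeping the residuals for the second-level contrast.

The regression is pooled over both conditions and condition is *not* a
regressor -- including it would remove the very effect under test.  Only
variance linearly explained by the covariates is removed; the condition
labels ride along unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def normalize_covariate(values: np.ndarray) -> np.ndarray:
    """Z-score a covariate: (x - mean) / sd, sample sd (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("covariate must be 1-D with at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate covariate: constant input has no variance to normalize")
    return (x - x.mean()) / sd


def _design_matrix(covariates: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        x = covariates.to_numpy(dtype=float)
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = [f"x{j}" for j in range(x.shape[1])]
    return x, names


def residualize(response: np.ndarray, covariates: pd.DataFrame | np.ndarray) -> np.ndarray:
    """OLS residuals of a per-trial response on covariates plus intercept.

    Fitted across all trial-windows pooled over conditions.  ``response``
    may be 1-D (n_trials,) or 2-D (n_trials, n_responses); each response
    column is residualised against the same design.

    Raises on rank-deficient designs, naming the collinear columns.
    """
    y = np.asarray(response, dtype=float)
    one_d = y.ndim == 1
    if one_d:
        y = y[:, None]
    x, names = _design_matrix(covariates)
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"{y.shape[0]} responses but {x.shape[0]} covariate rows")
    n, k = x.shape
    if n <= k + 1:
        raise ValueError(f"need more trials ({n}) than covariates + intercept ({k + 1})")
    design = np.column_stack([np.ones(n), x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by testing each against the preceding ones
        bad = []
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : j + 1]) == np.linalg.matrix_rank(design[:, :j]):
                bad.append(names[j - 1])
        raise ValueError(f"rank-deficient design: collinear columns {bad}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return resid[:, 0] if one_d else resid


def build_confound_table(eye_variance: np.ndarray, conditions: np.ndarray,
                         seed_power: np.ndarray | None = None,
                         source_power: np.ndarray | None = None) -> pd.DataFrame:
    """Assemble and z-score the per-trial covariate table.

    One row per trial-window (72 rows for 36 trials x 2 conditions).
    ``source_power`` is the power at one target voxel; coupling analyses
    rebuild the table per voxel.  All covariates are normalised to mean 0,
    sd 1 across the pooled rows; the condition column is a label only and
    never enters the regression design.
    """
    table = pd.DataFrame({"eye_variance": normalize_covariate(eye_variance)})
    if seed_power is not None:
        table["seed_power"] = normalize_covariate(seed_power)
    if source_power is not None:
        table["source_power"] = normalize_covariate(source_power)
    table["condition"] = np.asarray(conditions, dtype=object)
    return table


def residualize_map(values: np.ndarray, eye_variance: np.ndarray,
                    seed_power: np.ndarray | None = None,
                    source_power: np.ndarray | None = None) -> np.ndarray:
    """Residualise per-trial values at every voxel.

    values : (n_voxels, n_rows) per-trial coupling or power values.
    source_power : optional (n_voxels, n_rows) per-voxel power covariate,
        fitted independently per voxel (each voxel's regression gets its
        own source-power column).
    """
    values = np.asarray(values, dtype=float)
    n_vox, n_rows = values.shape
    common = [normalize_covariate(eye_variance)]
    if seed_power is not None:
        common.append(normalize_covariate(seed_power))
    common_x = np.column_stack(common)
    if source_power is None:
        return residualize(values.T, common_x).T
    out = np.empty_like(values)
    for v in range(n_vox):
        x = np.column_stack([common_x, normalize_covariate(source_power[v])])
        try:
            out[v] = residualize(values[v], x)
        except ValueError:
            # at the seed voxel itself the source-power column duplicates
            # the seed-power covariate; drop the redundant column
            out[v] = residualize(values[v], common_x)
    return out
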