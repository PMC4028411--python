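"""Dataset and result serialisation.

Simulated cohorts go to a self-describing HDF5 container (epochs, lead
fields, ground truth per subject; the config as root attributes), ground
truth additionally to CSV, configs to plain-text ``key = value`` files,
and statistical maps to NIfTI volumes whose affine encodes the 10-mm grid
spacing in MNI-like mm coordinates.
"""

from __future__ import annotations

import ast
import dataclasses
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .beamformer import SourceModel
from .containers import Epochs
from .groupstats import StatMap
from .synth import Dataset, SimConfig, SubjectGroundTruth, SubjectRecording


def write_config(config: SimConfig, path: str | Path) -> None:
    """Plain-text ``key = value`` dump of a simulation config."""
    lines = [f"{f.name} = {getattr(config, f.name)!r}" for f in dataclasses.fields(config)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> SimConfig:
    values = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, raw = line.partition("=")
        values[key.strip()] = ast.literal_eval(raw.strip())
    return SimConfig(**values)


def _config_to_attrs(config: SimConfig, attrs: h5py.AttributeManager) -> None:
    for f in dataclasses.fields(config):
        attrs[f.name] = repr(getattr(config, f.name))


def _config_from_attrs(attrs: h5py.AttributeManager) -> SimConfig:
    return SimConfig(**{k: ast.literal_eval(v) for k, v in attrs.items()})


def save_dataset(dataset: Dataset, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        _config_to_attrs(dataset.config, h5.attrs)
        for rec in dataset.subjects:
            g = h5.create_group(f"subjects/s{rec.truth.subject_id:02d}")
            g.create_dataset("epochs", data=rec.epochs.data, compression="gzip", shuffle=True)
            g.attrs["fs"] = rec.epochs.fs
            g.attrs["tmin"] = rec.epochs.tmin
            g.create_dataset("leadfield", data=rec.model.leadfield)
            g.create_dataset("voxel_coords", data=rec.model.voxel_coords)
            g.attrs["grid_shape"] = rec.model.grid_shape
            t = g.create_group("truth")
            for name in ("seed_voxel", "coupled_voxel", "pac_voxel"):
                t.attrs[name] = getattr(rec.truth, name)
            for name in ("power_ratio", "kappa_baseline", "kappa_cue",
                         "pac_depth_baseline", "pac_depth_cue"):
                t.attrs[name] = getattr(rec.truth, name)
            t.create_dataset("artifact_variance", data=rec.truth.artifact_variance)
            t.create_dataset("eye_variance_rows", data=rec.truth.eye_variance_rows)


def load_dataset(path: str | Path) -> Dataset:
    subjects = []
    with h5py.File(path, "r") as h5:
        config = _config_from_attrs(h5.attrs)
        for key in sorted(h5["subjects"]):
            g = h5[f"subjects/{key}"]
            epochs = Epochs(data=g["epochs"][()], fs=float(g.attrs["fs"]), tmin=float(g.attrs["tmin"]))
            model = SourceModel(voxel_coords=g["voxel_coords"][()], leadfield=g["leadfield"][()],
                                grid_shape=tuple(int(x) for x in g.attrs["grid_shape"]))
            t = g["truth"]
            truth = SubjectGroundTruth(
                subject_id=int(key[1:]),
                seed_voxel=int(t.attrs["seed_voxel"]),
                coupled_voxel=int(t.attrs["coupled_voxel"]),
                pac_voxel=int(t.attrs["pac_voxel"]),
                power_ratio=float(t.attrs["power_ratio"]),
                kappa_baseline=float(t.attrs["kappa_baseline"]),
                kappa_cue=float(t.attrs["kappa_cue"]),
                pac_depth_baseline=float(t.attrs["pac_depth_baseline"]),
                pac_depth_cue=float(t.attrs["pac_depth_cue"]),
                artifact_variance=t["artifact_variance"][()],
                eye_variance_rows=t["eye_variance_rows"][()],
            )
            subjects.append(SubjectRecording(epochs=epochs, model=model, truth=truth))
    return Dataset(config=config, subjects=subjects)


def grid_affine(voxel_coords: np.ndarray, grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Affine mapping voxel ijk indices to mm coordinates of the grid."""
    coords = np.asarray(voxel_coords).reshape(*grid_shape, 3)
    origin = coords[0, 0, 0]
    affine = np.eye(4)
    for ax in range(3):
        step = np.zeros(3)
        if grid_shape[ax] > 1:
            idx = [0, 0, 0]
            idx[ax] = 1
            step = coords[tuple(idx)] - origin
        else:
            step[ax] = 1.0
        affine[:3, ax] = step
    affine[:3, 3] = origin
    return affine


def save_map_nifti(values: np.ndarray, voxel_coords: np.ndarray,
                   grid_shape: tuple[int, int, int], path: str | Path) -> None:
    """One per-voxel map as a NIfTI volume on the grid."""
    vol = np.asarray(values, dtype=np.float64).reshape(grid_shape)
    img = nib.Nifti1Image(vol, grid_affine(voxel_coords, grid_shape))
    nib.save(img, str(path))


def save_statmap_nifti(stat_map: StatMap, voxel_coords: np.ndarray, prefix: str | Path) -> None:
    """t, z, and cluster-label volumes with a common filename prefix."""
    prefix = str(prefix)
    save_map_nifti(stat_map.t, voxel_coords, stat_map.grid_shape, prefix + "_tmap.nii.gz")
    save_map_nifti(stat_map.z, voxel_coords, stat_map.grid_shape, prefix + "_zmap.nii.gz")
    if stat_map.cluster_labels is not None:
        save_map_nifti(stat_map.cluster_labels.astype(float), voxel_coords,
                       stat_map.grid_shape, prefix + "_clusters.nii.gz")
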