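"""NIfTI I/O helpers for the voxel-level path.

The pipeline's native currency is the regional signal matrix; these helpers
bridge to volumetric inputs: loading 4-D runs, tissue-probability maps and
label atlases with nibabel, extracting label-averaged regional series, and
emitting a synthetic run as a 4-D image (each region rendered as a small
voxel block) for testing volumetric tooling. Registration and realignment
are upstream concerns and not handled here.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .preprocess import RegionalRun


def load_volumes(path: str | Path) -> np.ndarray:
    """Load a 4-D NIfTI run as a float array (x, y, z, t)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D run, got shape {data.shape}")
    return data


def load_labels(path: str | Path) -> np.ndarray:
    """Load a 3-D integer label atlas (0 = background)."""
    data = np.asarray(nib.load(str(path)).dataobj)
    return np.rint(data).astype(int)


def load_probability_map(path: str | Path) -> np.ndarray:
    """Load a 3-D tissue-probability map, validated to [0, 1]."""
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if data.min() < 0 or data.max() > 1:
        raise ValueError(f"{path}: probabilities outside [0, 1]")
    return data


def extract_regional_series(
    volumes: np.ndarray, labels: np.ndarray, tr: float
) -> RegionalRun:
    """Average voxel time courses within each atlas label.

    ``volumes`` is (x, y, z, t); ``labels`` a matching 3-D label image
    (0 = background, dropped). Returns a run with one row per present label,
    label order.
    """
    if volumes.shape[:3] != labels.shape:
        raise ValueError("volumes and labels must share the spatial shape")
    flat = volumes.reshape(-1, volumes.shape[-1])
    lab = labels.reshape(-1)
    region_ids = np.unique(lab[lab != 0])
    signals = np.stack([flat[lab == r].mean(axis=0) for r in region_ids])
    return RegionalRun(signals=signals, tr=tr, region_ids=region_ids)


def save_synthetic_run(
    run: RegionalRun, path: str | Path, voxels_per_region: int = 2
) -> np.ndarray:
    """Emit a regional run as a 4-D NIfTI and its matching label image.

    Each region becomes ``voxels_per_region`` voxels carrying its signal, laid
    out along one axis; a companion ``*_labels`` image holds the atlas. This
    is a synthetic voxelization for exercising volumetric tooling, not a
    spatial model. Returns the label volume.
    """
    path = Path(path)
    n_reg, n_vol = run.signals.shape
    vol = np.repeat(run.signals, voxels_per_region, axis=0).reshape(
        n_reg * voxels_per_region, 1, 1, n_vol
    )
    labels = np.repeat(np.asarray(run.region_ids), voxels_per_region).reshape(-1, 1, 1)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(vol, affine), str(path))
    label_path = path.with_name(path.name.replace(".nii", "_labels.nii"))
    nib.save(nib.Nifti1Image(labels.astype(np.int16), affine), str(label_path))
    return labels
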