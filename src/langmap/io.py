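"""NIfTI-1 reading/writing helpers.

All phantom volumes live on an isotropic grid; the affine is a plain scaling by
the voxel size (mm) with the origin at the grid corner. ``x`` is the first axis
and the left hemisphere is the lower-x half of the grid by convention.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np


def grid_affine(voxel_size_mm: float) -> np.ndarray:
    """Affine mapping voxel indices to mm for an isotropic grid."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = float(voxel_size_mm)
    return aff


def save_volume(path: str | os.PathLike, data: np.ndarray, voxel_size_mm: float = 3.0,
                affine: np.ndarray | None = None) -> None:
    """Write a 3D or 4D array as NIfTI-1 (.nii or .nii.gz by extension)."""
    if affine is None:
        affine = grid_affine(voxel_size_mm)
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms((voxel_size_mm,) * 3 + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, os.fspath(path))


def load_volume(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI-1 file; returns (data, affine)."""
    img = nib.load(os.fspath(path))
    return np.asarray(img.dataobj), img.affine
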