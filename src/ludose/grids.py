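"""Light-weight NIfTI I/O for isotropic voxel grids.

All volumes of one study share a single isotropic geometry; downstream
stages never resample, so geometry mismatches are hard errors.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["save_volume", "load_volume", "check_same_geometry"]


def save_volume(array: np.ndarray, voxel_size_mm: float, path) -> None:
    """Write a 3D array as NIfTI with an isotropic affine."""
    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(array), affine)
    img.header.set_zooms((voxel_size_mm,) * 3)
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, float]:
    """Read a NIfTI volume; returns (array, isotropic voxel size in mm)."""
    img = nib.load(str(Path(path)))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-5):
        raise ValueError(f"{path}: anisotropic voxels {zooms} are not supported")
    return np.asarray(img.dataobj, dtype=np.float64), float(zooms[0])


def check_same_geometry(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"geometry mismatch between volumes: {sorted(shapes)}")
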