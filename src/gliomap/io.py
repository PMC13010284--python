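"""NIfTI volume I/O helpers."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["read_volume", "write_volume"]


def write_volume(data: np.ndarray, path: str | Path,
                 voxel_size_mm=(1.0, 1.0, 1.0), affine: np.ndarray | None = None) -> Path:
    """Write a 3D array as NIfTI-1; the affine defaults to diag(voxel sizes)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), path)
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 3D NIfTI volume; returns (data, voxel sizes in mm)."""
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {img.ndim}D")
    data = np.asanyarray(img.dataobj)
    return data, tuple(float(z) for z in img.header.get_zooms()[:3])


def check_same_grid(a_path: str | Path, b_path: str | Path) -> None:
    a, za = read_volume(a_path)
    b, zb = read_volume(b_path)
    if a.shape != b.shape or not np.allclose(za, zb):
        raise ValueError(f"grid mismatch between {a_path} ({a.shape}, {za}) "
                         f"and {b_path} ({b.shape}, {zb})")
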