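"""NIfTI-1 volume I/O.

All pipeline volumes live on one shared voxel grid (inputs are assumed
co-registered to a common template space); voxel sizes are carried in the
NIfTI header and propagate into distance computations.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["read_volume", "write_volume"]


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 3D NIfTI volume; returns (data, voxel sizes in mm)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"expected 3D volume, got {data.ndim}D with shape {data.shape}: {path}"
        )
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(data), zooms


def write_volume(data: np.ndarray, path, voxel_size_mm=(1.0, 1.0, 1.0), dtype=np.float32) -> None:
    """Write a 3D array as NIfTI-1 with the given voxel sizes on the diagonal."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got shape {data.shape}")
    voxel_size_mm = tuple(float(v) for v in np.broadcast_to(voxel_size_mm, (3,)))
    affine = np.diag([*voxel_size_mm, 1.0])
    img = nib.Nifti1Image(data.astype(dtype), affine)
    img.header.set_zooms(voxel_size_mm)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
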