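"""NIfTI volume I/O.

Arrays are handled in ``(z, y, x)`` index order with per-axis ``spacing``
in mm; on disk the NIfTI data axes are ``(x, y, z)`` with the spacing in
the affine, so round-trips preserve both data and geometry.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

__all__ = ["save_volume", "load_volume"]


def save_volume(path, data: np.ndarray, spacing) -> None:
    """Write a ``(z, y, x)`` array as NIfTI with ``spacing`` (mm)."""
    arr = np.asarray(data)
    if arr.ndim != 3:
        raise ValueError("expected a 3D volume")
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    sz, sy, sx = (float(s) for s in spacing)
    affine = np.diag([sx, sy, sz, 1.0])
    nib.save(nib.Nifti1Image(np.ascontiguousarray(arr.T), affine), path)


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI file; returns ``(data_zyx, spacing_zyx)``."""
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume")
    zooms = img.header.get_zooms()[:3]
    return data.T, (float(zooms[2]), float(zooms[1]), float(zooms[0]))
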