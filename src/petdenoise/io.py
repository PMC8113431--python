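"""Volume I/O: NIfTI is the canonical on-disk format.

Arrays are kept in (slice, row, col) order in memory; on disk the NIfTI
axes are (col, row, slice) with the voxel size in the header zooms, so
write-then-read is a lossless roundtrip of values and geometry.
"""

from __future__ import annotations

from typing import Tuple, Union

import nibabel as nib
import numpy as np

from .phantom import SUVVolume

__all__ = ["read_volume", "write_volume", "FormatError"]


class FormatError(ValueError):
    """Malformed or unsupported volume file."""


def write_volume(
    volume: Union[SUVVolume, np.ndarray],
    path,
    voxel_size: Tuple[float, float, float] = None,
) -> None:
    """Write a volume to NIfTI with voxel geometry in the header."""
    if isinstance(volume, SUVVolume):
        values, voxel_size = volume.values, volume.voxel_size
    else:
        values = np.asarray(volume)
        if voxel_size is None:
            raise ValueError("voxel_size is required when writing a bare array")
    if values.ndim != 3:
        raise FormatError(f"expected a 3-D volume, got {values.ndim}-D")
    vz, vy, vx = voxel_size
    affine = np.diag([vx, vy, vz, 1.0])
    img = nib.Nifti1Image(np.asarray(values.T, dtype=np.float64), affine)
    img.header.set_zooms((vx, vy, vz))
    nib.save(img, str(path))


def read_volume(path, label: str = "") -> SUVVolume:
    """Read a NIfTI volume back into (slice, row, col) order."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(
            f"expected a 3-D volume, file has dimension {data.ndim}"
        )
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError("header field 'pixdim' has non-positive voxel sizes")
    voxel_size = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return SUVVolume(
        values=np.asarray(data.T, dtype=np.float64),
        voxel_size=voxel_size,
        label=label,
    )
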