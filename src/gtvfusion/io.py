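"""Reading and writing binary masks as NIfTI-1 or NRRD volumes.

Files are decoded through SimpleITK.  Any nonzero voxel is foreground; masks
are written back as 8-bit integer volumes with foreground 1.  Only
axis-aligned volumes are supported: direction matrices must be diagonal with
entries +/-1 (flipped axes are reoriented on load so that in-memory grids
always have positive spacing along +z, +y, +x).
"""

from __future__ import annotations

import os

import numpy as np
import SimpleITK as sitk

from .grid import BinaryMask, VoxelGrid

__all__ = ["MaskFormatError", "read_mask", "write_mask"]

_FORMAT_IO = {"nifti": "NiftiImageIO", "nrrd": "NrrdImageIO"}


class MaskFormatError(ValueError):
    """Raised when a volume file cannot be decoded as an axis-aligned 3D mask."""


def _infer_format(path: str) -> str:
    lower = str(path).lower()
    if lower.endswith((".nii", ".nii.gz")):
        return "nifti"
    if lower.endswith((".nrrd", ".nhdr")):
        return "nrrd"
    raise MaskFormatError(f"cannot infer volume format from extension of {path!r}")


def read_mask(path: str, format: str | None = None) -> BinaryMask:
    """Read a 3D scalar volume as a binary mask (nonzero => foreground).

    Parameters
    ----------
    path
        A ``.nii``/``.nii.gz`` or ``.nrrd`` file.
    format
        ``"nifti"`` or ``"nrrd"``; inferred from the extension when omitted.
    """
    fmt = format or _infer_format(path)
    if fmt not in _FORMAT_IO:
        raise MaskFormatError(f"unsupported format {fmt!r}; expected one of {sorted(_FORMAT_IO)}")
    if not os.path.exists(path):
        raise MaskFormatError(f"no such file: {path}")
    reader = sitk.ImageFileReader()
    reader.SetImageIO(_FORMAT_IO[fmt])
    reader.SetFileName(str(path))
    try:
        image = reader.Execute()
    except RuntimeError as exc:  # ITK wraps decode failures in RuntimeError
        raise MaskFormatError(f"unreadable {fmt} file {path!r}: {exc}") from exc
    if image.GetDimension() != 3:
        raise MaskFormatError(
            f"{path!r}: expected a 3D payload, got dimension {image.GetDimension()}"
        )
    if image.GetNumberOfComponentsPerPixel() != 1:
        raise MaskFormatError(f"{path!r}: expected a scalar volume")
    spacing_xyz = image.GetSpacing()
    if any(s <= 0 for s in spacing_xyz):
        raise MaskFormatError(f"{path!r}: spacing must be positive, got {spacing_xyz}")

    direction = np.asarray(image.GetDirection(), dtype=float).reshape(3, 3)
    if not np.allclose(np.abs(direction), np.eye(3), atol=1e-6):
        raise MaskFormatError(
            f"{path!r}: direction matrix is not axis-aligned (diagonal +/-1): {direction.tolist()}"
        )
    signs_xyz = np.sign(np.diag(direction))

    values = sitk.GetArrayFromImage(image) != 0  # (z, y, x)
    origin_xyz = list(image.GetOrigin())
    # Reorient flipped axes so the in-memory grid increases along +z, +y, +x.
    for axis_xyz in range(3):
        if signs_xyz[axis_xyz] < 0:
            axis_zyx = 2 - axis_xyz
            n = values.shape[axis_zyx]
            values = np.flip(values, axis=axis_zyx)
            origin_xyz[axis_xyz] -= spacing_xyz[axis_xyz] * (n - 1)
    grid = VoxelGrid(
        shape=values.shape,
        spacing_mm=(spacing_xyz[2], spacing_xyz[1], spacing_xyz[0]),
        origin_mm=(origin_xyz[2], origin_xyz[1], origin_xyz[0]),
    )
    return BinaryMask(grid, np.ascontiguousarray(values))


def write_mask(mask: BinaryMask, path: str, format: str | None = None) -> str:
    """Write a mask as an 8-bit volume (foreground 1); returns the path."""
    fmt = format or _infer_format(path)
    if fmt not in _FORMAT_IO:
        raise MaskFormatError(f"unsupported format {fmt!r}; expected one of {sorted(_FORMAT_IO)}")
    image = sitk.GetImageFromArray(mask.values.astype(np.uint8))
    sz, sy, sx = mask.grid.spacing_mm
    oz, oy, ox = mask.grid.origin_mm
    image.SetSpacing((sx, sy, sz))
    image.SetOrigin((ox, oy, oz))
    writer = sitk.ImageFileWriter()
    writer.SetImageIO(_FORMAT_IO[fmt])
    writer.SetFileName(str(path))
    try:
        writer.Execute(image)
    except RuntimeError as exc:
        raise MaskFormatError(f"cannot write {fmt} file {path!r}: {exc}") from exc
    return str(path)
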