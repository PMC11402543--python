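"""Voxel-grid geometry and binary-mask algebra.

Every stage of the pipeline trades in :class:`BinaryMask` objects living on a
:class:`VoxelGrid` — a regular, axis-aligned 3D lattice with (possibly
anisotropic) spacing in millimetres.  Conventions used throughout:

* axis order is ``(slice, row, col)`` = ``(z, y, x)``, 0-based indices;
* a voxel occupies the point at its *center*: the physical position of index
  ``(k, j, i)`` is ``origin + (k, j, i) * spacing``;
* nearest-neighbour index lookups round half-way points away from zero, so a
  point exactly mid-way between two voxel centers resolves to the center with
  the larger absolute coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelGrid",
    "BinaryMask",
    "GridMismatchError",
    "resample_nearest",
    "mask_union",
    "mask_intersection",
    "crop_to_support",
    "mask_volume_ml",
    "shift_mask",
]


class GridMismatchError(ValueError):
    """Raised when an operation requires masks on a common grid."""


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero."""
    return np.trunc(x + np.copysign(0.5, x))


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a regular axis-aligned 3D lattice.

    Parameters
    ----------
    shape
        Number of voxels per axis, ``(slices, rows, cols)``.
    spacing_mm
        Voxel pitch per axis in mm, ``(z, y, x)``; all entries positive.
    origin_mm
        Physical position of the center of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be three entries >= 1, got {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"grid spacing must be three positive entries, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        return self.origin_mm[axis] + np.arange(self.shape[axis]) * self.spacing_mm[axis]

    def isclose(self, other: "VoxelGrid", tol_mm: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=tol_mm)
            and np.allclose(self.origin_mm, other.origin_mm, atol=tol_mm)
        )


@dataclass
class BinaryMask:
    """Boolean field on a :class:`VoxelGrid`; the pipeline's universal currency."""

    grid: VoxelGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.shape != self.grid.shape:
            raise ValueError(
                f"mask values shape {values.shape} does not match grid shape {self.grid.shape}"
            )
        self.values = values.astype(bool, copy=False)

    @classmethod
    def empty(cls, grid: VoxelGrid) -> "BinaryMask":
        return cls(grid, np.zeros(grid.shape, dtype=bool))

    @classmethod
    def full(cls, grid: VoxelGrid) -> "BinaryMask":
        return cls(grid, np.ones(grid.shape, dtype=bool))

    @property
    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.values.sum())

    @property
    def volume_ml(self) -> float:
        return self.count * self.grid.voxel_volume_mm3 / 1000.0

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.grid, self.values.copy())

    def same_values(self, other: "BinaryMask") -> bool:
        return self.grid.isclose(other.grid) and bool(np.array_equal(self.values, other.values))


def _require_common_grid(masks: list[BinaryMask], what: str) -> VoxelGrid:
    grid = masks[0].grid
    for m in masks[1:]:
        if not grid.isclose(m.grid):
            raise GridMismatchError(f"{what} requires masks on one grid; got {grid} vs {m.grid}")
    return grid


def resample_nearest(mask: BinaryMask, reference: VoxelGrid) -> BinaryMask:
    """Resample a mask onto ``reference`` by nearest voxel center.

    Each output voxel takes the value of the input voxel whose center is
    nearest (in physical mm) to the output voxel's center; output voxels whose
    nearest input center lies outside the input lattice are background.
    Resampling onto the mask's own grid is the identity.
    """
    if mask.grid.isclose(reference):
        return mask.copy()
    index_arrays = []
    valid = None
    for axis in range(3):
        centers = reference.voxel_centers(axis)
        frac = (centers - mask.grid.origin_mm[axis]) / mask.grid.spacing_mm[axis]
        idx = _round_half_away(frac).astype(np.int64)
        ok = (idx >= 0) & (idx < mask.grid.shape[axis])
        idx = np.clip(idx, 0, mask.grid.shape[axis] - 1)
        shape = [1, 1, 1]
        shape[axis] = -1
        index_arrays.append(idx.reshape(shape))
        ok = ok.reshape(shape)
        valid = ok if valid is None else (valid & ok)
    out = mask.values[index_arrays[0], index_arrays[1], index_arrays[2]] & valid
    return BinaryMask(reference, out)


def mask_union(masks: list[BinaryMask]) -> BinaryMask:
    """Voxelwise logical OR of masks sharing one grid."""
    if not masks:
        raise ValueError("mask_union of an empty list")
    grid = _require_common_grid(masks, "mask_union")
    out = np.zeros(grid.shape, dtype=bool)
    for m in masks:
        out |= m.values
    return BinaryMask(grid, out)


def mask_intersection(masks: list[BinaryMask]) -> BinaryMask:
    """Voxelwise logical AND of masks sharing one grid."""
    if not masks:
        raise ValueError("mask_intersection of an empty list")
    grid = _require_common_grid(masks, "mask_intersection")
    out = np.ones(grid.shape, dtype=bool)
    for m in masks:
        out &= m.values
    return BinaryMask(grid, out)


def crop_to_support(mask: BinaryMask, support: BinaryMask) -> BinaryMask:
    """Restrict a mask to the region where ground truth is available.

    Voxelwise AND with ``support``; used to exclude regions without
    histopathology coverage from every comparison.
    """
    return mask_intersection([mask, support])


def mask_volume_ml(mask: BinaryMask) -> float:
    """Foreground volume in millilitres (count x voxel volume / 1000)."""
    return mask.volume_ml


def shift_mask(mask: BinaryMask, translation_mm: tuple[float, ...]) -> BinaryMask:
    """Translate mask content by a physical offset, nearest-neighbour resampled.

    ``translation_mm`` is ``(dy, dx)`` for an in-plane shift or ``(dz, dy, dx)``
    for a 3D shift.  The output voxel at physical point ``x`` takes the input
    value at ``x - t``; content shifted beyond the lattice is lost.  Because
    the lattice is uniform this reduces to an integer voxel shift of
    ``round(t / spacing)`` per axis (halves away from zero).
    """
    if len(translation_mm) == 2:
        t = (0.0, float(translation_mm[0]), float(translation_mm[1]))
    elif len(translation_mm) == 3:
        t = tuple(float(v) for v in translation_mm)
    else:
        raise ValueError("translation must be (dy, dx) or (dz, dy, dx)")
    steps = tuple(
        int(_round_half_away(np.asarray(t[a] / mask.grid.spacing_mm[a]))) for a in range(3)
    )
    return integer_shift(mask, steps)


def integer_shift(mask: BinaryMask, steps: tuple[int, int, int]) -> BinaryMask:
    """Shift mask content by whole voxels; out-of-lattice content is dropped."""
    out = np.zeros(mask.grid.shape, dtype=bool)
    src = []
    dst = []
    for axis, k in enumerate(steps):
        n = mask.grid.shape[axis]
        if abs(k) >= n:
            return BinaryMask(mask.grid, out)
        if k >= 0:
            src.append(slice(0, n - k))
            dst.append(slice(k, n))
        else:
            src.append(slice(-k, n))
            dst.append(slice(0, n + k))
    out[tuple(dst)] = mask.values[tuple(src)]
    return BinaryMask(mask.grid, out)
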