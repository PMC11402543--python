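"""Ground-truth lesion construction from per-slice histopathology delineations.

Whole-mount histopathology yields, per axial slice, one or more delineated
tumour foci annotated with a Gleason pattern (3, 4 or 5).  Delineations that
overlap in-plane on *consecutive* slices belong to the same lesion; a gap
slice breaks the chain.  The validation target is the dominant high-grade
lesion: the largest lesion by Gleason-pattern-4/5 volume, restricted to its
pattern-4/5 voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .grid import BinaryMask, VoxelGrid

__all__ = [
    "SliceDelineation",
    "LesionLabeling",
    "merge_lesions_z",
    "target_lesion_mask",
    "read_slice_delineations",
    "write_slice_delineations",
]


@dataclass
class SliceDelineation:
    """One delineated focus on one histopathology slice."""

    slice_index: int
    region: np.ndarray = field(repr=False)  # 2D bool, (rows, cols) of the reference grid
    gleason_pattern: int

    def __post_init__(self) -> None:
        self.region = np.asarray(self.region).astype(bool, copy=False)
        if self.region.ndim != 2:
            raise ValueError("region must be a 2D boolean field")
        if self.gleason_pattern not in (3, 4, 5):
            raise ValueError(f"Gleason pattern must be 3, 4 or 5, got {self.gleason_pattern}")


@dataclass
class LesionLabeling:
    """Integer lesion-id field on the reference grid (0 = background)."""

    grid: VoxelGrid
    labels: np.ndarray = field(repr=False)
    lesion_count: int
    #: lesion id assigned to each input delineation, parallel to the input list
    delineation_lesion: list[int] = field(default_factory=list)


def _check_slices(delineations: list[SliceDelineation], grid: VoxelGrid) -> None:
    for d in delineations:
        if not 0 <= d.slice_index < grid.shape[0]:
            raise ValueError(
                f"slice index {d.slice_index} out of range for grid with {grid.shape[0]} slices"
            )
        if d.region.shape != grid.shape[1:]:
            raise ValueError(
                f"region shape {d.region.shape} does not match grid in-plane shape {grid.shape[1:]}"
            )


def merge_lesions_z(delineations: list[SliceDelineation], grid: VoxelGrid) -> LesionLabeling:
    """Merge per-slice delineations into 3D lesions by consecutive-slice overlap.

    Two delineations share a lesion id iff they are connected by a chain of
    pairs on consecutive slices whose regions share at least one in-plane
    voxel.  Delineations on the same slice stay distinct unless bridged
    through another slice; identical regions two slices apart with nothing in
    between are distinct lesions.

    Lesion ids are 1-based and assigned in order of each lesion's first
    delineation in the input list.  Where delineations of different lesions
    overlap on the same voxel (possible for same-slice foci), the later
    delineation in the input list wins in the voxel labelling.
    """
    if not delineations:
        raise ValueError("merge_lesions_z requires at least one delineation")
    _check_slices(delineations, grid)
    n = len(delineations)
    by_slice: dict[int, list[int]] = {}
    for idx, d in enumerate(delineations):
        by_slice.setdefault(d.slice_index, []).append(idx)
    rows, cols = [], []
    for z, idxs in by_slice.items():
        for i in idxs:
            for j in by_slice.get(z + 1, []):
                if np.any(delineations[i].region & delineations[j].region):
                    rows.append(i)
                    cols.append(j)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, comp = connected_components(adj, directed=False)

    # renumber components by first appearance in the input order
    order: dict[int, int] = {}
    for c in comp:
        if c not in order:
            order[c] = len(order) + 1
    lesion_of = [order[c] for c in comp]

    labels = np.zeros(grid.shape, dtype=np.int32)
    for idx, d in enumerate(delineations):
        labels[d.slice_index][d.region] = lesion_of[idx]
    return LesionLabeling(
        grid=grid, labels=labels, lesion_count=n_comp, delineation_lesion=lesion_of
    )


def target_lesion_mask(
    labeling: LesionLabeling,
    delineations: list[SliceDelineation],
    grade_filter: frozenset[int] | set[int] = frozenset({4, 5}),
) -> BinaryMask:
    """High-grade voxels of the dominant lesion.

    Restricts each lesion to the voxels covered by delineations whose Gleason
    pattern is in ``grade_filter`` (default {4, 5}) and returns the lesion
    with the largest such volume.
    """
    if not grade_filter:
        raise ValueError("grade_filter must be nonempty")
    if len(labeling.delineation_lesion) != len(delineations):
        raise ValueError("labeling does not correspond to the given delineations")
    grid = labeling.grid
    graded = np.zeros(grid.shape, dtype=bool)
    for idx, d in enumerate(delineations):
        if d.gleason_pattern in grade_filter:
            graded[d.slice_index] |= d.region
    counts = np.bincount(
        (labeling.labels[graded]).ravel(), minlength=labeling.lesion_count + 1
    )
    counts[0] = 0
    if counts.sum() == 0:
        raise ValueError(f"no lesion contains voxels with Gleason pattern in {sorted(grade_filter)}")
    dominant = int(counts.argmax())
    return BinaryMask(grid, graded & (labeling.labels == dominant))


def write_slice_delineations(
    delineations: list[SliceDelineation], grid: VoxelGrid, volume_path: str, table_path: str
) -> None:
    """Store delineations as a multi-label volume plus a CSV sidecar table.

    Each delineation gets a distinct positive label in the volume; the CSV has
    columns ``label, slice, gleason_pattern``.  Overlapping delineations are
    resolved in favour of the later one, matching the labelling convention of
    :func:`merge_lesions_z`.
    """
    from .io import write_mask  # local import to avoid cycle at module load

    _check_slices(delineations, grid)
    volume = np.zeros(grid.shape, dtype=np.int16)
    records = []
    for idx, d in enumerate(delineations, start=1):
        volume[d.slice_index][d.region] = idx
        records.append({"label": idx, "slice": d.slice_index, "gleason_pattern": d.gleason_pattern})
    import SimpleITK as sitk

    image = sitk.GetImageFromArray(volume)
    sz, sy, sx = grid.spacing_mm
    oz, oy, ox = grid.origin_mm
    image.SetSpacing((sx, sy, sz))
    image.SetOrigin((ox, oy, oz))
    sitk.WriteImage(image, str(volume_path))
    pd.DataFrame.from_records(records).to_csv(table_path, index=False)


def read_slice_delineations(volume_path: str, table_path: str) -> tuple[list[SliceDelineation], VoxelGrid]:
    """Inverse of :func:`write_slice_delineations` (up to overlap resolution)."""
    import SimpleITK as sitk

    image = sitk.ReadImage(str(volume_path))
    volume = sitk.GetArrayFromImage(image)
    sx, sy, sz = image.GetSpacing()
    ox, oy, oz = image.GetOrigin()
    grid = VoxelGrid(shape=volume.shape, spacing_mm=(sz, sy, sx), origin_mm=(oz, oy, ox))
    table = pd.read_csv(table_path)
    delineations = []
    for row in table.itertuples(index=False):
        region = volume[int(row.slice)] == int(row.label)
        delineations.append(
            SliceDelineation(
                slice_index=int(row.slice), region=region, gleason_pattern=int(row.gleason_pattern)
            )
        )
    return delineations, grid
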