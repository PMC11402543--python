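"""Synthetic cohort generator.

Emulates the statistical structure of a histopathology-validation study of
intraprostatic GTV delineations: ~15 patients, four observers, four image
types (T2w, DWI, DCE, PSMA-PET), a whole-gland histopathology support mask,
and a high-grade (Gleason pattern 4/5) target lesion whose volume spans
roughly 0.2-11.2 ml with a heavy right tail (drawn log-uniformly).

Each patient is built as follows:

1. an ellipsoidal gland (the histopathology support);
2. a blob-shaped lesion — the superlevel set of a sum of 1-3 random
   Gaussian bumps — whose highest-intensity core is labelled Gleason 4/5
   (the delineation target), the remainder pattern 3;
3. observer masks drawn from the STAPLE generative model: each truth voxel
   is kept with probability p (the observer x image-type sensitivity) and
   false positives are added with probability 1-q inside a 5 mm shell
   around the lesion;
4. optional boundary noise (a random smooth perturbation of the contour, in
   mm) and a per-image-type in-plane misregistration translation drawn from
   Normal(0, misregistration_sd_mm) and shared by all observers of that
   image type.

All randomness is driven by per-patient counter-based seeds derived from the
master seed, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .dataset import IMAGE_TYPES, DelineationSet
from .grid import BinaryMask, VoxelGrid, shift_mask
from .histology import SliceDelineation
from .io import read_mask, write_mask

__all__ = [
    "CohortConfig",
    "generate_patient",
    "generate_cohort",
    "simulate_observer",
    "patient_slice_delineations",
    "write_cohort",
    "load_cohort",
]

#: sd (mm) for which the expected norm of a 2D isotropic Gaussian shift is 1.7 mm
DEFAULT_MISREG_SD = 1.7 / math.sqrt(math.pi / 2.0)

DEFAULT_SENSITIVITY: dict[str, tuple[float, float]] = {
    "T2w": (0.85, 0.95),
    "DWI": (0.85, 0.95),
    "DCE": (0.80, 0.90),  # DCE delineations are the least reliable
    "PSMA-PET": (0.85, 0.95),
}
DEFAULT_SPECIFICITY: dict[str, tuple[float, float]] = {t: (0.95, 0.99) for t in IMAGE_TYPES}


def _as_range_map(value, image_types: tuple[str, ...], what: str) -> dict[str, tuple[float, float]]:
    if isinstance(value, dict):
        ranges = {t: tuple(map(float, value[t])) for t in image_types}
    else:
        lo, hi = value
        ranges = {t: (float(lo), float(hi)) for t in image_types}
    for t, (lo, hi) in ranges.items():
        if not (0.5 < lo <= hi <= 1.0):
            raise ValueError(f"{what} range for {t} must lie in (0.5, 1], ordered; got ({lo}, {hi})")
    return ranges


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort."""

    n_patients: int = 15
    grid: VoxelGrid = dc_field(
        default_factory=lambda: VoxelGrid(shape=(24, 96, 96), spacing_mm=(2.5, 1.0, 1.0))
    )
    lesion_volume_range_ml: tuple[float, float] = (0.2, 11.2)
    n_observers: int = 4
    image_types: tuple[str, ...] = IMAGE_TYPES
    sensitivity_range: dict[str, tuple[float, float]] | tuple[float, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_SENSITIVITY)
    )
    specificity_range: dict[str, tuple[float, float]] | tuple[float, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_SPECIFICITY)
    )
    boundary_noise_mm: float = 1.0
    misregistration_sd_mm: float = DEFAULT_MISREG_SD
    gleason4or5_fraction: float = 0.75
    fp_shell_mm: float = 5.0
    gland_half_axes_mm: tuple[float, float, float] = (20.0, 26.0, 26.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_observers < 1:
            raise ValueError("n_patients and n_observers must be positive")
        lo, hi = self.lesion_volume_range_ml
        if not 0 < lo <= hi:
            raise ValueError("lesion volume range must be positive and ordered")
        if not 0.0 < self.gleason4or5_fraction <= 1.0:
            raise ValueError("gleason4or5_fraction must be in (0, 1]")
        if self.boundary_noise_mm < 0 or self.misregistration_sd_mm < 0:
            raise ValueError("noise levels must be non-negative")
        self.image_types = tuple(self.image_types)
        self.sensitivity_range = _as_range_map(self.sensitivity_range, self.image_types, "sensitivity")
        self.specificity_range = _as_range_map(self.specificity_range, self.image_types, "specificity")

    def observer_ids(self) -> list[str]:
        return [f"obs{j + 1}" for j in range(self.n_observers)]


def _physical_coords(grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    z = grid.voxel_centers(0)[:, None, None]
    y = grid.voxel_centers(1)[None, :, None]
    x = grid.voxel_centers(2)[None, None, :]
    return z, y, x


def _gland_support(grid: VoxelGrid, half_axes: tuple[float, float, float]) -> BinaryMask:
    z, y, x = _physical_coords(grid)
    center = [grid.origin_mm[a] + 0.5 * (grid.shape[a] - 1) * grid.spacing_mm[a] for a in range(3)]
    r = (
        ((z - center[0]) / half_axes[0]) ** 2
        + ((y - center[1]) / half_axes[1]) ** 2
        + ((x - center[2]) / half_axes[2]) ** 2
    )
    return BinaryMask(grid, r <= 1.0)


def _lesion_field(grid: VoxelGrid, support: BinaryMask, rng: np.random.Generator) -> np.ndarray:
    """Smooth random field whose superlevel sets are blob-shaped lesions."""
    z, y, x = _physical_coords(grid)
    center = [grid.origin_mm[a] + 0.5 * (grid.shape[a] - 1) * grid.spacing_mm[a] for a in range(3)]
    n_bumps = int(rng.integers(1, 4))
    base = [
        center[0] + rng.uniform(-8, 8),
        center[1] + rng.uniform(-10, 10),
        center[2] + rng.uniform(-10, 10),
    ]
    f = np.zeros(grid.shape)
    for _ in range(n_bumps):
        cz = base[0] + rng.uniform(-4, 4)
        cy = base[1] + rng.uniform(-6, 6)
        cx = base[2] + rng.uniform(-6, 6)
        sz = rng.uniform(3.0, 7.0)
        sy = rng.uniform(3.0, 8.0)
        sx = rng.uniform(3.0, 8.0)
        f += rng.uniform(0.6, 1.0) * np.exp(
            -0.5 * (((z - cz) / sz) ** 2 + ((y - cy) / sy) ** 2 + ((x - cx) / sx) ** 2)
        )
    f[~support.values] = -np.inf
    return f


def _top_k_mask(field: np.ndarray, k: int, within: np.ndarray) -> np.ndarray:
    """Boolean mask of the k largest field values inside ``within``."""
    flat = np.where(within.ravel(), field.ravel(), -np.inf)
    idx = np.argpartition(flat, -k)[-k:]
    out = np.zeros(field.size, dtype=bool)
    out[idx] = True
    return out.reshape(field.shape)


def _perturb_boundary(mask: BinaryMask, noise_mm: float, rng: np.random.Generator) -> BinaryMask:
    """Random smooth contour perturbation of ~noise_mm amplitude.

    The signed Euclidean distance to the contour (positive outside) is
    compared against a smooth zero-mean unit-variance noise field scaled by
    ``noise_mm``, moving the boundary in or out locally by about that much.
    """
    if noise_mm == 0 or mask.count == 0:
        return mask.copy()
    spacing = mask.grid.spacing_mm
    d_out = distance_transform_edt(~mask.values, sampling=spacing)
    d_in = distance_transform_edt(mask.values, sampling=spacing)
    signed = d_out - d_in
    noise = gaussian_filter(rng.standard_normal(mask.grid.shape), sigma=1.5)
    sd = noise.std()
    if sd == 0:
        return mask.copy()
    noise /= sd
    return BinaryMask(mask.grid, signed <= noise_mm * noise)


def simulate_observer(
    truth: BinaryMask,
    p: float,
    q: float,
    rng: np.random.Generator,
    fp_region: BinaryMask | None = None,
) -> BinaryMask:
    """Draw one observer decision field from the STAPLE generative model.

    Truth voxels are kept with probability ``p``; voxels of ``fp_region``
    (default: everywhere outside the truth) become false positives with
    probability ``1 - q``.
    """
    u = rng.random(truth.grid.shape)
    keep = truth.values & (u < p)
    outside = ~truth.values if fp_region is None else (fp_region.values & ~truth.values)
    add = outside & (u >= q)  # P(u >= q) = 1 - q, independent of the keep draw region
    return BinaryMask(truth.grid, keep | add)


def generate_patient(config: CohortConfig, patient_seed: int, patient_id: str | None = None) -> DelineationSet:
    """Generate one synthetic patient; bit-reproducible for a given seed."""
    rng = np.random.default_rng(np.random.SeedSequence([int(patient_seed)]))
    grid = config.grid
    support = _gland_support(grid, config.gland_half_axes_mm)
    field = _lesion_field(grid, support, rng)

    lo, hi = config.lesion_volume_range_ml
    target_ml = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    vox_ml = grid.voxel_volume_mm3 / 1000.0
    n_target = max(1, round(target_ml / vox_ml))
    n_lesion = max(n_target, round(n_target / config.gleason4or5_fraction))
    if n_lesion > support.count:
        raise ValueError(
            f"infeasible lesion volume {target_ml:.2f} ml for a gland of {support.volume_ml:.2f} ml"
        )
    lesion_full = BinaryMask(grid, _top_k_mask(field, n_lesion, support.values))
    target = BinaryMask(grid, _top_k_mask(field, n_target, lesion_full.values))

    from .alignment import expand_margin  # deferred import (alignment uses metrics)

    shell = BinaryMask(grid, expand_margin(target, config.fp_shell_mm).values & ~target.values)

    observers = config.observer_ids()
    masks: dict[tuple[str, str], BinaryMask] = {}
    perf: dict[str, dict[str, tuple[float, float]]] = {}
    shifts: dict[str, tuple[float, float]] = {}
    for itype in config.image_types:
        p_lo, p_hi = config.sensitivity_range[itype]
        q_lo, q_hi = config.specificity_range[itype]
        t = rng.normal(0.0, config.misregistration_sd_mm, size=2) if config.misregistration_sd_mm > 0 else np.zeros(2)
        shifts[itype] = (float(t[0]), float(t[1]))
        for obs in observers:
            p = float(rng.uniform(p_lo, p_hi))
            q = float(rng.uniform(q_lo, q_hi))
            perf.setdefault(obs, {})[itype] = (p, q)
            m = simulate_observer(target, p, q, rng, fp_region=shell)
            m = _perturb_boundary(m, config.boundary_noise_mm, rng)
            if any(abs(v) > 0 for v in shifts[itype]):
                m = shift_mask(m, shifts[itype])
            masks[(obs, itype)] = m

    return DelineationSet(
        patient_id=patient_id or f"P{patient_seed}",
        masks=masks,
        histo_lesion=target,
        histo_support=support,
        truth_params={
            "seed": int(patient_seed),
            "target_volume_ml": target.volume_ml,
            "lesion_volume_ml": lesion_full.volume_ml,
            "performance": perf,
            "translations_mm": shifts,
            "full_lesion": lesion_full,
        },
    )


def generate_cohort(config: CohortConfig) -> list[DelineationSet]:
    """Generate ``config.n_patients`` independent patients.

    Per-patient seeds are derived deterministically from ``config.seed`` so a
    cohort is reproducible and individual patients can be regenerated alone.
    """
    master = np.random.SeedSequence(int(config.seed))
    seeds = master.generate_state(config.n_patients, dtype=np.uint32) % (2**31)
    return [
        generate_patient(config, int(seeds[i]), patient_id=f"P{i + 1:02d}")
        for i in range(config.n_patients)
    ]


def patient_slice_delineations(dset: DelineationSet) -> list[SliceDelineation]:
    """Per-slice histopathology delineations of a synthetic patient.

    Emits, per slice, the Gleason-4/5 core footprint (pattern 4) and the
    surrounding low-grade part of the lesion (pattern 3), suitable as input to
    :func:`gtvfusion.histology.merge_lesions_z`.
    """
    full = dset.truth_params.get("full_lesion")
    if full is None:
        raise ValueError("patient has no recorded full lesion (not a synthetic patient?)")
    out: list[SliceDelineation] = []
    for z in range(dset.grid.shape[0]):
        high = dset.histo_lesion.values[z]
        low = full.values[z] & ~high
        if high.any():
            out.append(SliceDelineation(slice_index=z, region=high, gleason_pattern=4))
        if low.any():
            out.append(SliceDelineation(slice_index=z, region=low, gleason_pattern=3))
    return out


def write_cohort(cohort: list[DelineationSet], directory: str) -> str:
    """Write a cohort as NIfTI masks + manifest CSV + generating-truth JSON."""
    os.makedirs(directory, exist_ok=True)
    rows = []
    truth: dict[str, dict] = {}
    for dset in cohort:
        pdir = os.path.join(directory, dset.patient_id)
        os.makedirs(pdir, exist_ok=True)
        write_mask(dset.histo_lesion, os.path.join(pdir, "histo_lesion.nii.gz"))
        write_mask(dset.histo_support, os.path.join(pdir, "histo_support.nii.gz"))
        for (obs, itype), mask in sorted(dset.masks.items()):
            fname = f"{obs}_{itype.replace('/', '-')}.nii.gz"
            write_mask(mask, os.path.join(pdir, fname))
            rows.append(
                {
                    "patient_id": dset.patient_id,
                    "observer": obs,
                    "image_type": itype,
                    "path": os.path.join(dset.patient_id, fname),
                }
            )
        tp = {k: v for k, v in dset.truth_params.items() if k != "full_lesion"}
        truth[dset.patient_id] = tp
    pd.DataFrame(rows).to_csv(os.path.join(directory, "manifest.csv"), index=False)
    with open(os.path.join(directory, "truth_params.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
    return directory


def load_cohort(directory: str) -> list[DelineationSet]:
    """Read a cohort previously written by :func:`write_cohort`."""
    manifest = pd.read_csv(os.path.join(directory, "manifest.csv"))
    cohort = []
    for pid, group in manifest.groupby("patient_id", sort=True):
        pdir = os.path.join(directory, str(pid))
        masks = {
            (str(row.observer), str(row.image_type)): read_mask(
                os.path.join(directory, str(row.path))
            )
            for row in group.itertuples(index=False)
        }
        cohort.append(
            DelineationSet(
                patient_id=str(pid),
                masks=masks,
                histo_lesion=read_mask(os.path.join(pdir, "histo_lesion.nii.gz")),
                histo_support=read_mask(os.path.join(pdir, "histo_support.nii.gz")),
            )
        )
    return cohort
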