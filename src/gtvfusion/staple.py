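"""STAPLE fusion of multi-observer delineations and GTV construction.

STAPLE (Simultaneous Truth and Performance Level Estimation) treats the
unknown true segmentation ``T_i`` as a latent binary field and each observer
``j`` as a channel with sensitivity ``p_j = P(d_ij = 1 | T_i = 1)`` and
specificity ``q_j = P(d_ij = 0 | T_i = 0)``.  EM alternates between the
voxelwise posterior

    W_i = a_i / (a_i + b_i),
    a_i = g * prod_j p_j^d_ij (1 - p_j)^(1 - d_ij),
    b_i = (1 - g) * prod_j (1 - q_j)^d_ij q_j^(1 - d_ij),

and the performance estimates

    p_j = sum_i W_i d_ij / sum_i W_i,
    q_j = sum_i (1 - W_i)(1 - d_ij) / sum_i (1 - W_i),

with a fixed foreground prior ``g``.  Fused GTVs are obtained by thresholding
the converged posterior (default 0.95) and cropping to the histopathology
support.

Two construction schemes are provided: per-image-type fusion of the four
observers (:func:`fuse_single_modality`), and the union-then-STAPLE scheme
for multi-modality GTVs (:func:`fuse_multi_modality`), where each observer's
delineations across the requested image types are first merged into a union
and STAPLE then fuses the four per-observer unions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import DelineationSet
from .grid import BinaryMask, VoxelGrid, crop_to_support, mask_union

__all__ = [
    "StapleParams",
    "StapleModel",
    "StapleResult",
    "staple_em",
    "threshold_posterior",
    "fuse_single_modality",
    "fuse_multi_modality",
    "observer_union_gtv",
]

_PROB_CLAMP = 1e-6


@dataclass(frozen=True)
class StapleParams:
    """EM settings for STAPLE fusion.

    Parameters
    ----------
    threshold
        Posterior probability above which (inclusively) a voxel enters the
        fused GTV; in ``(0, 1]``.
    max_iterations, tolerance
        EM stops when the mean absolute change in the posterior between
        iterations drops below ``tolerance``, or after ``max_iterations``.
    prior_mode
        ``"global_fraction"`` sets the foreground prior to the mean of the
        observers' foreground fractions; ``"fixed"`` uses ``fixed_prior``.
        The prior is held fixed across iterations either way.
    """

    threshold: float = 0.95
    max_iterations: int = 200
    tolerance: float = 1e-7
    prior_mode: str = "global_fraction"
    fixed_prior: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.prior_mode not in ("global_fraction", "fixed"):
            raise ValueError(f"unknown prior_mode {self.prior_mode!r}")
        if self.prior_mode == "fixed" and not 0.0 < self.fixed_prior < 1.0:
            raise ValueError(f"fixed_prior must be in (0, 1), got {self.fixed_prior}")


@dataclass
class StapleResult:
    """Converged STAPLE estimate.

    Attributes
    ----------
    posterior
        Ground-truth probability field ``W`` on the reference grid.
    sensitivity, specificity
        Per-observer performance estimates ``p_j`` and ``q_j``, ordered as
        ``observer_ids``.
    prior
        The (fixed) foreground prior used.
    """

    grid: VoxelGrid
    posterior: np.ndarray = field(repr=False)
    sensitivity: np.ndarray
    specificity: np.ndarray
    observer_ids: list[str]
    prior: float
    iterations_run: int
    converged: bool
    params: StapleParams

    def threshold(self, tau: float | None = None) -> BinaryMask:
        """Binarize the posterior at ``tau`` (default: the fit's threshold)."""
        return threshold_posterior(self, self.params.threshold if tau is None else tau)

    def summary(self) -> str:
        lines = [
            "STAPLE fusion results",
            "=" * 54,
            f"observers: {len(self.observer_ids)}   voxels: {self.grid.n_voxels}",
            f"prior (fixed): {self.prior:.6f}",
            f"iterations: {self.iterations_run}   converged: {self.converged}",
            "-" * 54,
            f"{'observer':<16}{'sensitivity p':>18}{'specificity q':>18}",
        ]
        for name, p, q in zip(self.observer_ids, self.sensitivity, self.specificity):
            lines.append(f"{name:<16}{p:>18.6f}{q:>18.6f}")
        lines.append("=" * 54)
        return "\n".join(lines)


class StapleModel:
    """Binary STAPLE EM over a stack of observer masks.

    Parameters
    ----------
    observer_masks
        One binary mask per observer, all on one grid.
    observer_ids
        Labels for reporting; defaults to ``obs1..obsJ``.
    region
        Optional mask restricting the voxels entering the estimation (e.g. a
        region of interest around the lesion).  Voxels outside the region are
        excluded from both the performance estimates and the posterior (their
        posterior is reported as 0).
    """

    def __init__(
        self,
        observer_masks: list[BinaryMask],
        observer_ids: list[str] | None = None,
        region: BinaryMask | None = None,
    ) -> None:
        if not observer_masks:
            raise ValueError("STAPLE requires at least one observer mask")
        grid = observer_masks[0].grid
        for m in observer_masks[1:]:
            if not grid.isclose(m.grid):
                raise ValueError("observer masks must share one grid")
        if region is not None and not grid.isclose(region.grid):
            raise ValueError("region must share the observers' grid")
        self.grid = grid
        self.observer_masks = observer_masks
        self.observer_ids = observer_ids or [f"obs{j + 1}" for j in range(len(observer_masks))]
        if len(self.observer_ids) != len(observer_masks):
            raise ValueError("observer_ids length must match observer_masks")
        self.region = region

    def fit(self, params: StapleParams | None = None) -> StapleResult:
        params = params or StapleParams()
        if self.region is None:
            sel = None
            D = np.stack([m.values.ravel() for m in self.observer_masks], axis=1)
        else:
            sel = self.region.values.ravel()
            D = np.stack([m.values.ravel()[sel] for m in self.observer_masks], axis=1)
        D = D.astype(np.float64)
        n_vox, n_obs = D.shape

        if params.prior_mode == "global_fraction":
            prior = float(D.mean())
            if prior == 0.0:
                raise ValueError(
                    "degenerate input: all observers empty, global-fraction prior would be 0"
                )
            if prior == 1.0:
                prior = 1.0 - _PROB_CLAMP
        else:
            prior = float(params.fixed_prior)

        W = D.mean(axis=1)
        iterations = 0
        converged = False
        p = np.full(n_obs, 0.5)
        q = np.full(n_obs, 0.5)
        for iterations in range(1, params.max_iterations + 1):
            # M-step
            w_sum = W.sum()
            c_sum = n_vox - w_sum
            p = (W @ D) / max(w_sum, _PROB_CLAMP)
            q = ((1.0 - W) @ (1.0 - D)) / max(c_sum, _PROB_CLAMP)
            p = np.clip(p, _PROB_CLAMP, 1.0 - _PROB_CLAMP)
            q = np.clip(q, _PROB_CLAMP, 1.0 - _PROB_CLAMP)
            # E-step (log space)
            log_a = np.log(prior) + D @ np.log(p) + (1.0 - D) @ np.log(1.0 - p)
            log_b = np.log(1.0 - prior) + D @ np.log(1.0 - q) + (1.0 - D) @ np.log(q)
            m = np.maximum(log_a, log_b)
            a = np.exp(log_a - m)
            b = np.exp(log_b - m)
            W_new = a / (a + b)
            change = float(np.abs(W_new - W).mean())
            W = W_new
            if change < params.tolerance:
                converged = True
                break

        posterior = np.zeros(self.grid.n_voxels)
        if sel is None:
            posterior[:] = W
        else:
            posterior[sel] = W
        return StapleResult(
            grid=self.grid,
            posterior=posterior.reshape(self.grid.shape),
            sensitivity=p,
            specificity=q,
            observer_ids=list(self.observer_ids),
            prior=prior,
            iterations_run=iterations,
            converged=converged,
            params=params,
        )


def staple_em(
    observer_masks: list[BinaryMask],
    params: StapleParams | None = None,
    observer_ids: list[str] | None = None,
    region: BinaryMask | None = None,
) -> StapleResult:
    """Fit binary STAPLE EM; see :class:`StapleModel`."""
    return StapleModel(observer_masks, observer_ids=observer_ids, region=region).fit(params)


def threshold_posterior(result: StapleResult, tau: float) -> BinaryMask:
    """Foreground where the posterior is >= ``tau`` (inclusive)."""
    if not 0.0 < tau <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {tau}")
    return BinaryMask(result.grid, result.posterior >= tau)


def _fuse(masks: list[BinaryMask], ids: list[str], support: BinaryMask, params: StapleParams) -> BinaryMask:
    result = StapleModel(masks, observer_ids=ids).fit(params)
    return crop_to_support(result.threshold(), support)


def fuse_single_modality(
    dset: DelineationSet, image_type: str, params: StapleParams | None = None
) -> BinaryMask:
    """STAPLE-fuse all observers' delineations of one image type.

    The converged posterior is thresholded at ``params.threshold`` and the
    result cropped to the histopathology support.
    """
    params = params or StapleParams()
    observers = dset.observers
    masks = [dset.mask_for(obs, image_type) for obs in observers]
    return _fuse(masks, observers, dset.histo_support, params)


def fuse_multi_modality(
    dset: DelineationSet, image_types: list[str], params: StapleParams | None = None
) -> BinaryMask:
    """Union-then-STAPLE combination across image types.

    Each observer's delineations for the requested image types are first
    merged into a union; STAPLE then fuses the per-observer unions, and the
    thresholded posterior is cropped to the histopathology support.  With
    ``["T2w", "DWI"]`` this builds the bpMRI GTV, with ``["T2w", "DWI",
    "DCE"]`` the mpMRI GTV, and with all four image types the PSMA-PET/mpMRI
    GTV.
    """
    if not image_types:
        raise ValueError("image_types must be nonempty")
    params = params or StapleParams()
    observers = dset.observers
    unions = [
        mask_union([dset.mask_for(obs, itype) for itype in image_types]) for obs in observers
    ]
    return _fuse(unions, observers, dset.histo_support, params)


def observer_union_gtv(dset: DelineationSet, observer: str) -> BinaryMask:
    """One observer's combined GTV: union across image types, cropped to support."""
    if observer not in dset.observers:
        raise KeyError(f"unknown observer {observer!r} for patient {dset.patient_id!r}")
    masks = [dset.masks[(obs, itype)] for (obs, itype) in dset.masks if obs == observer]
    return crop_to_support(mask_union(masks), dset.histo_support)
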