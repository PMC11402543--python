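# Methods

This note documents the models and procedures implemented in `gtvfusion`,
the conventions that make them reproducible, and what the synthetic cohort
does and does not emulate.

## Grids, masks and conventions

All data are binary masks on regular, axis-aligned 3D lattices with
per-axis spacing in millimetres (axis order: slice, row, column — z, y, x).
A voxel occupies the point at its center: the physical position of index
`(k, j, i)` is `origin + (k, j, i) ⊙ spacing`. Nearest-neighbour lookups
round half-way points away from zero. Volumes are foreground count × voxel
volume / 1000 (ml).

File I/O supports NIfTI-1 and NRRD through SimpleITK. Only axis-aligned
direction matrices (diagonal ±1) are accepted; flipped axes are reoriented
on load. Oblique volumes are rejected rather than silently resampled,
because the analysis assumes intra-patient co-registered grids. All
downstream analysis happens on the histopathology reference grid; observer
masks acquired on coarser grids (e.g. 5 mm DWI/DCE slices versus 2.5 mm
T2w) are resampled there by nearest voxel center immediately after loading.

## STAPLE fusion

Binary STAPLE treats the true segmentation as a latent Bernoulli field with
a foreground prior γ and each observer as a noisy channel with sensitivity
`p_j` and specificity `q_j`. The EM iteration alternates the voxelwise
posterior (E-step) with the performance estimates (M-step), as written in
the package docstrings. Implementation choices that the original
formulation leaves open:

- **Prior.** γ is the mean of the observers' foreground fractions and is
  held fixed across iterations (`prior_mode="global_fraction"`; a fixed
  user-supplied value is also available). Re-estimating γ each iteration
  can drift the posterior toward degenerate solutions on small foregrounds;
  a fixed data-driven prior is the simplest reproducible choice.
- **Initialisation.** The posterior starts at the voxelwise mean of the
  observer decisions and the first step is the M-step. This is
  deterministic and indifferent to the number of raters.
- **Clamping.** `p_j`, `q_j` are clamped to `[1e-6, 1 − 1e-6]` each M-step
  so unanimous regions do not produce 0·log 0.
- **Stopping.** Iteration ends when the mean absolute posterior change
  drops below `1e-7` (default) or after 200 iterations.
- **Thresholding.** Fused GTVs are the posterior at `W_i ≥ 0.95`
  (inclusive, so the unanimous case reproduces the input exactly). The same
  threshold is used for single- and multi-modality fusion.
- **Numerics.** The E-step runs in log space with a max-subtraction, so
  products over many raters cannot underflow.

The E-step can optionally be restricted to a region of interest; voxels
outside report posterior 0 and do not enter the performance estimates.
This matters when false positives are known to be spatially confined: the
specificity estimate is only interpretable relative to the region actually
considered.

Multi-modality GTVs use union-then-STAPLE: each observer's delineations
across the combined image types are merged into a union first, and STAPLE
then fuses the per-observer unions. Requesting a single image type through
this path reduces exactly to single-modality fusion. Every fused GTV is
cropped to the histopathology support, excluding regions without ground
truth from all comparisons.

An identifiability caveat: with four raters and a small foreground,
sensitivity and specificity are recovered well (within a few hundredths)
when specificity is high (≳0.95), but if a rater floods the background
with false positives (specificity ≲0.9 over a large background) the latent
truth is no longer well separated and estimates bias accordingly. The test
suite probes the well-identified regime.

## Ground truth from histopathology

Per-slice delineations (2D regions with a Gleason pattern 3, 4 or 5) are
merged into 3D lesions: two delineations belong to the same lesion iff they
are connected by a chain of pairs on *consecutive* slices whose regions
share at least one in-plane voxel. A one-slice gap breaks the chain.
Overlap requires a single shared voxel; no area-fraction threshold is
applied, and raw footprints are used without morphological cleanup. The
validation target (the dominant intraprostatic lesion) is operationalised
as the lesion with the largest Gleason-4/5 volume, restricted to its
pattern-4/5 voxels. Where same-slice delineations overlap on a voxel, the
later delineation in the input wins the voxel label; lesion membership
itself is order-invariant.

## Metrics and margins

DSC and lesion coverage are exact integer voxel counts; both raise an error
rather than adopt a convention when undefined (two empty masks for DSC, an
empty lesion for coverage), because the analysis never produces those cases
legitimately and a silent 0 or 1 would hide upstream bugs. Evaluation of a
(GTV, margin) pair applies the margin first, then crops to the
histopathology support, then measures both metrics against the lesion.

CTV margins are isotropic in physical millimetres: the expanded mask is
every voxel whose center lies within the radius (inclusive) of a foreground
voxel center, computed with a spacing-aware Euclidean distance transform.
On 5 mm slices a 3 mm margin therefore grows in-plane only — the behaviour
clinical margin recipes exhibit on anisotropic dose grids.

## Penalized translation registration and calibration

To quantify the impact of the residual in-plane histology-to-imaging
registration error, each patient's GTV may be translated in-plane to
maximise `J(t) = DSC(shift(GTV, t), lesion) − λ‖t‖₂`. Design choices:

- **Objective.** The kappa-type overlap objective is exactly the Dice
  coefficient; the penalty is linear in distance, which keeps the
  calibrated population mean interpretable as a distance.
- **Search.** For binary masks under nearest-neighbour shifting the DSC is
  piecewise constant in `t` (it depends only on `round(t / spacing)`), so
  gradient methods are inapplicable; the optimum is found by exhaustive
  coarse-to-fine grid search (coarse step: half the in-plane spacing over a
  10 mm disc; refinement: 0.1 mm around the incumbent). Ties are broken
  toward the smaller `‖t‖`, then lexicographically, so an already-aligned
  case returns the zero translation. Because the zero translation is always
  searched, `dsc_after ≥ dsc_before` for every λ ≥ 0.
- **Plateau semantics.** Any translation inside the optimal voxel cell is a
  maximiser at λ = 0; the reported translation is the cell's minimum-norm
  point, so "recovering" a constructed shift is accurate to about half the
  in-plane voxel size on coarse grids and to the 0.1 mm search resolution
  on grids at least that fine.
- **Calibration.** λ* is found by geometric bracket growth from [0, 1]
  followed by bisection on the cohort mean of `‖t*(λ)‖`, which is
  non-increasing in λ. Iteration stops when the mean is within the
  tolerance (default 0.01 mm) of the target (default 1.7 mm, the reported
  median in-plane registration error) or the bracket collapses, returning
  the λ whose mean came closest. If the unpenalized mean is already below
  the target, the boundary solution λ* = 0 is returned with a warning flag.
  Because the per-patient optimal distances take discretely many values
  (minimum-norm points of voxel cells), the achievable cohort means form a
  staircase; with 15 patients on 1 mm in-plane grids its steps near the
  target are typically 0.005–0.03 mm, so a 0.01 mm tolerance is usually —
  but not structurally always — attainable. The calibration result records
  the achieved mean so the residual gap is always visible.
- **Calibration GTV.** Per patient, the all-MRI all-observer combination
  (union-then-STAPLE over T2w + DWI + DCE).

The DSC table used by the optimiser is memoised per integer shift, so
re-optimising the whole cohort at each bisection step costs almost nothing
after the first pass.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes, at
desk scale. Defaults and rationale:

| parameter | default | why |
| --- | --- | --- |
| patients | 15 | cohort size of the emulated study design |
| grid | 24×96×96 at (2.5, 1, 1) mm | T2w-like slice thickness, ~1 mm in-plane |
| gland half-axes | (20, 26, 26) mm | ≈ 50 ml gland, a typical prostate |
| Gleason-4/5 lesion volume | log-uniform 0.2–11.2 ml | spans the reported range with a heavy right tail |
| Gleason-4/5 fraction | 0.75 | ratio of reported median high-grade to total lesion volume |
| observers × image types | 4 × 4 | study structure |
| sensitivity | 0.85–0.95 (DCE 0.80–0.90) | good-but-imperfect raters; DCE weakest |
| specificity | 0.95–0.99 | few false positives near the lesion |
| false-positive shell | 5 mm around the lesion | observers err near the boundary, not across the gland |
| boundary noise | 1 mm | contour jitter of careful delineation |
| misregistration sd | 1.356 mm per modality | expected in-plane displacement norm ≈ 1.7 mm |

The lesion is the superlevel set of a sum of 1–3 random Gaussian bumps (its
highest-intensity core is the Gleason-4/5 target, so the high-grade region
is interior and connected, as whole-mount sections typically show); the
gland is an ellipsoid; observer masks are drawn voxel-independently from
the STAPLE generative model, then boundary-perturbed by comparing the
signed distance to a smooth random field, then shifted by a per-image-type
in-plane translation shared across observers. Per-patient random streams
are derived from the master seed by counter-based seeding, so cohorts are
bit-reproducible and individual patients can be regenerated alone.

For the calibration experiment the per-modality misregistration scale is
raised to `2 × 1.7 × √3 / √(π/2) ≈ 4.70` mm: fusing three modality shifts
attenuates the effective displacement by about √3, and the factor 2 places
the expected unpenalized optimal shift near twice the target so the penalty
has a real population mean to pull down.

What the generator does **not** emulate: image intensities (only masks),
systematic observer bias (over-/under-segmentation tendencies, modality
cross-correlations of errors), multifocal disease (one dominant lesion per
patient), deformable registration error (translations only), and the
spatial correlation of real delineation errors beyond the boundary-noise
field. Passing tests therefore demonstrate the correctness of the
algorithms under the stated generative model, not clinical performance on
real delineations; the reported patient-level overlap values of any real
study depend on data this package does not ship.

## Problem sizes in the test suite

Unit tests run on 8×8×4 to 24×96×96 grids; the straight-loop EM reference
is checked on 50 small random instances; metric exactness on 200 random
pairs; the calibration experiment on the full 15-patient default-grid
cohort. The complete suite runs in well under a minute on one CPU core,
with the calibration acceptance test dominating.
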