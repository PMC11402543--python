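# gtvfusion

Multi-observer gross tumour volume (GTV) fusion and histopathology validation
for intraprostatic lesions.

Focal dose escalation in prostate radiotherapy needs a trustworthy target:
the visible tumour is delineated by several observers on several image types
(T2-weighted MRI, diffusion-weighted MRI, dynamic contrast-enhanced MRI and
PSMA-PET), and the resulting GTVs are validated voxel-wise against
whole-mount histopathology, where high-grade (Gleason pattern 4/5) tumour
delineations serve as ground truth. `gtvfusion` implements that validation
pipeline end to end for researchers working with co-registered binary
segmentation masks:

- **STAPLE fusion** (Simultaneous Truth and Performance Level Estimation):
  binary EM estimation of the latent true segmentation `T_i` from observer
  decisions `d_ij`, with per-observer sensitivity `p_j = P(d_ij=1 | T_i=1)`
  and specificity `q_j = P(d_ij=0 | T_i=0)`. The posterior
  `W_i = a_i / (a_i + b_i)` with
  `a_i = γ ∏_j p_j^{d_ij}(1-p_j)^{1-d_ij}` and
  `b_i = (1-γ) ∏_j (1-q_j)^{d_ij} q_j^{1-d_ij}`
  is thresholded at 0.95 to form fused GTVs.
- **Single- and multi-modality GTV construction**: per-image-type fusion of
  the four observers, and the union-then-STAPLE scheme for combined GTVs
  (bpMRI = T2w+DWI, mpMRI = T2w+DWI+DCE, PSMA-PET/mpMRI = all four), all
  cropped to the histopathology support.
- **Ground-truth construction**: merging per-slice histopathology
  delineations into 3D lesions by consecutive-slice in-plane overlap and
  selecting the dominant Gleason-4/5 region.
- **Overlap metrics**: Dice similarity coefficient
  `DSC = 2|A∩B| / (|A|+|B|)` and lesion coverage (voxel-wise sensitivity)
  `|GTV∩L| / |L|`, evaluated across isotropic CTV margins of 0–3 mm applied
  in physical millimetres on anisotropic grids.
- **Registration-uncertainty experiment**: per-patient penalized in-plane
  translation registration maximising `J(t) = DSC(shift(GTV,t), L) − λ‖t‖₂`,
  with the penalty weight λ calibrated by bisection so the population-mean
  optimal translation distance equals the known 1.7 mm in-plane
  histology-to-imaging registration error.
- **Synthetic cohorts**: a generator producing study-shaped patients
  (ellipsoidal gland, blob lesions of 0.2–11.2 ml with a high-grade core,
  observers drawn from the STAPLE generative model, boundary noise,
  injected misregistrations) so everything is testable without patient data.

## Worked example

```python
import numpy as np
from gtvfusion import CohortConfig, VoxelGrid, generate_cohort, staple_em, summarize_cohort
from gtvfusion.pipeline import evaluate_patient

cfg = CohortConfig(n_patients=4, seed=7,
                   grid=VoxelGrid(shape=(16, 64, 64), spacing_mm=(2.5, 1.0, 1.0)),
                   lesion_volume_range_ml=(0.5, 4.0),
                   gland_half_axes_mm=(16.0, 22.0, 22.0))
cohort = generate_cohort(cfg)

dset = cohort[0]
res = staple_em([dset.mask_for(obs, "T2w") for obs in dset.observers],
                observer_ids=dset.observers)
print(res.summary())
```

```
STAPLE fusion results
======================================================
observers: 4   voxels: 65536
prior (fixed): 0.004204
iterations: 7   converged: True
------------------------------------------------------
observer             sensitivity p     specificity q
obs1                      0.829258          0.998018
obs2                      0.883145          0.999253
obs3                      0.849926          0.999155
obs4                      0.777562          0.999625
======================================================
```

The estimated sensitivities reflect how much of the (latent) true lesion
each observer delineated; specificities are near 1 because false positives
are rare relative to the large background. Evaluating every GTV definition
against the ground-truth lesion and aggregating over the cohort:

```python
records = []
for d in cohort:
    records.extend(evaluate_patient(d, [0.0, 1.0, 2.0, 3.0]))
summary = summarize_cohort(records)
row = summary.row("mpMRI", "staple", 0.0, "dsc")
print(f"mpMRI DSC, no margin: {row.value:.2f} ({row.vmin:.2f}, {row.vmax:.2f})")
```

```
            T2w (S) margin 0 mm: DSC 0.87 (0.66, 0.89)  coverage 0.89 (0.68, 0.91)
            T2w (S) margin 3 mm: DSC 0.47 (0.37, 0.51)  coverage 1.00 (0.99, 1.00)
          mpMRI (S) margin 0 mm: DSC 0.75 (0.68, 0.84)  coverage 0.99 (0.96, 0.99)
```

The pattern is the expected one: adding a CTV margin drives lesion coverage
toward 1 while the DSC falls (more healthy tissue enters the target), and
multi-modality GTVs achieve high coverage without the margin. STAPLE rows
report the median (min, max) over patients; individual-observer rows report
the mean of the observers' per-patient medians with the extreme medians.

## Command line

```bash
gtvfusion simulate  --config config.yaml --out cohort/
gtvfusion fuse      --config config.yaml --cohort cohort/ --out gtvs/
gtvfusion evaluate  --config config.yaml --cohort cohort/ --out records.csv
gtvfusion calibrate --cohort cohort/ --target-mean-mm 1.7 --tolerance-mm 0.01 --out calib.json
gtvfusion report    --records records.csv --out summary.csv --plots plots/
```

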