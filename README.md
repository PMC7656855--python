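# provseg — training-contour provenance for CT segmentation

Radiotherapy planning needs the hippocampus contoured as an organ at risk,
but the structure is barely visible on the planning CT: contours are normally
drawn on a registered MR and propagated to the CT frame.  A CT-only
segmentation CNN would simplify the workflow — but must such a network be
*trained* on propagated MR-based contours, or can cheaper CT-drawn (and
therefore noisier) contours do the job?

`provseg` implements that study end to end at desk scale, replacing the
private patient cohort with a fully synthetic one.  It is aimed at people
studying training-label noise in medical image segmentation: every stage —
phantom cohort, contour degradation, propagation, network, hyperparameter
search, uncertainty estimation, evaluation — is seeded, tested and
inspectable.

**The pipeline:**

* **Synthetic cohort** — paired pseudo-MR (high contrast) / pseudo-CT (low
  contrast, noisy) volumes of the same anatomy: bilateral curved tubes
  inclined ~20° to the axial plane; a tilted MR frame (structure in-plane,
  as for manual contouring), a CT frame displaced by a known rigid
  misregistration, exact contours, and degraded CT-frame contours calibrated
  to ~0.59 Dice agreement with the clean ones (the reported level of manual
  CT-vs-MR contour agreement).
* **Preprocessing** — 1.5 mm resampling, CT windowing (center/width
  40/80 HU → [0,1]), MR 2nd/98th-percentile normalization, tilt-reverting
  affine contour propagation (1 mm isotropic → untilt → affine →
  Gaussian-smooth → threshold), flip and rigid augmentation.
* **Network** — a hybrid 2D/3D dense encoder-decoder (Tiramisu-style dense
  blocks in-plane; a separable 3×3×1 + unpadded 1×1×3 convolution before
  each pooling) mapping a 7-slice slab to a 1-slice, 3-class softmax map;
  Dice loss `1 − (2Σ_fg pt + ε)/(Σ_fg p + Σ_fg t + ε)`.  Implemented in pure
  NumPy with hand-written, finite-difference-verified backprop and Adam.
* **Model selection** — successive halving over random init + log-uniform
  learning rate (reference ladder 16(5k)/8(10k)/4(20k)/2(40k)/1(80k)),
  ranked by full-volume validation Jaccard.
* **Inference** — sliding-slab prediction, threshold 0.5, largest
  26-connected component per side, and Monte-Carlo-dropout entropy maps
  `U(x) = −Σ_k p̄_k ln p̄_k` (N = 25 reference).
* **Evaluation** — Dice, mean surface distance, Hausdorff, contour Dice at
  1/3/5/7/10 mm, RTOG 0933 passing rate (HD ≤ 7 mm), uncertainty density
  within τ = k·1.5 mm of the predicted contour, Wilcoxon signed-rank tests.

## Worked example

Score one draw of the contour-degradation model (the stand-in for a manual
low-contrast annotator) against the clean CT-frame contours:

```python
from provseg import PhantomSpec, generate_phantom_pair, \
    calibrated_degradation, degrade_contour
from provseg.metrics import evaluate_case

case = generate_phantom_pair(PhantomSpec(seed=0), "demo")
degraded = degrade_contour(case.gt_mask_ct, calibrated_degradation(seed=0))
for rec in evaluate_case("demo", degraded, case.gt_mask_ct):
    print(f"{rec.side:>5}: Dice {rec.dice:.3f}, "
          f"MSD {rec.mean_surface_distance_mm:.2f} mm, "
          f"HD {rec.hausdorff_mm:.2f} mm, "
          f"contour Dice@7mm {rec.contour_dice[7.0]:.3f}")
```

prints

```
 left: Dice 0.701, MSD 1.07 mm, HD 4.74 mm, contour Dice@7mm 0.938
right: Dice 0.548, MSD 1.31 mm, HD 8.49 mm, contour Dice@7mm 0.974
```

— one side of this draw agrees well with the clean contour, the other drifts
past the 7 mm acceptance threshold; averaged over many draws the calibration
sits at ~0.59–0.61 mean Dice, the intended inter-modality agreement level.

Run the full desk-scale study (20 cases, 5 folds, both CT-frame arms) from
the shell:

```sh
provseg experiment run --seed 1 --out-dir scratch/study
```

The report compares the arm trained on clean propagated contours with the
arm trained on degraded contours, both evaluated against the same propagated
clean ground truth: per-arm median Dice with IQR, surface distances, RTOG
passing rates, uncertainty densities and paired Wilcoxon p-values.  At desk
scale the clean-contour arm's median test Dice exceeds the degraded-contour
arm's by a wide margin and the degraded arm is visibly more uncertain near
its contours — the directional findings the study design predicts.

Other entry points: `provseg simulate` writes a NIfTI cohort + manifest;
`provseg predict` segments a volume with a saved checkpoint (optionally with
an entropy map); `provseg evaluate` scores two NIfTI masks.  The library API
(`provseg.run_experiment`, `provseg.desk_config`, …) exposes everything the
CLI does and more.

## Layout

```
src/provseg/
  types.py       volumes, label masks, affine transforms, NIfTI I/O
  cohort.py      phantom cohort, contour degradation, fold splits
  preprocess.py  resampling, normalization, propagation, augmentation
  nn.py          NumPy layers + Adam (hand-written backprop)
  network.py     the hybrid 2D/3D dense network and Dice loss
  training.py    slab sampling, training, successive-halving search
  inference.py   sliding-slab prediction, postprocessing, MC dropout
  metrics.py     evaluation metrics and paired statistics
  experiment.py  the full study: arms, folds, reports
  cli.py         `provseg` command-line interface
docs/methods.md  model, assumptions, parameters, design choices
```
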