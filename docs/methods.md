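# Methods

`provseg` asks a training-data question with a segmentation pipeline built
around it: if the contours used to train a CT segmentation CNN are drawn in a
low-contrast modality (and are therefore noisy), how much segmentation
performance is lost — and how much predictive uncertainty is gained —
compared to training on high-quality contours drawn in a high-contrast
modality and propagated into the CT frame?  The package implements the whole
study at desk scale on synthetic phantom cohorts, since the clinical cohorts
such studies use are private.

## The synthetic cohort

Each case is one "patient": the same anatomy rendered in two frames/modalities.

**Structure model.** Each hippocampus proxy is a curved tube: a parametric
centerline `c + s·d + bow(s)·e_x` with direction `d` inclined 20° to the
axial plane (the reported inclination of the hippocampus body), a zero-mean
quadratic lateral bow toward the midline, and a radius tapering linearly from
1.15·r at the head to 0.7·r at the tail.  The left tube is mirrored across
the midsagittal plane.  Masks are rasterized analytically (nearest centerline
sample within its radius), so geometry is exact in every frame.

**Frames.** The anatomy lives in a canonical frame.  The pseudo-MR volume is
stored *tilted*: rotated about the left-right axis so the structure lies in
the axial plane, emulating the reformat used for manual contouring (fewer
slices to contour).  `CaseRecord.tilt_angle_deg` records that rotation.  The
pseudo-CT frame is the canonical frame moved by a small random rigid jitter
(`affine_jitter`, default ±2.5 mm / ±2.5°); `true_affine` maps untilted-MR
(= canonical) coordinates to CT coordinates — exactly the role of a
registration matrix computed between untilted volumes.  Contour propagation
therefore reverts the tilt and applies `true_affine`, mirroring the clinical
pipeline.

**Appearance.** Pseudo-MR: background 100, foreground contrast 60, noise SD 6
(CNR 10).  Pseudo-CT: background 30 HU, contrast 20 HU, noise SD 10 (CNR 2) —
the study design attributes CT contouring error to poor soft-tissue contrast,
so the pseudo-CT keeps the structure barely visible while the pseudo-MR is
easy.  Generation refuses specs whose MR CNR does not exceed the CT CNR by a
configurable factor (default 2), and refuses structures that violate a
2-voxel margin in any frame after jitter.

**What the generator does not emulate:** anatomical texture and neighbouring
structures (ventricles, brain stem) that a real CT model would exploit,
scanner-specific noise spectra, bias fields, deformable misregistration, and
inter-annotator systematic bias.  Passing tests therefore show that the
*pipeline* recovers training-label-quality effects under controlled
conditions, not that the effect sizes transfer to clinical data.

## Contour degradation

Manual contouring error on low-contrast images is spatially correlated along
the contour, not voxelwise flip noise.  `degrade_contour` works per side and
per axial slice on the clean CT-frame mask:

1. one global in-plane shift per side ~ N(0, `global_shift_sd_mm`);
2. an independent in-plane jitter per slice ~ N(0, `per_slice_jitter_sd_mm`);
3. a correlated boundary perturbation: the slice's signed distance function
   (mm) is compared against a Gaussian random field (white noise smoothed to
   correlation length `corr_length_mm`, normalized to
   `boundary_noise_sd_mm`), i.e. the new region is `{x : sdf(x − shift) ≤
   field(x)}`;
4. each occupied end slice is dropped with probability `dropout_prob_slice`
   (uncertainty about the superior/inferior extent).

All scales zero reproduces the input bitwise.  Expected Dice against the
clean contour decreases monotonically in each scale (verified by Monte
Carlo).  The correlation length is a free knob (real studies report only
summary agreement); 5 mm was chosen with the calibration below.

**Calibration.** `calibrated_degradation()` (boundary 2.0 mm, shift 1.8 mm,
jitter 1.6 mm, end-slice dropout 0.5, correlation 5 mm) was fixed by a
Monte-Carlo search on the default phantom to reproduce the reported
inter-modality contour agreement of roughly median Dice 0.59 / median
Hausdorff ≈ 6 mm; over 50 seeded draws it yields mean Dice ≈ 0.61 and median
HD ≈ 6.2 mm.  `desk_calibrated_degradation()` re-targets the same ~0.59
agreement for the smaller desk-scale structures (thinner tubes need gentler
absolute noise for the same relative disagreement).

## Preprocessing

* Resampling preserves physical extent; images interpolate trilinearly,
  masks by per-label indicator interpolation + argmax (no staircase noise).
* CT normalization: window center/width 40/80 HU mapped to [0, 1], clamped.
* MR normalization: 2nd/98th intensity percentiles mapped to 0/1, clamped
  (clamping keeps network inputs bounded; a constant volume is an error).
* Contour propagation: mask → 1 mm isotropic → revert tilt → apply affine →
  Gaussian-smooth each label indicator (`smooth_sd_mm`, default 1.0 mm) →
  threshold (default 0.5) → argmax.  Smoothing suppresses resampling
  artifacts (single-voxel spurs vanish); both knobs are config-exposed since
  the clinical pipeline specifies neither.
* Augmentation: left-right flip (mirror + label swap) and on-the-fly rigid
  draws — isotropic scale ~ N(1, 2.5%), rotations ~ N(0, 5°/5°/2.5°) about
  the axial/sagittal/coronal axes.  Augmentation is applied to the sampled
  slab (not the whole volume) for speed; for 5–7-slice slabs the difference
  is a slight attenuation of out-of-plane rotation context.

## Network

A hybrid 2D/3D dense encoder-decoder mapping a `slab_in`-slice slab to a
1-slice, 3-class (background/left/right) softmax map.  In-plane it is a
Tiramisu-style dense network: dense blocks (BN → ReLU → 3×3 conv → dropout
per layer, concatenated), 2×2 max pooling, transposed-convolution upsampling
with skip connections.  Between each encoder dense block and its pooling sits
a separable 3D convolution — padded 3×3×1 then unpadded 1×1×3 — so each of
the `n_levels − 1` encoder levels consumes two slices: with four levels the
slab shrinks 7→5→3→1 and the decoder runs purely 2D.  Whether the decoder
should also carry z-convolutions is an open design point; placing all three
on the encoder is the unique arrangement that exactly consumes a 7-slice slab
with three poolings, so that is what is built (the config validates
`slab_in − slab_out = 2·(n_levels − 1)`).  Skips pass the central slice of
each encoder level to the matching decoder level.

The implementation is pure NumPy with hand-written backward passes for every
layer (im2col/matmul convolutions, batch-norm, dropout, pooling, transposed
convolution) plus Adam; the full backprop is verified against central finite
differences to < 1e-3 relative error in the test suite.  All randomness
(init, dropout, sampling) flows through seeded `numpy.random.Generator`s, so
training and Monte-Carlo inference are exactly reproducible.

**Dice loss.** `1 − (2·Σ_fg p·t + ε)/(Σ_fg p + Σ_fg t + ε)` with ε = 1e-5,
pooling both foreground channels and the batch; background is excluded.
Pooling the channels (rather than averaging per-channel ratios) keeps the
loss near 1 when the prediction misses all foreground and avoids a 1/ε
gradient spike when a foreground class is absent from a batch.

**Defaults.** 4 levels, 2 layers/block, growth 8, dropout 0.1, 256² in-plane
(configurable down to 20² for desk scale); `sep_channels` optionally narrows
the separable convolutions.  Width choices follow the Tiramisu family at
strongly reduced scale; the parameter count is deterministic per config.

## Training and model selection

Random weight initialization and a log-uniform learning rate are the only
searched hyperparameters.  A successive-halving ladder trains `n₀` fresh
trials to the first budget, then repeatedly resumes the top half — ranked by
the mean Jaccard coefficient of full-volume predictions on the fold's
validation cases, ties to the lower trial id — to the next budget.  The
reference schedule 16(5k)/8(10k)/4(20k)/2(40k)/1(80k) is encodable
(`HyperbandSchedule.reference()`); the desk default is (4, 60)/(2, 120)/
(1, 240).  Survivors resume from their checkpoint (standard successive
halving); whether the original study re-initialized between rungs is
unknown.  Validation Jaccard is computed on full volumes rather than slabs
because model selection should reflect the deployment task.

Training slabs are drawn 80% within 10 slices of the foreground, 20%
uniformly; batch size 4; Adam β = (0.9, 0.999).  A non-finite loss marks the
trial failed and excludes it from selection.

## Inference and uncertainty

`predict_volume` slides the slab window over z with stride 1, edge-padding by
replicated slices so every input slice receives a prediction.
`postprocess` thresholds each foreground channel at 0.5, keeps the single
largest 26-connected component per side (deliberately preserving the known
failure mode where a large false positive displaces the true structure), and
optionally resamples to an isotropic evaluation grid.

`mc_entropy_map` runs N stochastic forward passes with dropout active at
every dropout layer (batch norm stays in inference mode), averages the
softmax, and reports the voxelwise entropy of the mean predictive
distribution, `U(x) = −Σ_k p̄_k ln p̄_k` (nats, bounded by ln 3).  Entropy of
the mean — rather than mean per-sample entropy — is the standard predictive
uncertainty estimator.  The reference sample count is N = 25; the desk
config uses N = 5.

## Evaluation metrics

All metrics run on 3D masks, separately per side.  Surface voxels are mask
voxels with a face-adjacent background neighbour; distances are spacing-aware
Euclidean distance transforms.

* Dice `2|A∩B|/(|A|+|B|)`; both empty → 1, one empty → 0.
* Mean surface distance: mean of the two directed mean surface-to-surface
  distances; Hausdorff: max of the two directed maxima.  Undefined for empty
  masks — such records carry a flag, are excluded from distance aggregates
  (with a reported count) and count as failures in the RTOG rate.
* Contour Dice at tolerances 1/3/5/7/10 mm: per-axial-slice 2D boundary
  points, pooled over slices, symmetric form — the fraction of pooled contour
  points of either mask lying within the in-plane tolerance of the other
  mask's same-slice contour.  The literature definition it follows is not
  fully specified (one-sided vs symmetric, per-slice vs pooled); the pooled
  symmetric choice is documented here, not asserted as the original.
* RTOG 0933 passing rate: percentage of cases with Hausdorff ≤ 7 mm.
* Uncertainty density at τ = k·1.5 mm, k = 1..5: predicted components not
  intersecting the reference are removed (true-positive filtering), then the
  mean entropy over all voxels within τ of the filtered prediction's surface.
  No true-positive component → flagged, no density recorded.
* Wilcoxon signed-rank (two-sided, zero differences dropped): delegated to
  `scipy.stats.wilcoxon` — exact null for n ≤ 25 without ties, normal
  approximation with continuity and tie correction otherwise; the test suite
  cross-checks the exact branch against a full 2ⁿ enumeration.

Aggregates are median, IQR (Q3 − Q1, linear-interpolation quantiles), mean
and SD per metric.

## The experiment

`run_experiment` generates a cohort with seeded random fold splits in 3:1:1
train/validation/test blocks (each case tested in exactly one fold), prepares
each case (CT windowing, MR percentile normalization, propagated clean
ground truth in the CT frame), and then per fold and per arm runs the
hyperparameter search, predicts the held-out cases, postprocesses, and
scores everything against the same propagated-clean ground truth:

* `clean_contours` — CT images, propagated clean contours (the high-quality
  training-label arm);
* `degraded_contours` — CT images, degraded contours (the noisy-label arm);
* `mr_upper_bound` — MR images with clean MR-frame contours; its predictions
  are propagated to the CT frame before scoring;
* `manual_degraded` — the degraded contours themselves scored against ground
  truth (no human in the loop: the degradation model plays the low-contrast
  annotator).

Monte-Carlo entropy maps and uncertainty densities are computed for the two
CT-frame arms.  Arm comparisons use the per-case paired structure (same test
case and side in both arms) with the Wilcoxon signed-rank test.  A failed
fold yields a partial report with a failure manifest; `verify_no_leakage`
asserts from the manifest that every prediction comes from its fold's test
set and no case is tested twice.

**Desk-scale conditions** (`desk_config`): 20 cases in 5 folds of 12/4/4;
18×24×24 grids at 1.5 mm isotropic (structures scaled to fit with margins);
a 3-level network (5-slice slab, growth 4, 1 layer/block, separable-conv
width 8, ~5.8k parameters); halving ladder (4, 60)/(2, 120)/(1, 240);
learning rate log-uniform on [1e-3, 3e-2]; N = 5 Monte-Carlo samples;
training, prediction and evaluation on the native 1.5 mm grid.  One replicate
runs in a few minutes on a single CPU.  At this scale a replicate reproduces
the directional findings: the clean-contour arm's median test Dice exceeds
the degraded-contour arm's by a wide margin, and the degraded-contour arm's
uncertainty density is higher at every tolerance.

## Numerical choices and degenerate inputs

* Label resampling ties: argmax over interpolated indicators; background wins
  exact ties by channel order.
* Signed-distance identity: with all degradation scales zero the region
  `{sdf ≤ 0}` is exactly the input region (interior sdf < 0, exterior > 0).
* `normalize_mr` on a constant volume and `surface_distances` on an empty
  mask raise; callers record flags instead where the study design expects
  missing values.
* Entropy is clipped to [0, ln 3] against floating-point drift; probabilities
  are clipped at 1e-12 before the log.
* Successive-halving ties break to the lower trial id, making selection
  deterministic.
* Grids must be even in-plane per pooling level (validated at config time).

## Known limitations

* The NumPy network is desk-scale; the full-resolution 256² / 80k-iteration
  configuration is expressible but not practical on one CPU.
* Slab-level (not volume-level) rigid augmentation slightly underrepresents
  out-of-plane rotation effects.
* The phantom's two-tube world contains no distractor anatomy, so the
  absolute metric levels are far above clinical values; only effect
  directions and the degradation calibration are designed to be comparable.
* Uncertainty densities are computed on the prediction grid (1.5 mm at desk
  scale), not a finer evaluation grid.
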