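# Methods

This note records the models and procedures `roiaudit` implements, the
parameter choices that matter, and the limits of what the synthetic
validation shows.

## The audit

The object under audit is a multi-label image classifier together with a
per-image binary ROI mask.  Five dataset variants are derived per image:
`FULL` (identity), `ONLY_ROI` / `NO_ROI` (keep only the inside / outside of
the precise mask), and `ONLY_ROI_BB` / `NO_ROI_BB` (the same with the
tightest axis-aligned bounding box, which removes shape information and
includes or excludes structures adjacent to the ROI).  Masked pixels take
the value 0 on the [0, 1] intensity scale — identical to the black padding
added during preprocessing — and masking happens *before* any
model-specific feature standardization, so removed regions carry no
residual signal.

Preprocessing resizes each image by `S / max(H, W)`, centers it, and pads
with black to `S × S` (default S = 512 at full scale; the synthetic
desk-scale runs use S = 128).  The mask undergoes the identical geometric
transform with nearest-neighbour interpolation.  Non-binary 8-bit masks are
binarized at > 127.  Records whose mask is missing/empty or whose
mask-quality score is not strictly above 0.7 are excluded (the boundary
value 0.7 itself is excluded, matching the "strictly above" reading of the
quality recommendation the score emulates); exclusions are logged.

One model is trained per variant under a 5-fold label-stratified
cross-validation; each fold model early-stops on its held-out fold's
validation loss.  Every model is then evaluated on every masked variant of
a held-out test set, giving the 5 × 5 (× classes) cross-masking AUC matrix
of fold means ± SD.  Undefined cells (single-class evaluation subset) are
reported missing, never imputed as 0.5.

**Interpretation rule.** Masking only removes information, so a model
trained and evaluated without the ROI should collapse to chance unless the
data carry signal outside the ROI — a shortcut.  The automated verdict
tests each `NO_ROI` / `NO_ROI_BB` diagonal cell against a label-permuted
null (one-sided permutation p-value per fold, add-one corrected, default
200 permutations) and flags risk when `p < α` in at least `min_folds`
folds (defaults α = 0.05, 3 of 5, strict inequalities).

## Statistics

*AUC* is the Mann–Whitney rank statistic with half credit for ties,
computed with midranks in O(n log n); it equals the pairwise-count
definition exactly, which the tests verify against an O(n²) oracle.

*DeLong test.* Two score vectors on the same samples are compared through
their structural components: the placement of each positive among the
negatives (`v10`) and of each negative among the positives (`v01`),
computed with midranks for tie correctness.  The empirical covariances of
the paired components give the variance of the AUC difference;
`z = (A₁ − A₂)/√var` is referred to the normal distribution, two-sided.
Degenerate cases: identical AUCs with zero variance give p = 1; unequal
AUCs with zero variance give p = 0 with a warning.  The implementation is
cross-checked in the tests against the `pROC` reference implementation in
R and calibrated under a simulated null (rejection rate at α = 0.05 within
[0.035, 0.065] over 1000 replicates).  No multiple-testing correction is
applied across cells or classes; the report states this.

*Fold rule.* A comparison is "significant" when `p < 0.05` in ≥ 3 of the
5 folds, strictly.  This is deliberately conservative and simple; the
boundary behaviour (p = 0.05 never counts) is pinned by tests.

*Dilation.* Mask growth uses morphological dilation with a Euclidean disk
of radius `factor` pixels at the working resolution (`factor = 0` is the
identity).  Two sweep protocols exist: evaluating the FULL-trained model on
increasingly dilated `ONLY_ROI`/`NO_ROI` test images (where does the signal
live?), and evaluating the strategy-trained model itself with the dilation
applied only to the positives' or only the negatives' masks
(ROI-size-confound probing).  Default desk-scale factors are
{0, 2, 5, 12, 25} at S = 128, i.e. the same mask-growth fractions as
factors ≈ 8–100 at S = 512.

## Backbone classifier

The built-in model is a compact sklearn-style estimator
(`PooledMLPClassifier`): images are block-pooled to a 32 × 32 grid with
*both* the block mean and the block max retained (2048 features), features
are standardized, and a single hidden ReLU layer (64 units — the model's
embedding) feeds independent per-class sigmoid outputs.  The mean channel
carries diffuse structure (blobs, visible area); the max channel makes
small high-contrast marks (device tokens, text glyphs) detectable wherever
they fall within a block, emulating a convolutional detector's translation
tolerance.  The backbone is pluggable: the audit only requires
`predict_proba` and `embed`.

Training: Adam on (optionally class-weighted, weights = inverse positive
frequency) binary cross-entropy; early stopping restores the best epoch's
weights when the validation loss has not improved by `delta` for
`patience` epochs.  The full-scale protocol defaults (`TrainingConfig`)
are lr 1e-4, batch 32, 250 epochs max, patience 10, delta 1e-3, rotation
±45°, horizontal flip p = 0.5, brightness factor 0.7–1.1.  The desk-scale
protocol (`TrainingConfig.desk_scale()`) raises the learning rate to 1e-3
for the small backbone, caps epochs at 120, and keeps only the horizontal
flip: augmentation here operates on already-masked images, and rotation or
brightness scaling would move or re-scale the masked-out hole, breaking
the exactness of the masking contract.  Flipping image and mask regions
together commutes with masking and is kept.

Two inference-time safeguards matter for the audit's validity and are part
of the model, not the evaluation:

* **Support pruning.** Features that never varied during training or were
  visible in fewer than 5% of training images are forced to zero at
  inference.  A model cannot have learned anything about such features;
  leaving their near-initialization weights active would inject systematic
  noise exactly when masked regions reappear (dilation sweeps,
  cross-masking cells).
* **Training-range clipping.** Standardized features are clipped to the
  per-feature range observed during training.  Occlusion (Shapley) and
  cross-masking push features far outside anything seen in training, where
  the network's response is unconstrained; clipping bounds those
  out-of-distribution excursions.  Both safeguards are ordinary robustness
  measures and apply identically to all strategies.

The tabular baseline is a per-fold logistic regression (standardized
features) on sex, birth year, and projection, using the same folds as the
image models, after dropping rows with any missing feature.  It quantifies
how much of the image models' AUC is explainable by metadata alone.

## Attribution

Superpixels default to a regular grid (`⌈√M⌉` cells per side, trailing
cells merged so exactly M nonempty segments remain); grid segmentation
makes the oracle tests deterministic, and content-based SLIC segmentation
is available as an option.  The value function of the cooperative game is
the model's class probability with absent segments occluded to black (the
masking value).  `exact_shapley` enumerates all 2^M coalitions with the
combinatorial weights (refused above M = 15).  `shapley_occlusion` samples
segment permutations in antithetic pairs within a model-call budget
(default 1000 calls); marginal contributions along one permutation
telescope to `f(x) − f(∅)`, so the estimator satisfies the efficiency axiom
exactly and assigns exactly zero to dummy segments, and when the budget
covers all coalitions it switches to exact enumeration.  Antithetic pairs
are exact for games with only pairwise interactions; the variance tests
therefore use a third-order game.

`roi_attribution_share` is the fraction of *positive* attribution mass on
segments whose pixel majority lies inside the ROI.  The audit default is
25 grid segments at S = 128 (≈ 26 px cells, organ scale): much finer grids
dilute the share with per-segment Monte-Carlo noise and occlusion
artifacts; the segment count of the original occlusion-SHAP setting is not
specified anywhere, so this is a package choice.

## Embedding comparison

For the FULL-trained model, each test image is embedded unmasked and under
each masking strategy; the paired cosine similarities are summarized per
strategy and per class (plus a pooled "All" row).  A seeded t-SNE
(perplexity 30, capped at 2000 points stratified by strategy, exact
gradients below 500 points so duplicate inputs stay coincident) gives the
global view.  A standing caveat is attached to every similarity output:
proximity of pre-head features can disagree with the AUC ordering —
variants sharing many pixels embed close together regardless of what the
classification head uses — so these comparisons are supporting evidence
only.

## Synthetic data generator

The generator emulates the *confound structure* of chest X-ray and fundus
datasets, not their appearance.  All randomness flows from one seed through
per-record child streams; identical configurations are byte-identical, and
any subset of records is reproducible alone.

* **Geometry.** `two_lungs`: two vertically elongated ellipses (radii
  0.28 S × 0.11 S, jittered) with a mediastinal gap, inside a brighter
  body ellipse on a dark background.  `disc`: one filled circle (radius
  0.11 S, size jitter 6%, position jitter 0.03 S — disc location in fundus
  photographs is anatomically consistent) on a mid-bright retina circle.
* **Labels.** Exactly `round(n · prevalence)` positives by stratified
  assignment.  Folds are label-stratified.
* **Disease signal** (positives only, strictly inside the ROI; the
  pattern centre is drawn from the mask eroded by twice the pattern
  scale, like a lesion inside the organ rather than on its rim).  For
  lungs: an additive difference-of-Gaussians blob (bright core, faint wide
  negative surround whose integrals cancel) plus mild core texture —
  an opacity-like *contrast* pattern with zero net intensity, default
  amplitude 0.25 (5× the noise SD).  For the disc: a zero-mean *texture*
  patch (local variance increase, hard-truncated to stay ≥ 2 px inside the
  disc boundary).  Zero-net-intensity signals are essential: a
  net-brightness signal would let any model read the label off the total
  visible intensity, confounding every manipulation that changes visible
  area (dilation, bounding boxes); clinically, opacities and cupping are
  contrast/structure changes too.
* **Shortcuts.** `token`: a small bright rounded rectangle with a
  lead-like line (device emulation), placed uniformly outside the ROI;
  `border_text`: a glyph band in a top/bottom border strip (burnt-in
  annotation emulation); `global_offset`: constant offset on all non-ROI
  pixels.  Presence matches the label with probability ρ, so
  `P(shortcut | y=1) − P(shortcut | y=0) = 2ρ − 1`; ρ = 0.5 is
  label-independent.  Shortcut pixels never intersect the ROI (placement
  retries, then a named error).  Amplitudes (token 0.45, text 0.5
  defaults) reflect that such artifacts are high-contrast in real images;
  no real-data calibration exists for them, they are free parameters.
* **Size confound.** `roi_size_label_slope` scales the ROI radii by
  (1 + slope) for positives; slope 0.15 gives a +32% area confound,
  emulating a disc-size bias.
* **Metadata.** A binormal latent with separability `metadata_auc`
  (mean shift √2 · Φ⁻¹(AUC)) is quantile-binned into birth years; sex and
  projection are label-independent.  At 0.5 all columns are independent of
  the label; at 1.0 the year ranges are disjoint (linearly separable).
  Monotone binning preserves the latent's AUC, so a logistic model on the
  metadata recovers ≈ `metadata_auc` (verified at 0.75 ± 0.05, n = 2000).
* **Mask quality.** With probability `low_quality_fraction` (default 0.1)
  the score is drawn from U(0.40, 0.695), otherwise from U(0.72, 0.99),
  so the strict 0.7 filter removes a controllable fraction.

### What the synthetic validation does and does not show

Passing the audit's validation on these datasets shows that the *pipeline*
is sound: the statistics are exact/calibrated, masking algebra is lossless,
planted shortcuts of realistic strength (ρ ≥ 0.8–0.9) are flagged and
label-independent ones are not, an ROI-size confound produces the
characteristic climbing dilation curve while its absence leaves the curve
flat, and attribution mass localizes to wherever the true signal was
planted.  It does **not** show that any particular real dataset is clean
or biased, nor that the compact backbone behaves like a large CNN on real
textures; photorealism, patient-level structure, multi-site effects and
label noise are all absent from the generator by design.

## Problem sizes and defaults

Desk-scale study conditions, used by the test suite and the acceptance
script: n = 600 images at 128 × 128 (450 train / 150 test), prevalence
0.5, noise SD 0.05, 5 folds, token ρ = 0.9 vs. matched ρ = 0.5 control,
disc slope 0.15 vs. 0 control, attribution over 10 positives with 1000
model calls each.  A full run of the acceptance script takes ≈ 5 minutes
on one CPU.

## Known limitations

* The backbone has no spatial weight sharing; its translation tolerance
  comes entirely from block pooling, and signals much smaller than a
  pooling block (4 px at the defaults) fade.
* The verdict's permutation null tests each cell marginally; with many
  classes the family-wise error of the *verdict* grows (no correction, as
  in the per-class reporting convention the audit follows).
* Class-conditional dilation applied at evaluation time necessarily shows
  the model content it never saw during training; the support-pruning and
  range-clipping safeguards bound, but cannot eliminate,
  out-of-distribution response in that regime.
* `padchest_filter` implements the chest X-ray metadata filtering rules
  (lateral-view removal, null/excluded labels, mask join, strict quality
  cut) against the real CSV dialects, but the package ships no real data;
  the filter is validated against an independent row-by-row oracle on
  synthetic tables in the same dialect.
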