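# Methods

This note documents the models, numerical choices and limitations of
`phasestain`. It is written for a reader who wants to know exactly
what the package computes and what passing its tests does and does not
demonstrate about real microscopy data.

## The problem being modeled

Polyglutamine-expanded Huntingtin exon 1 overexpressed in cultured
cells forms dense intracellular aggregates within ~48 h. A
multi-plane transmitted-light microscope records an 8-plane
brightfield defocus stack of each field of view (350 nm interplanar
spacing, 111 nm back-projected pixels); an algorithm converts the
stack into a quantitative phase image (QPI), whose pixel values (rad)
are proportional to the local dry-mass surface density through the
refractive increment. A U-Net trained on pixel-registered pairs of
label-free inputs and widefield fluorescence projections then predicts
the fluorescence channel from the label-free input alone, so unlabeled
aggregates can be found, segmented and weighed in live cells.

## Synthetic specimens (`simulate`)

The generator's role is to make every downstream stage testable with
known ground truth. A scene consists of:

- **Cells**: 2–3 overlapping ellipses with semi-axes 0.22–0.45 of the
  field size and phase levels drawn from `cell_phase_range_rad`
  (default 0.3–0.8 rad). Where cells overlap the maximum level is
  kept. At 60× magnification a ~10–40 µm field is dominated by one or
  two adherent cells, which the relative sizing reflects.
- **Aggregates**: compact ellipses (axis ratio 1–1.8) with phase drawn
  from `aggregate_phase_range_rad` (default 1.2–2.0 rad, strictly
  above the cell interval so aggregate pixels always rise above the
  cell background). Footprints are rasterized by ranking pixels on the
  elliptical quadratic form and keeping exactly
  `round(area/pixel_area)` of them, so recorded truth areas are exact
  to the grid. The default area range is 3–30 µm²; 3 µm² is the
  smallest aggregate the workflow is expected to resolve. An optional
  core/shell profile raises the innermost 30% of pixels to 1.3× the
  shell level, echoing the core-and-shell ultrastructure of unlabeled
  inclusions. Aggregates that cannot be packed without overlap raise
  an error rather than being silently dropped.
- **Phase blur**: the assembled piecewise-constant map is smoothed
  with a Gaussian (`boundary_sigma_px`, default 3 px ≈ 0.33 µm),
  standing in for the diffraction-limited transfer of a high-NA
  objective. Smoothing conserves the integral, so scene bookkeeping
  (total phase = cell contribution + Σ aggregate contributions)
  closes exactly.
- **Fluorophore density**: a spatially uniform diffuse pool plus a
  per-aggregate bound amplitude (0.7–1.3). The diffuse level is solved
  so that `diffuse_fluor_fraction` (default 10%) of total fluorophore
  lies outside aggregates; scenes without aggregates get a flat
  `diffuse_floor` (0.05), the negative-control condition.

**Rendering.** The fluorescence channel is a Poisson draw at
`fluor_photon_scale` expected photons per unit density (default 5000,
a bright widefield exposure; lowering it emulates short exposures).
The brightfield stack propagates the unit-amplitude field `exp(iφ)`
with the exact (non-paraxial) angular-spectrum transfer function to
each of the 8 symmetric plane offsets and records `|U|²`; evanescent
components are cut. For the band-limited scenes the generator
produces, propagation conserves energy to machine precision and
agrees with a single-FFT Fresnel propagator to ~1e-6 RMS, which the
tests use as an independent oracle.

**Time lapses** place one aggregate whose area follows a logistic
curve with midpoint halfway between the onset frame and the last
frame, reaching `final_area_um2` at plateau; frames before onset
contain only diffuse fluorophore. Defaults (60 frames at 2 min,
onset at frame 10, rate 0.15 min⁻¹) give a plateau within 5% of the
target by the end of the series (this requires
`k·(t_end − t_mid) ≥ ln 19 ≈ 2.94`). Lateral drift is applied by
re-rendering the scene at drifted coordinates each frame, which keeps
truth masks exactly consistent with the continuous maps.

**Chimeric aggregates** for heterogeneity testing remove a contiguous
angular sector containing exactly `round(fraction·n)` of each
aggregate's pixels and splice in donor-scene background (phase,
fluorescence and mask together), retrying the donor placement until no
donor aggregate pixels are imported.

**What the generator does not emulate**: organelle texture, partially
coherent white-light illumination, polarization, 3-D refractive-index
structure, camera read noise and optical aberrations. Tests passing on
these scenes therefore demonstrate the correctness and internal
consistency of the algorithms, not field performance on real
micrographs.

## Phase retrieval and dry mass (`qpi`)

The original instrument's Fourier-filtering phase retrieval is
proprietary; this package implements a standard transport-of-intensity
(TIE) style inversion, validated by round trips against the built-in
forward model rather than by equivalence to any external code:

1. Normalize each plane by its mean and estimate the axial derivative
   of the intensity contrast by a per-pixel least-squares linear fit
   across the plane offsets (the symmetric offsets cancel the
   quadratic term of the defocus expansion).
2. In Fourier space, a weak phase object obeys
   `Î(f, z) ≈ δ(f) + 2 sin(πλz|f|²) φ̂(f)`, so the fitted slope at
   focus is `D(f)·φ̂(f)` with `D(f) = 2πλ|f|²`. The inversion applies
   the Tikhonov-regularized filter `D/(D² + ε²)`.
3. The phase background (median over pixels outside an optional
   foreground mask) is subtracted so dry mass cannot depend on a
   global offset.

**Regularizer.** `ε = regularizer × max(D)` with default
`regularizer = 1e-5`. The scale matters: the crossover frequency where
the filter attenuates by half grows as the square root of the
regularizer, and at 1e-3 it sits near (7 µm)⁻¹ — inside the band
occupied by cell bodies — which measurably destroys the retrieved map
(round-trip Pearson r drops from 0.999 to ≈0.4 on noise-free
weak-phase scenes). At 1e-5 the crossover is ≈(22 µm)⁻¹ and the
retrieval is accurate for noise-free and moderately noisy stacks alike;
raise the value for very noisy data. With shot noise the round-trip
quality improves monotonically with plane count (8 ≥ 4 ≥ 2), as more
planes average the per-pixel derivative estimate.

The TIE linearization assumes a weak phase object (max φ ≲ 0.5 rad)
and defocus small against the feature period; accuracy degrades for
strong-phase specimens, which is why quantitative round-trip claims in
the tests are made in the weak-phase regime (max ≈ 0.3 rad).

**Dry mass** is the exact pixelwise map
`σ = λ/(2πα)·φ` (λ default 0.550 µm, the mean wavelength of a
white-light halogen source; α = 0.19 µm³/pg, the canonical protein
refractive increment), and an aggregate's mass is the sum of σ over
its mask times the pixel area. At the defaults, 1 rad ↦ 0.4607 pg/µm²
and a uniform 100-pixel mask at that density weighs 0.5676 pg.

## Data preparation (`prep`)

Planes are registered to the central plane by phase correlation with
20× sub-pixel refinement and aligned with a Fourier shift. Training
labels are maximum z-projections of the fluorescence stack;
classification labels are their Otsu masks, so classification labels
always derive from regression labels. Otsu's threshold is computed on
a fixed 256-bin histogram of the min-max-normalized image and returns
a bin edge; when the between-class variance plateaus across empty
bins, any edge inside the plateau yields the identical binarization.
Images are min-max normalized to [0, 1] (a constant image maps to
zeros, with a warning). Splits draw 10% of acquisitions for test and
20% of the remainder for validation, operate on acquisition ids (so
time-lapse frames never straddle a boundary) and can stratify by
construct tag. Reduced-plane inputs (1/2/4) are taken symmetrically
about the stack center: planes 4; 4–5; 2, 4, 5, 7 (1-based).

## The model (`model`, `nn`)

The architecture is the canonical 4-level U-Net — two 3×3
convolutions + ReLU per level, 2×2 max pooling, feature maps doubling
per level, 2× up-convolutions (nearest upsampling + 2×2 convolution,
the classic parameter count) with skip concatenation, a final 1×1
convolution and a sigmoid — with `base_features = 16` instead of 64.
That ÷4 reduction cuts trainable parameters from 31,030,593 to
1,940,817, a floor ratio of 15, verified against a layer-by-layer hand
count.

No deep-learning framework is part of the dependency set; the layers,
backpropagation (verified against finite differences) and the Adam
optimizer are implemented in NumPy (`phasestain.nn`), float32
throughout, with every random draw taken from an explicit seeded
generator. Runs are bit-reproducible on one machine; across BLAS
builds small numerical differences are possible, and test tolerances
are sized for that.

**Training recipe**: Adam at 1e-4, MSE loss for both regression
(targets: normalized fluorescence projections) and classification
(targets: binary Otsu masks — the same loss, deliberately, rather
than cross-entropy), early stopping on the validation loss and
best-checkpoint weight restoration. One addition proved necessary at
desk scale: the final convolution's bias is initialized to the logit
of the training-label mean. Labels here are sparse (bright aggregates
on a dim background), and with an unbiased start the sigmoid+MSE
combination descends into a constant-output collapse from which small
desk-scale runs do not recover (held-out r ≈ 0 after hundreds of
steps); with the bias start the same runs reach r > 0.9. This is the
standard initialization for imbalanced dense prediction.

**Desk-scale problem sizes.** The package's reference training run —
used in the test suite — fits the base-16 U-Net on 200 synthetic
96×96 phase/fluorescence pairs (144 train / 36 validation / 20 test
after the split), batch size 4, at most 20 epochs with patience 3
(early stopping typically ends it sooner). The 96 px field keeps a
full training run in the minutes range on one CPU core while
remaining divisible by 2⁴ for the 4-level encoder.

**Input normalization.** Phase inputs are divided by a fixed
calibration constant (2.0 rad, the top of the default aggregate
interval) and clipped to [0, 1]; brightfield intensity inputs, which
carry no absolute scale, are min-max normalized per plane, as are the
fluorescence labels. The distinction is deliberate: quantitative
phase has physical units, and the inclusion/cytoplasm contrast (1.2–
2.0 rad vs 0.3–0.8 rad here) is the signal that makes a dense protein
aggregate identifiable. Stretching each phase image to [0, 1]
independently erases that cue — in an aggregate-free field the
brightest cell lands at 1.0, and a small bright cell partially
overlapping a dimmer one becomes pixel-for-pixel indistinguishable
from an aggregate resting on a cytoplasm pedestal. In a texture-free
synthetic world no model, however good, can then satisfy the
negative-control contract; with the fixed scale the task is
well-posed. Real micrographs carry texture cues that soften this
degeneracy, but fixed-scale normalization of calibrated phase is the
physically meaningful choice there too.

**Training-set composition.** Each scene's aggregate count is drawn
uniformly from 0–3, so about a quarter of training fields contain no
aggregate — as in a scanned acquisition, where most fields of view
are aggregate-free. This matters under per-image min-max
normalization: in an aggregate-free field the brightest *cell* is
stretched to 1.0, and a model trained only on aggregate-positive
fields learns the intensity shortcut "value ≈ 1 ⇒ aggregate" and
hallucinates on negative controls. Negative fields in the training
distribution break that shortcut. Their labels are all-zero: a
rendered fluorescence image whose peak-to-peak range falls below its
mean carries no real structure (diffuse background plus shot noise),
and min-max stretching of shot noise would otherwise fabricate a
bright label for a blank field. Pearson r against an all-zero label
is undefined and reported as NaN, so held-out correlation summaries
average over the aggregate-containing test pairs.

**Masks from predictions**: Otsu thresholding suits
aggregate-containing fields; for fields that may contain nothing (the
negative controls) the classification-style fixed 0.5 cut is the
appropriate rule, since Otsu always splits an image regardless of
absolute level. `triage_fov` votes per model on the Otsu mask
(positive iff some 8-connected component reaches 3 µm²) and flags a
field only on unanimous consensus — trading false negatives for a
minimal false-positive rate; the aggregate count is taken on the
intersection of the per-model masks.

## Metrics and experiments (`metrics`)

- **NMSE** defaults to `Σ(pred−truth)²/Σtruth²`. The alternative
  normalization by the *square of the summed* label is available
  behind a flag, but it scales with image size and cannot produce
  magnitudes comparable across crops, so the sum-of-squares reading is
  the default.
- **SSIM** uses a 7×7 Gaussian window (σ = 1.5), K₁ = 0.01,
  K₂ = 0.03, data range 1.0 on normalized images, kernel-weighted
  moments and a cropped border; the tests check it against a literal
  per-window double-loop implementation to 1e-6.
- **Overlap**: Jaccard, Dice, and pixelwise F1 with the second mask as
  truth (equal to Dice for binary masks — asserted at runtime). Two
  empty masks count as perfect agreement, with a warning.
- **Dice is reported as a coefficient** (higher is better).
- **Robustness experiment**: for each phase-noise variance (e.g. up to
  the 0.48 rad² stress level, where the specimen is no longer visually
  identifiable) the scene's phase map is corrupted (globally or inside
  aggregates only), optionally pre-filtered, normalized and predicted;
  each row carries the full metric report. The pre-filter is a 3×3
  median by default (Gaussian available) — deliberately the simplest
  denoiser that restores the aggregate signal at high variance.
- **Subsampling study**: mean |subsample SD − full-set SD| of
  aggregate area and circularity (ddof = 1) over without-replacement
  draws; 10⁴ repeats by default (the full-scale study used 10⁵; the
  default keeps desk runtime in seconds and the count is a config
  knob). Fraction 1.0 returns exactly zero.

## Quantification (`quantify`)

Aggregates are 8-connected components of a mask at or above 3 µm²
(both choices configurable; 8-connectivity merges diagonal contacts,
matching how closely neighboring inclusions blend optically).
Perimeter comes from marching-squares contours of the padded
component at the 0.5 level; circularity is 4πA/P², clipped at 1.05 to
absorb quantization overshoot on small disks. Construct comparisons
use Welch's unequal-variance t-test (two-sided, unpaired) by default —
the safer reading when only "unpaired t-test" is stated — with
Student's pooled flavor behind a flag, and no multiple-testing
correction (also a flag). Groups under n = 3 are excluded with a
warning.

## Dynamics (`dynamics`)

The per-frame spatial mean of the network output, min-max normalized
over the series, is fit with a logistic
`b + A/(1+exp(−k(t−t₀)))` by least squares (initial values from the
data; a flat or badly-fitting series is flagged degenerate, a
time-reversed one fits with k < 0 and is flagged as decay). The three
regimes — diffuse protein, formation, steady state — are split at the
first frames where the fitted curve crosses `b + 0.05A` and
`b + 0.95A`; for an ideal logistic these crossings sit at
`t₀ ∓ ln(19)/k`. The 5%/95% thresholds are configurable choices.
Per-frame dry mass and area use the fixed 0.5 prediction cut (so
pre-onset frames yield empty masks and (0, 0)) and the co-registered
phase images. Error bars are emitted both as the whole-image spatial
SD and, when an ROI is supplied, the within-ROI SD.

**Negative-control behavior.** With the fixed-scale inputs and mixed
training composition, negative-control fields (cells expressing only
diffuse fluorophore) predict essentially blank: on a ten-scene
negative panel, nine fields contain zero pixels above the 0.5 cut and
the full pipeline (0.5 cut followed by the 3 µm² component floor)
reports zero aggregates on all ten. The residual failure mode is a
rare sub-detection-limit blob (≈1–2 µm², one field in ten) over the
brightest spot of a near-top-of-range cell — the regression decision
boundary between the brightest cytoplasm (0.8 rad) and the dimmest
aggregate (1.2 rad) is soft, and which marginal field shows a blob
varies with the training checkpoint. Multi-model consensus triage
exists precisely to remove such single-model false positives.

## Known limitations

- The TIE retrieval underestimates high-frequency phase content at
  large defocus (sinc-type attenuation); dry masses of very small or
  sharp-edged objects are biased low by up to several percent even in
  the weak-phase regime.
- The forward model is single-wavelength and fully coherent; contrast
  of real white-light brightfield stacks differs quantitatively.
- Training at 96 px with a uniform diffuse fluorophore pool makes the
  virtual-staining task easier than real data, where cytoplasmic
  texture, labeling variability and registration error add label
  noise. Held-out correlations here certify the learning machinery,
  not expected field accuracy.
- The NumPy engine is CPU-only and unsuited to full-scale (352 px,
  thousands of images) training; it exists to make the recipe and
  architecture fully testable and reproducible without a GPU stack.
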