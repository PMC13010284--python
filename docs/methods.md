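# Methods

## Model and procedure

The package treats cross-modality synthesis as paired image-to-image
translation. Per subject, three co-registered MRI volumes and a methionine-PET
SUV volume share one grid. Preprocessing is strictly per-subject (prospective:
no statistic of the rest of the cohort is used):

* **Intensity normalization.** The 256-bin histogram of brain-mask voxel
  intensities is built over equal-width bins spanning the masked min–max; the
  mode bin's center anchors the rescaling `v ↦ clip(v / mode × 75, 0, 255)`,
  applied to the full non-skull-stripped volume. The mode — in practice the
  dominant normal-tissue intensity — becomes a fixed point at 75, which makes
  the map exactly invariant to global multiplicative gain (the histogram
  edges scale with the data). Ties between bins resolve to the
  lowest-intensity bin; a constant masked volume has its constant as mode; a
  non-positive mode is an error.
* **zCE.** One global OLS fit of normalized T1Gd on normalized T1W over
  brain-mask voxels defines the subject's no-enhancement line; each voxel's
  z-score is its residual over the global residual SD (population SD). A
  per-voxel SD is undefined with one observation per voxel, so the single
  global SD is the z-score unit; by construction brain-mask z-scores have
  mean 0 and SD 1. Encoding `clip(z × 51, 0, 255)` saturates at z = 5 and
  clips negative z to 0 — deliberately lossy, since the 8-bit channel carries
  no sign and hypo-enhancement is not the target signal. The fit uses all
  brain voxels (enhancing voxels included); the z map is evaluated on the
  full grid.
* **T/N scaling.** SUV over the mean SUV of the cerebellum mask; mean T/N
  over the reference region is exactly 1 and the transform is invariant to
  injected-dose scale. The ×51 encoding maps the usable ratio range [0, 5]
  onto 8 bits; decoding flags saturated voxels (encoded 255), whose true
  ratio is only known to be ≥ 5.

Slice pairs quantize continuous 0–255 values to integers exactly once
(round-half-up) at pair assembly. Slices are center-cropped/padded to the
GAN's square input size; a slice qualifies if its brain-mask coverage is at
least `min_brain_fraction` (default 0.05 — the slice-inclusion rule is a free
parameter of this implementation). Mirroring augmentation doubles the
training pairs; splits are by subject.

The translator is the pix2pix recipe: U-Net generator (stride-2 4×4
convolutions, instance normalization, leaky-ReLU encoder / ReLU decoder,
skip connections, tanh head scaled to 0–255), PatchGAN discriminator on
concatenated (source, target), BCE-with-logits adversarial loss plus λ·L1
(λ = 100), Adam at lr 2 × 10⁻⁴, β₁ = 0.5, alternating D/G updates. It is
implemented directly in NumPy with manual backpropagation (im2col
convolutions whose gradients are finite-difference-verified in the test
suite); training and inference are fully deterministic under the seed.

## Presets and problem sizes

* `desk_preset`: 64 px, 16 base channels, 3 U-Net levels, 2-layer PatchGAN,
  10 epochs, batch 2. With 200 training pairs this is ~1000 optimizer updates
  and trains in roughly half a minute on one CPU core; the package's own
  end-to-end checks run at this scale.
* `full_preset`: 256 px, 64 base channels, 7 levels, 3-layer PatchGAN,
  200 epochs, batch 1 — the full-scale configuration; impractical without
  acceleration, provided for completeness.

Batch size and normalization layers are not pinned by the published
description of the method; batch 1 with instance norm follows the public
pix2pix implementation, and the desk preset uses batch 2 so that one epoch
is both cheap and a meaningful early measurement point of the validation
curve.

A generated slice is recorded as *failed* when its dynamic range collapses
below `min_dynamic_range` (default 5 on the 8-bit scale) — image-generation
failure is observed in practice but has no standard definition, so a
range-collapse heuristic is used.

## The phantom generator

Phantoms emulate exactly the statistical structure the pipeline assumes:
an ellipsoidal brain, a posterior-inferior ellipsoidal cerebellum (the
normal reference region, disjoint from the tumor), and a concentric-shell
tumor — enhancing core (default radius 8 mm), non-enhancing rim (6 mm), and
edema halo (10 mm) — with per-subject jitter of center and radii. The latent
cell-density field decays linearly from a central peak (default
30 000 cells/mm²) to zero at the outer rim, and PET uptake is affine in
density: `T/N = 1 + 5.8 × 10⁻⁵ · density`, the same line the density
regression is expected to recover, giving a peak T/N near 2.7 — a realistic
methionine uptake for glioblastoma — and non-degenerate Dice/expansion
threshold curves. T1Gd equals T1W plus a fixed enhancement signal inside the
core only. Per-subject multiplicative gains (default range 0.5–2.0 per MRI
sequence, 0.8–1.25 for PET) emulate inter-institution scale and
injected-dose variability; noise is additive Gaussian clipped at zero.
Default grid 96 × 96 × 64 at 2 mm voxels (slice thickness and in-plane
resolution are free choices); the test suite mostly uses a reduced
64 × 64 × 40 grid at 2.5 mm.

What the phantom does **not** model: scanner physics, bias fields, partial
volume, motion, registration error, anatomical texture, multi-focal tumors.
Passing tests therefore demonstrate correctness of the computational
pipeline and learnability of a clean affine source→target relationship —
not clinical-grade synthesis on real heterogeneous cohorts, whose published
headline metrics depend on an undeposited patient dataset and are out of
scope here.

## Evaluation choices

* Residual error is reported as mean, SD of |Δ T/N| plus the signed mean
  (exposing systematic over/underestimation), over the brain mask by default
  — background voxels would meaninglessly inflate agreement.
* PSNR is `10·log10(255²/MSE)`. "Regular SNR" has no universal definition;
  here it is the reference-energy ratio `10·log10(Σ truth²/Σ (truth−pred)²)`.
  SSIM uses the standard constants (K1 = 0.01, K2 = 0.03, dynamic range 255,
  11-tap Gaussian window σ = 1.5) averaged over axial slices, via
  scikit-image. Identical volumes report PSNR/SNR as +∞.
* Dice conventions: both lesions empty → 1; exactly one empty → 0.
* Volume expansion is `|enhancing ∪ lesion(t)| / |enhancing|` (how much the
  thresholded lesion extends the gadolinium-enhancing target); a pure-ratio
  variant is available via `union=False`. In phantoms the enhancing lesion is
  the generator's mask; for real data a zCE threshold would be substituted.
* The VOI is the cube of voxels whose centers fall within the 1-cm box
  around the sampling coordinate; VOIs touching the grid boundary are
  errors.
* The density regression is ordinary least squares with the slope's
  two-sided t-test p-value.

Curves are reported per subject; cohort summaries average per-subject
values (matching how test-set metrics are conventionally reported as
mean ± SD over subjects).

## Numerical notes

* Normalization divides before rescaling so a voxel exactly at the mode maps
  to exactly 75.0 in floating point.
* A fitted residual SD below 1e-8 (rounding-noise level on the 0–255 scale)
  is treated as a perfect fit and rejected, since z-scores are then
  undefined.
* Network math is float32; losses are checked finite every iteration and
  training aborts on divergence.
* All randomness (phantom sampling, splits, weight init, shuffling) flows
  from explicit integer seeds; identical seed + configuration reproduces
  volumes, splits, losses and generated images bit-for-bit on fixed
  hardware.

## Known limitations

* The hand-rolled NumPy GAN is CPU-bound and desk-scale; it makes no attempt
  to match full-scale training throughput or the image quality of the
  original large-cohort model.
* zCE clipping discards hypo-enhancement; saturation discards T/N > 5.
* The slice-inclusion rule and square resizing are implementation choices;
  different choices change pair counts.
* Cerebellar reference voxels are taken as given by the mask; no exclusion
  of pathological overlap is attempted.
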