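# gliomap

Glioblastoma infiltrates well beyond its gadolinium-enhancing rim, and the
non-contrast-enhancing tumor (nCET) is hard to distinguish from vasogenic
edema on routine MRI. Methionine PET (MET-PET) maps tumor cell density and
delineates nCET reliably, but is expensive and scarce. `gliomap` implements a
pipeline that *translates* routine MRI into a MET-PET-like volume — a
"Gliomap" — whose voxel values decode to tumor-to-normal (T/N) uptake ratios
and act as a tumor-cell-density surrogate. It is aimed at researchers in
cross-modality medical image synthesis who want a fully testable, end-to-end
reference implementation: because clinical cohorts of this kind are not
publicly deposited, the package ships a synthetic-phantom generator with
known cell-density ground truth, and every stage is exercised against it.

## The pipeline

1. **Mode-anchored MRI normalization.** Each sequence (T1W, T2W, T1Gd) is
   rescaled per subject so the mode of its 256-bin brain-masked intensity
   histogram maps to 75 on a 0–255 scale,

   `SI_norm = SI_orig × 75 / mode(SI_256bins)`, ceilinged at 255,

   removing arbitrary per-scanner intensity gain without observing any other
   subject.
2. **z-score contrast enhancement (zCE).** Per subject, OLS of normalized
   T1Gd on normalized T1W over brain voxels; each voxel's residual divided by
   the global residual SD is its enhancement z-score, encoded as
   `clip(z × 51, 0, 255)`. This surfaces even subtle enhancement invisible on
   raw T1Gd.
3. **T/N PET scaling.** PET SUV is divided by the mean SUV of the cerebellum
   and encoded as `clip(T/N × 51, 0, 255)` (inverse: pixel / 51).
4. **Pair assembly.** Axial slices are packed into 8-bit RGB sources
   (R = T1W, G = T2W, B = zCE) with the encoded T/N slice as target;
   horizontal mirroring doubles the training set; splits are by subject.
5. **Conditional GAN.** A pix2pix-style translator — U-Net generator,
   PatchGAN discriminator, adversarial BCE + λ·L1 (λ = 100) objective, Adam
   (lr 2 × 10⁻⁴, β₁ = 0.5) — implemented in NumPy with manual
   backpropagation. A `desk_preset` (64 px, 16 base channels, 10 epochs)
   trains in minutes on one CPU; a `full_preset` mirrors the full-scale
   configuration.
6. **Evaluation.** Residual error in T/N units, peak/regular SNR, SSIM,
   Sørensen-Dice vs T/N threshold, volume-expansion ratios over the
   enhancing lesion, cubic VOI statistics at sampling coordinates, and the
   OLS regression of VOI-mean Gliomap value on tumor cell density.

Stages are sklearn-style estimators (`ModeIntensityNormalizer`,
`ContrastEnhancementZScorer`, `TumorToNormalScaler`, `Pix2PixTranslator`)
with plain-function wrappers, plus a `gliomap` CLI (`phantom`, `normalize`,
`zce`, `pet`, `run`, `evaluate` subcommands).

## Worked example

```python
from gliomap import PipelineConfig, run_pipeline

summary = run_pipeline(PipelineConfig(out_dir="run", seed=1, noise_scale=0.2))
print(round(summary["val_residual_tn"][0], 3),
      "->", round(summary["val_residual_tn"][-1], 3))
print("mean Dice @ T/N 1.5:", round(summary["mean_dice_at_1.5"], 3))
print("mean residual (T/N):", round(summary["mean_residual_tn"], 3))
```

prints (about 40 s on one CPU core):

```
0.118 -> 0.032
mean Dice @ T/N 1.5: 0.807
mean residual (T/N): 0.117
```

That is: a 7-subject low-noise phantom cohort is generated, 5 subjects train
the desk-scale GAN on 200 augmented slice pairs, and on the 2 held-out
subjects the held-out generation error falls from 0.118 to 0.032 T/N over
10 epochs while the lesions the Gliomap predicts at a T/N threshold of 1.5
overlap the ground-truth PET lesions with a mean Dice of 0.81. Per-subject
reports (`run/report_*.json`) carry the full metric battery and
threshold curves.

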