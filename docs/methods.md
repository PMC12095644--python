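# Methods

## The model

`flowseg` segments microscopy images by letting each image train its own
pixel classifier. The chain is:

1. **Surrogate motion.** The image `I` is Gaussian-blurred into `I_σ`.
   Blurring redistributes intensity locally while conserving it globally —
   the same constraint dense optical flow assumes about real motion — so
   the pair `(I, I_σ)` behaves like two frames of a movie in which textured
   regions "move" and flat regions do not.
2. **Dense flow.** A pyramidal Farneback estimator computes a per-pixel
   displacement field between `I` and `I_σ`. Each frame is approximated
   neighborhood-by-neighborhood as a quadratic form
   `f(x) ≈ xᵀA x + bᵀx + c` (Gaussian-weighted least squares via separable
   correlations); displacement solves `A d = Δb`, iterated coarse-to-fine.
3. **Self-labeling.** Pixels whose flow-magnitude (box-aggregated, see
   below) exceeds an upper percentile threshold are provisionally *cell*;
   pixels below a lower percentile are *background*; the band between
   stays unlabeled. The two percentiles are chosen from a small grid by
   maximizing the difference in mean local Shannon entropy between the two
   provisional classes — cells are more textured than background, so a
   good labeling maximizes that contrast. No ground truth is consulted.
4. **Per-image classifier.** At the labeled pixels, three untransformed
   features are read: local entropy *e* (bits, disk window), Sobel
   gradient magnitude *g* (intensity units/pixel), and intensity *i*
   ([0, 1]). A Gaussian naive Bayes model is fit per image with a
   stratified 10-fold cross-validation record, then applied to every
   pixel. Ties in the posterior go to background.
5. **Cleanup.** Small components are removed and interior holes filled;
   optionally, touching objects are split by a watershed on the negated
   Euclidean distance transform seeded at distance maxima.

The method needs no curated training data and no per-image parameter
tuning; a batch shares one frozen configuration while every image still
self-tunes its own thresholds and fits its own classifier.

## Numerical choices that matter

**Pixel-integrated blur kernel.** Kernel weights are per-pixel integrals
of the continuous Gaussian (differences of error functions), truncated at
4σ, applied separably with reflective boundaries. Two consequences: summed
intensity is conserved to machine precision (reflective extension plus a
symmetric normalized kernel is exactly mass-preserving), and sub-pixel σ
remains meaningful — at the default σ = 0.1 px the off-center weight is
~2.9·10⁻⁷, a tiny but representable redistribution, whereas a sampled
(density-evaluated) kernel is bit-identical to the identity there. Flow
magnitudes at σ = 0.1 are accordingly tiny (~10⁻⁸ px), which is harmless:
thresholds are percentiles of the magnitude distribution and therefore
scale-free. The fixture suite exercises σ ∈ {0.1, 0.5, 1.0, 2.0}.

**Damped per-pixel flow solve.** Classical dense-flow practice averages
the normal equations `(AᵀA, AᵀΔb)` over a window before solving. For
blur-as-motion this is counterproductive: blurring displaces individual
texture grains in incoherent directions, so vector averaging cancels the
very signal being measured, while in flat noisy background the
near-singular systems produce unbounded spurious displacements (the
least-squares solution is contrast-invariant). Defaults therefore solve
per pixel (`window_size = 1`; the polynomial-expansion window already
aggregates a neighborhood) with a Tikhonov term
`λ = damping × mean structure energy` (default `damping = 0.3`) that
pulls weak-structure pixels toward zero displacement, and the *modulus*
of the field is box-aggregated over `magnitude_window = 15` px before
thresholding. Window averaging remains available (`window_size > 1`) and
recovers genuine coherent translations to ~1% in tests. With the damped
per-pixel setting, cell-pixel precision of the top magnitude percentiles
on fixtures is 0.88–0.99 across the σ range; with the classical windowed
setting it drops to ≤ 0.4.

**Entropy.** Intensities are quantized to 64 bins on [0, 1]; entropy is
the Shannon entropy (bits) of the histogram in a disk of radius 4 px.
The same field serves both the self-tuning objective and feature *e*.

**Self-tuning objective and ties.** Objective = mean entropy of
provisional cells minus mean entropy of provisional background (median
available via `tuning_statistic`). Candidates leaving either class empty
are skipped; if all do, the stage fails loudly (degenerate image). Equal
objectives break toward the smallest upper percentile, then the largest
lower percentile — the most inclusive labeling.

**Classifier.** Fitting and cross-validation use scikit-learn
(`GaussianNB`, `StratifiedKFold`, shuffled with the config seed); the
deployed model is refit on all retained rows after the CV record is
taken. Training rows are capped at 50 000 per class (seeded, class
balanced) so memory is bounded on megapixel images; priors consequently
default to ~0.5/0.5, with pre-subsample empirical priors available as a
config switch. Variances are floored at 10⁻⁹ (8-bit quantization can
produce zero within-class variance). Prediction computes log-space
posteriors from the stored (π, μ, σ²) directly, so serialized models are
self-contained and ties resolve to background deterministically.

**Degenerate inputs.** Constant images are rejected at normalization
(nothing to segment). A constant flow-magnitude field fails self-tuning.
A class with fewer rows than folds fails training. Each failure carries
its stage name; batch runs isolate failures per image.

**Connectivity and declumping.** Objects are 8-connected, background
4-connected. Watershed seeds are distance-transform maxima separated by
≥ `min_distance` (10 px default) within a disk footprint (radius 7 px),
scaled to the yeast/nucleus fixtures; declumping partitions the
foreground exactly (no growth or shrinkage) and is off by default, as
appropriate for adherent cells. Label ids are canonicalized by raster
order of first pixel, making labelings reproducible bit for bit.

**Evaluation.** Pixel-pooled F1 = TP / (TP + (FN + FP)/2) per image with
cell as the positive class; both-empty pairs score 1.0 and are flagged
degenerate. Batch reports add a mean ± sd summary row.

## What the synthetic generator emulates — and what it does not

Fixtures are constant background plus i.i.d. Gaussian sensor noise
(sd 0.02 after normalization), with smooth random shapes (perturbed
ellipses, lobed yeast, nucleus disks; radii ~22–60 px as at 40–63×
magnification on 512 px frames) painted at modest intensity contrast
(0.15, or 0.005 in the texture-only variant) and filled with correlated
Gaussian speckle (sd 0.20, correlation length 2.5 px) standing in for
organelle/cytoskeleton texture. Ground truth derives from the same
geometry that painted the image, so masks are exact. The standard suite
is 20 images spanning ~5–40% confluency, plus texture-only, declumping,
and nucleus variants; every fixture is reproducible from (suite seed,
index).

Not emulated: point-spread blurring, uneven illumination, vignetting,
modality physics (DIC relief, IRM fringes, phase halos), debris, or
annotation noise. Passing fixtures therefore demonstrates that the
mechanics of the method work when its core premise (texture contrast
between cells and background) holds; it does not certify accuracy on any
particular real modality. Measured on this suite: mean pixel F1 ≈ 0.95
(sd ≈ 0.006) at the default configuration, and ≈ 0.95 in the texture-only
regime where cells are invisible to mean-intensity thresholding.

## Problem sizes used by the test suite and acceptance script

Fixtures are 512×512; the acceptance script fits the pipeline on the
20-image suite (~1 s/image on one CPU core), evaluates the texture-only
variants, and verifies the conservation, identity, declumping, and
determinism properties on subsets of 3–5 images — sizes chosen so the
whole recomputation stays within a few minutes while every quantity is
still measured, never assumed.

## Known limitations

- σ is stated without units upstream; it is interpreted as pixels here,
  with the pixel-integrated kernel making sub-pixel values meaningful.
  The config exposes it.
- The exact self-tuning search and flow post-processing of the original
  method are not public; the percentile grid, the class-mean entropy
  objective, the damped per-pixel solve, and magnitude aggregation are
  this package's reconstruction, chosen for robustness across blur
  widths and documented above.
- Very low confluency (< ~5% cell area) caps the precision of the upper
  percentile labels (the 95th percentile then necessarily includes
  background); the classifier tolerates this on fixtures, but images that
  are almost entirely background are the hardest case.
- Declumping targets round, non-adherent objects; irregular adherent
  cells are out of scope.
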