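# flowseg

Self-supervised cell segmentation for microscopy images — every image
trains its own pixel classifier, with no curated training data and no
per-image parameter tuning.

High-throughput imaging produces more images, modalities, and phenotypes
than pretrained deep-learning segmenters generalize to, and curating
annotation sets for every new condition does not scale. `flowseg` takes a
different route: the image supplies its own training labels. A Gaussian
blur of the image acts as a surrogate "second frame"; dense Farneback
optical flow between the original and the blur shows apparent motion
where there is texture (cells: organelles, cytoskeleton) and none where
the image is flat (background). Thresholding the flow magnitude —
self-tuned by maximizing the local-entropy contrast between the
provisional classes — yields confident cell/background labels, which
train a per-image Gaussian naive Bayes classifier over three transparent
features: local entropy *e*, gradient magnitude *g*, and intensity *i*.
The classifier then labels every pixel of the same image.

The core quantities, in the field's standard notation:

- flow field `d(x)` between `I` and `I_σ` from quadratic polynomial
  expansion `f(x) ≈ xᵀA x + bᵀx + c`, solved coarse-to-fine;
- self-tuning objective `ΔH = mean H|cell − mean H|background` over a
  percentile-pair grid, `H` the windowed Shannon entropy;
- per-pixel posterior `P(c | e, g, i) ∝ π_c · N(e; μ, σ²) · N(g; μ, σ²)
  · N(i; μ, σ²)`, computed in log space;
- evaluation `F1 = TP / (TP + ½(FN + FP))`, pixel-pooled, cells positive.

It works on grayscale or per-channel fluorescence TIFF/PNG/JPEG (8- or
16-bit), at any magnification, and is intended for confluency
quantification, phenotype screening, and fine-structure segmentation;
an optional watershed step declumps round, non-adherent objects.

## Worked example

```python
from flowseg import SelfSupervisedSegmenter, FixtureSpec, generate_fixture
from flowseg.evaluate import confusion_counts, f1_score

fx = generate_fixture(FixtureSpec(seed=1))     # synthetic image + ground truth
result = SelfSupervisedSegmenter(fx.image).fit()
print(result.summary())
print("pixel F1 vs truth:", round(f1_score(confusion_counts(result.mask, fx.truth_mask)), 4))
```

prints (abridged):

```
Self-supervised segmentation results
====================================================
image:                synthetic:seed=1
size:                 512 x 512
blur sigma:           0.1
selected thresholds:  upper p95 (t_cell=2.905e-07), lower p20 (t_bg=1.196e-07)
tuning objective:     1.9567 bits (mean entropy difference)
self-labels:          13108 cell, 52429 background
training rows:        13108 cell, 50000 background
CV accuracy:          0.9967 +/- 0.0006 (10 folds)

class      prior      mu_e      mu_g      mu_i     var_e     var_g     var_i
------------------------------------------------------------------------------
background 0.7923    2.2722    0.0100    0.3500  2.08e-02  2.77e-05  3.70e-04
cell       0.2077    4.2290    0.0785    0.5080  2.09e-01  2.35e-03  3.98e-02
------------------------------------------------------------------------------
cell fraction (confluency): 0.1263

pixel F1 vs truth: 0.9533
```

The thresholds are tiny in absolute terms — at the default blur width the
apparent displacements are of order 10⁻⁷ px — but only their percentile
rank matters, and the selected labeling separates the classes by ~2 bits
of local entropy.

The summary is the per-image model itself: the selected flow thresholds,
the class priors, and the Gaussian parameters of each feature per class —
every segmentation decision can be traced back to these numbers.

From the shell:

```bash
flowseg synth --suite --seed 0 --out fixtures/          # fixture images + truths
flowseg segment fixtures/sparse_*.tif --out out/        # batch, one frozen config
flowseg evaluate --pred out/ --truth fixtures/ --out eval.csv
```

`segment` writes, per image, a binary mask TIFF, a boundary-overlay PNG,
the serialized classifier, and the self-tuning report, plus a batch CSV
(thresholds, CV accuracy, timings, failures isolated per image).

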