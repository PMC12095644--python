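"""Model/Results interface over the self-supervised segmentation pipeline.

:class:`SelfSupervisedSegmenter` is constructed from one image (plus a
config) and :meth:`~SelfSupervisedSegmenter.fit` runs the whole chain —
blur, dense flow, entropy-guided self-labeling, feature extraction,
Gaussian NB training with k-fold validation, whole-image prediction, mask
cleanup and optional declumping — returning a :class:`SegmentationResult`
that carries the estimates (per-image classifier parameters), their
validation record, the self-tuning diagnostics, and the masks, with a
``summary()`` table and output writers.

>>> from flowseg import SelfSupervisedSegmenter, generate_fixture, FixtureSpec
>>> fx = generate_fixture(FixtureSpec(seed=1))
>>> res = SelfSupervisedSegmenter(fx.image).fit()
>>> 0.0 < res.mask.cell_fraction < 1.0
True
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import blur_flow, classify, features, postprocess, self_label
from .config import PipelineConfig
from .io import IntensityImage, OutputPaths, read_image, write_outputs

__all__ = ["SelfSupervisedSegmenter", "SegmentationResult"]


@dataclass(frozen=True)
class SegmentationResult:
    """Everything the per-image fit produced.

    Attributes
    ----------
    mask : SegmentationMask
        Final cleaned binary mask.
    raw_mask : SegmentationMask
        Classifier output before cleanup.
    labeled : LabeledMask or None
        Declumped objects, when declumping was enabled.
    classifier : PixelClassifierModel
        The per-image model: priors, per-class Gaussian parameters over
        (e, g, i), and the k-fold validation accuracies.
    tuning : TuningReport
        Every threshold candidate with its entropy-difference objective.
    label_set : PixelLabelSet
        The sparse self-generated training labels.
    entropy_field, gradient_field, flow_magnitude : ndarray
        The per-pixel feature/flow fields (flow magnitude is the
        aggregated field the thresholds refer to).
    """

    image: IntensityImage
    config: PipelineConfig
    mask: classify.SegmentationMask
    raw_mask: classify.SegmentationMask
    labeled: postprocess.LabeledMask | None
    classifier: classify.PixelClassifierModel
    tuning: self_label.TuningReport
    label_set: self_label.PixelLabelSet
    entropy_field: np.ndarray
    gradient_field: np.ndarray
    flow_magnitude: np.ndarray

    @property
    def cell_fraction(self) -> float:
        """Confluency estimate from the final mask."""
        return self.mask.cell_fraction

    @property
    def n_objects(self) -> int | None:
        return self.labeled.n_objects if self.labeled is not None else None

    def summary(self) -> str:
        """Plain-text summary of the fitted per-image model."""
        m = self.classifier
        sel = self.tuning.selected
        lines = [
            "Self-supervised segmentation results",
            "=" * 52,
            f"image:                {self.image.source_path or 'in-memory'}",
            f"size:                 {self.image.height} x {self.image.width}",
            f"blur sigma:           {self.config.blur_sigma}",
            f"selected thresholds:  upper p{sel.upper_percentile:g} "
            f"(t_cell={sel.t_cell:.4g}), lower p{sel.lower_percentile:g} "
            f"(t_bg={sel.t_bg:.4g})",
            f"tuning objective:     {sel.objective:.4f} bits "
            f"({self.tuning.statistic} entropy difference)",
            f"self-labels:          {self.label_set.n_cell} cell, "
            f"{self.label_set.n_background} background",
            f"training rows:        {m.n_train[1]} cell, {m.n_train[0]} background",
            f"CV accuracy:          {m.cv_mean:.4f} +/- {m.cv_sd:.4f} "
            f"({len(m.cv_accuracies)} folds)",
            "",
            "class      prior      mu_e      mu_g      mu_i     var_e     var_g     var_i",
            "-" * 78,
        ]
        for ci, name in enumerate(("background", "cell")):
            mu, var = m.means[ci], m.variances[ci]
            lines.append(
                f"{name:<10} {m.priors[ci]:.4f} "
                f"{mu[0]:9.4f} {mu[1]:9.4f} {mu[2]:9.4f} "
                f"{var[0]:9.2e} {var[1]:9.2e} {var[2]:9.2e}"
            )
        lines += [
            "-" * 78,
            f"cell fraction (confluency): {self.cell_fraction:.4f}",
        ]
        if self.labeled is not None:
            lines.append(f"objects after declumping:   {self.labeled.n_objects}")
        return "\n".join(lines) + "\n"

    def save(self, out_dir, name: str | None = None) -> OutputPaths:
        """Write mask TIFF, overlay PNG, model text, and tuning report."""
        return write_outputs(
            self.mask.mask,
            self.image,
            out_dir,
            model_text=self.classifier.to_text() + "\n" + self.summary(),
            tuning_text=self.tuning.to_text(),
            name=name,
        )

    def plot_overlay(self, ax=None):
        """Matplotlib rendering of the image with mask boundaries."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.imshow(self.image.pixels, cmap="gray", vmin=0, vmax=1)
        target = self.labeled if self.labeled is not None else self.mask
        for contour in postprocess.extract_boundaries(target):
            ax.plot(contour[:, 1], contour[:, 0], color="yellow", linewidth=1)
        ax.set_axis_off()
        return ax


class SelfSupervisedSegmenter:
    """Per-image segmentation model.

    Parameters
    ----------
    image : IntensityImage
        The normalized image to segment (and to train on — the method is
        self-supervised, so the training data and the target coincide).
    config : PipelineConfig, optional
        Pipeline parameters; defaults reproduce the standard automated
        setting (no per-image tuning).
    """

    def __init__(self, image: IntensityImage, config: PipelineConfig | None = None):
        self.image = image
        self.config = config or PipelineConfig()

    @classmethod
    def from_file(
        cls,
        path,
        channel: int | None = None,
        config: PipelineConfig | None = None,
    ) -> "SelfSupervisedSegmenter":
        """Build a segmenter from a TIFF/PNG/JPEG file."""
        return cls(read_image(path, channel=channel), config)

    def fit(self) -> SegmentationResult:
        """Run the full self-supervised pipeline on this image."""
        cfg = self.config
        img = self.image

        blurred = blur_flow.gaussian_blur(img, cfg.blur_sigma)
        flow = blur_flow.farneback_flow(img, blurred, cfg.flow)

        entropy_field = self_label.local_entropy(
            img, cfg.entropy_window_radius, cfg.entropy_bins
        )
        labels, tuning, agg_magnitude = self_label.self_label(
            img, flow.magnitude, entropy_field, cfg
        )

        gradient_field = features.gradient_magnitude(img)
        table = features.extract_features(img, labels, entropy_field, gradient_field)

        model = classify.train_classifier(
            table,
            folds=cfg.cv_folds,
            seed=cfg.rng_seed,
            max_per_class=cfg.max_training_pixels_per_class,
            use_empirical_priors=cfg.use_empirical_priors,
        )
        raw_mask = classify.predict_mask(model, entropy_field, gradient_field, img)
        mask = postprocess.clean_mask(raw_mask, cfg.min_object_area, cfg.fill_holes)

        labeled = None
        if cfg.declump.enabled:
            labeled = postprocess.declump(
                mask, cfg.declump.min_distance, cfg.declump.footprint_radius
            )

        return SegmentationResult(
            image=img,
            config=cfg,
            mask=mask,
            raw_mask=raw_mask,
            labeled=labeled,
            classifier=model,
            tuning=tuning,
            label_set=labels,
            entropy_field=entropy_field,
            gradient_field=gradient_field,
            flow_magnitude=agg_magnitude,
        )
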