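"""Per-image Gaussian Naive Bayes pixel classifier.

Each image gets its own model: the self-labeled feature table is
subsampled to a class-balanced training set, scored by stratified k-fold
cross-validation (the validation record travels with the model), refit on
all retained rows, and then applied to every pixel of the same image.

The deployed parameters are the plain Gaussian NB sufficient statistics —
class priors and per-class, per-feature means and variances — serialized
as text so the per-image model is an inspectable artifact. Prediction is a
log-space posterior computation (three Gaussian factors underflow linear
space at extreme feature values); ties go to background.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB

from .exceptions import ContractError, TrainingError
from .features import FEATURE_NAMES, FeatureTable
from .io import IntensityImage
from .self_label import BACKGROUND, CELL

__all__ = ["PixelClassifierModel", "SegmentationMask", "train_classifier", "predict_mask"]

VARIANCE_FLOOR = 1e-9  # quantized 8-bit input can give zero within-class variance


@dataclass(frozen=True)
class SegmentationMask:
    """Binary segmentation on the image grid (True = cell)."""

    mask: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def cell_fraction(self) -> float:
        """Confluency: fraction of the field covered by cells."""
        return float(self.mask.mean())


@dataclass(frozen=True)
class PixelClassifierModel:
    """Gaussian NB parameters over (e, g, i) plus the training record.

    ``class_order`` is (BACKGROUND, CELL); ``means`` and ``variances`` are
    (2, 3) arrays in that class order and (e, g, i) feature order.
    """

    priors: np.ndarray  # (2,), sums to 1
    means: np.ndarray  # (2, 3)
    variances: np.ndarray  # (2, 3), floored
    n_train: tuple[int, int]  # rows used per class after subsampling
    cv_accuracies: tuple[float, ...]
    seed: int

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0):
            raise ContractError("class priors must sum to 1")
        if (self.variances <= 0).any():
            raise ContractError("variances must be positive")

    @property
    def cv_mean(self) -> float:
        return float(np.mean(self.cv_accuracies))

    @property
    def cv_sd(self) -> float:
        return float(np.std(self.cv_accuracies, ddof=1))

    def log_posteriors(self, features: np.ndarray) -> np.ndarray:
        """Normalized log P(class | x) for feature rows (n, 3).

        Returns (n, 2) in class order (BACKGROUND, CELL); each row
        logsumexp-normalizes to 0 so posteriors sum to one.
        """
        x = np.asarray(features, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != 3:
            raise ContractError("features must be (n, 3)")
        # log prior + sum of log Gaussians, vectorized over both classes
        diff = x[:, None, :] - self.means[None, :, :]
        log_lik = -0.5 * (
            np.log(2.0 * np.pi * self.variances)[None, :, :]
            + diff**2 / self.variances[None, :, :]
        ).sum(axis=2)
        with np.errstate(divide="ignore"):  # a zero prior is a valid degenerate model
            log_prior = np.log(self.priors)
        joint = log_prior[None, :] + log_lik
        # normalize: log p - logsumexp(log p)
        mx = joint.max(axis=1, keepdims=True)
        norm = mx + np.log(np.exp(joint - mx).sum(axis=1, keepdims=True))
        return joint - norm

    def to_text(self) -> str:
        buf = _io.StringIO()
        buf.write("# per-image Gaussian naive Bayes pixel classifier\n")
        buf.write(f"seed = {self.seed}\n")
        buf.write(f"n_train_background = {self.n_train[0]}\n")
        buf.write(f"n_train_cell = {self.n_train[1]}\n")
        buf.write(f"prior_background = {float(self.priors[0])!r}\n")
        buf.write(f"prior_cell = {float(self.priors[1])!r}\n")
        for ci, cname in enumerate(("background", "cell")):
            for fi, fname in enumerate(FEATURE_NAMES):
                buf.write(f"mu_{cname}_{fname} = {float(self.means[ci, fi])!r}\n")
                buf.write(f"var_{cname}_{fname} = {float(self.variances[ci, fi])!r}\n")
        buf.write(
            "cv_accuracies = " + ",".join(repr(float(a)) for a in self.cv_accuracies) + "\n"
        )
        buf.write(f"cv_mean = {self.cv_mean!r}\ncv_sd = {self.cv_sd!r}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "PixelClassifierModel":
        kv: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        means = np.empty((2, 3))
        variances = np.empty((2, 3))
        for ci, cname in enumerate(("background", "cell")):
            for fi, fname in enumerate(FEATURE_NAMES):
                means[ci, fi] = float(kv[f"mu_{cname}_{fname}"])
                variances[ci, fi] = float(kv[f"var_{cname}_{fname}"])
        return cls(
            priors=np.array([float(kv["prior_background"]), float(kv["prior_cell"])]),
            means=means,
            variances=variances,
            n_train=(int(kv["n_train_background"]), int(kv["n_train_cell"])),
            cv_accuracies=tuple(float(a) for a in kv["cv_accuracies"].split(",")),
            seed=int(kv["seed"]),
        )


def _subsample_balanced(
    table: FeatureTable, max_per_class: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Cap each class at max_per_class rows (seeded, order-stable)."""
    keep = np.zeros(len(table), dtype=bool)
    for cls in (BACKGROUND, CELL):
        idx = np.nonzero(table.labels == cls)[0]
        if len(idx) > max_per_class:
            idx = rng.choice(idx, size=max_per_class, replace=False)
        keep[idx] = True
    sel = np.nonzero(keep)[0]
    return table.values[sel], table.labels[sel]


def train_classifier(
    table: FeatureTable,
    folds: int = 10,
    seed: int = 0,
    max_per_class: int = 50_000,
    use_empirical_priors: bool = False,
) -> PixelClassifierModel:
    """Fit the per-image model with a stratified k-fold validation record.

    Cross-validation measures model quality on the (subsampled) training
    table; the deployed model is then refit on all retained rows. Priors
    default to the post-subsampling (class-balanced) frequencies;
    ``use_empirical_priors`` substitutes the pre-subsample label
    frequencies instead.

    Raises
    ------
    TrainingError
        If either class has fewer rows than ``folds`` — degenerate
        self-labeling upstream.
    """
    if table.n_cell < folds or table.n_background < folds:
        raise TrainingError(
            f"need >= {folds} rows per class, got cell={table.n_cell}, "
            f"background={table.n_background}"
        )
    rng = np.random.default_rng(seed)
    X, y = _subsample_balanced(table, max_per_class, rng)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accuracies = []
    for train_idx, test_idx in skf.split(X, y):
        nb = GaussianNB()
        nb.fit(X[train_idx], y[train_idx])
        accuracies.append(float(accuracy_score(y[test_idx], nb.predict(X[test_idx]))))

    final = GaussianNB()
    final.fit(X, y)
    order = np.argsort(final.classes_)  # ensure (BACKGROUND, CELL) row order
    means = final.theta_[order]
    variances = np.maximum(final.var_[order], VARIANCE_FLOOR)
    if use_empirical_priors:
        n_bg, n_cell = table.n_background, table.n_cell
        priors = np.array([n_bg, n_cell], dtype=np.float64) / (n_bg + n_cell)
    else:
        priors = final.class_prior_[order]
    counts = [(y == cls).sum() for cls in (BACKGROUND, CELL)]
    return PixelClassifierModel(
        priors=priors,
        means=means,
        variances=variances,
        n_train=(int(counts[0]), int(counts[1])),
        cv_accuracies=tuple(accuracies),
        seed=int(seed),
    )


def predict_mask(
    model: PixelClassifierModel,
    entropy_field: np.ndarray,
    gradient_field: np.ndarray,
    image: IntensityImage,
) -> SegmentationMask:
    """Classify every pixel of the image; ties go to background."""
    for name, fld in (("entropy", entropy_field), ("gradient", gradient_field)):
        if np.asarray(fld).shape != image.shape:
            raise ContractError(f"{name} field shape does not match image")
    features = np.column_stack(
        [
            np.asarray(entropy_field, dtype=np.float64).ravel(),
            np.asarray(gradient_field, dtype=np.float64).ravel(),
            image.pixels.ravel(),
        ]
    )
    logpost = model.log_posteriors(features)
    cell = logpost[:, 1] > logpost[:, 0]  # strict: ties -> background
    return SegmentationMask(
        mask=cell.reshape(image.shape),
        provenance=f"image={image.source_path or 'in-memory'} seed={model.seed}",
    )
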