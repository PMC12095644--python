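"""The unsupervised stage: entropy-guided self-tuning of flow thresholds.

Cells are more textured than background (organelles, cytoskeleton), so the
mean local entropy of a candidate "cell" labeling minus that of the
candidate "background" labeling is a label-free quality score. The stage
evaluates a grid of (upper, lower) percentile pairs of the flow-magnitude
distribution, labels magnitude >= upper threshold as CELL and <= lower
threshold as BACKGROUND, and keeps the pair maximizing the entropy
difference. Pixels between the thresholds stay UNLABELED — the supervised
classifier exists precisely to decide them.

Thresholds are percentiles, not raw magnitudes, because absolute flow
scales vary by orders of magnitude with blur width and modality while the
rank structure (cells high, background low) does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters.rank import entropy as _rank_entropy
from skimage.morphology import disk

from .config import PipelineConfig
from .exceptions import ContractError, LabelingError, SelfTuningError
from .io import IntensityImage

__all__ = [
    "CELL",
    "BACKGROUND",
    "UNLABELED",
    "PixelLabelSet",
    "TuningReport",
    "local_entropy",
    "aggregate_magnitude",
    "tune_thresholds",
    "label_pixels",
]

# label codes on the image grid
BACKGROUND = 0
CELL = 1
UNLABELED = 2


@dataclass(frozen=True)
class PixelLabelSet:
    """Sparse self-generated pixel labels on the image grid."""

    labels: np.ndarray  # uint8 grid of {BACKGROUND, CELL, UNLABELED}
    thresholds_used: tuple[float, float]  # (t_cell, t_bg), magnitude units

    @property
    def n_cell(self) -> int:
        return int((self.labels == CELL).sum())

    @property
    def n_background(self) -> int:
        return int((self.labels == BACKGROUND).sum())

    @property
    def cell_mask(self) -> np.ndarray:
        return self.labels == CELL

    @property
    def background_mask(self) -> np.ndarray:
        return self.labels == BACKGROUND


@dataclass(frozen=True)
class TuningCandidate:
    upper_percentile: float
    lower_percentile: float
    t_cell: float
    t_bg: float
    n_cell: int
    n_background: int
    objective: float  # class entropy difference (cell - background); nan if a class is empty


@dataclass(frozen=True)
class TuningReport:
    """Every candidate evaluated by the self-tuner, plus the selection."""

    candidates: tuple[TuningCandidate, ...]
    selected: TuningCandidate
    statistic: str = "mean"

    def to_text(self) -> str:
        lines = [
            f"# self-tuning report (objective: {self.statistic} entropy difference, bits)",
            "upper_pct lower_pct t_cell t_bg n_cell n_background objective selected",
        ]
        for c in self.candidates:
            mark = "*" if c == self.selected else ""
            lines.append(
                f"{c.upper_percentile:g} {c.lower_percentile:g} {c.t_cell:.6g} "
                f"{c.t_bg:.6g} {c.n_cell} {c.n_background} {c.objective:.6g} {mark}"
            )
        return "\n".join(lines) + "\n"


def local_entropy(image: IntensityImage, window_radius: int, bins: int = 64) -> np.ndarray:
    """Per-pixel Shannon entropy (bits) of the local intensity histogram.

    The [0, 1] intensities are quantized to ``bins`` levels and the entropy
    of the histogram within a disk of ``window_radius`` pixels is computed
    at every pixel. Constant neighborhoods give 0 bits; a balanced
    two-valued neighborhood gives 1 bit.
    """
    if window_radius < 1:
        raise ContractError("window_radius must be >= 1")
    if not 2 <= bins <= 256:
        raise ContractError("bins must be in [2, 256]")
    quantized = np.minimum((image.pixels * bins).astype(np.uint8), bins - 1)
    return _rank_entropy(quantized, disk(window_radius)).astype(np.float64)


def aggregate_magnitude(magnitude: np.ndarray, window: int) -> np.ndarray:
    """Box-average the flow magnitude over a local window.

    Blurring displaces individual texture grains in incoherent directions;
    the per-pixel magnitudes are therefore spiky at the grain scale.
    Averaging the modulus (never the vectors, whose directions cancel)
    turns them into a stable per-region flow-energy score.
    """
    if window <= 1:
        return np.asarray(magnitude, dtype=np.float64)
    return ndi.uniform_filter(np.asarray(magnitude, dtype=np.float64), window, mode="reflect")


def _class_stat(values: np.ndarray, statistic: str) -> float:
    return float(np.median(values)) if statistic == "median" else float(values.mean())


def tune_thresholds(
    magnitude: np.ndarray,
    entropy_field: np.ndarray,
    upper_grid=(80.0, 85.0, 90.0, 95.0),
    lower_grid=(20.0, 30.0, 40.0, 50.0),
    statistic: str = "mean",
) -> tuple[float, float, TuningReport]:
    """Exhaustively score every (upper, lower) percentile pair.

    For each pair with upper > lower, pixels with magnitude >= the upper
    percentile are provisionally CELL and <= the lower percentile
    BACKGROUND; the objective is the entropy statistic of the CELL class
    minus that of the BACKGROUND class. Returns the maximizing thresholds
    (ties broken to the smallest upper percentile, then the largest lower
    percentile — the most inclusive labeling) and the full report.

    Raises
    ------
    SelfTuningError
        If the magnitude field is constant, or every candidate pair leaves
        a class empty.
    """
    magnitude = np.asarray(magnitude, dtype=np.float64)
    entropy_field = np.asarray(entropy_field, dtype=np.float64)
    if magnitude.shape != entropy_field.shape:
        raise ContractError("magnitude and entropy fields must share a shape")
    if magnitude.max() == magnitude.min():
        raise SelfTuningError("flow magnitude is constant: percentiles collapse")

    flat_mag = magnitude.ravel()
    flat_ent = entropy_field.ravel()
    percentiles = sorted({float(p) for p in (*upper_grid, *lower_grid)})
    cuts = dict(zip(percentiles, np.percentile(flat_mag, percentiles)))

    candidates: list[TuningCandidate] = []
    best: TuningCandidate | None = None
    for up in upper_grid:
        for lo in lower_grid:
            if up <= lo:
                continue
            t_cell, t_bg = cuts[float(up)], cuts[float(lo)]
            cell_sel = flat_mag >= t_cell
            bg_sel = flat_mag <= t_bg
            n_cell, n_bg = int(cell_sel.sum()), int(bg_sel.sum())
            if n_cell == 0 or n_bg == 0:
                objective = float("nan")
            else:
                objective = _class_stat(flat_ent[cell_sel], statistic) - _class_stat(
                    flat_ent[bg_sel], statistic
                )
            cand = TuningCandidate(float(up), float(lo), float(t_cell), float(t_bg),
                                   n_cell, n_bg, objective)
            candidates.append(cand)
            if np.isnan(objective):
                continue
            if (
                best is None
                or objective > best.objective
                or (
                    objective == best.objective
                    and (cand.upper_percentile, -cand.lower_percentile)
                    < (best.upper_percentile, -best.lower_percentile)
                )
            ):
                best = cand

    if best is None:
        raise SelfTuningError("every threshold candidate left a class empty")
    report = TuningReport(tuple(candidates), best, statistic)
    return best.t_cell, best.t_bg, report


def label_pixels(magnitude: np.ndarray, t_cell: float, t_bg: float) -> PixelLabelSet:
    """Apply a threshold pair: high magnitude CELL, low BACKGROUND.

    ``magnitude >= t_cell`` -> CELL, ``magnitude <= t_bg`` -> BACKGROUND,
    anything strictly between stays UNLABELED (a zero-width band labels
    every pixel).
    """
    if t_cell < t_bg:
        raise ContractError(f"t_cell ({t_cell}) must be >= t_bg ({t_bg})")
    magnitude = np.asarray(magnitude, dtype=np.float64)
    labels = np.full(magnitude.shape, UNLABELED, dtype=np.uint8)
    labels[magnitude >= t_cell] = CELL
    labels[magnitude <= t_bg] = BACKGROUND
    out = PixelLabelSet(labels=labels, thresholds_used=(float(t_cell), float(t_bg)))
    if out.n_cell == 0 or out.n_background == 0:
        raise LabelingError(
            f"empty class after thresholding (n_cell={out.n_cell}, "
            f"n_background={out.n_background})"
        )
    return out


def self_label(
    image: IntensityImage,
    magnitude: np.ndarray,
    entropy_field: np.ndarray,
    config: PipelineConfig,
) -> tuple[PixelLabelSet, TuningReport, np.ndarray]:
    """Full unsupervised stage: aggregate, tune, label.

    Returns the label set, the tuning report, and the aggregated magnitude
    field the thresholds refer to.
    """
    agg = aggregate_magnitude(magnitude, config.magnitude_window)
    t_cell, t_bg, report = tune_thresholds(
        agg,
        entropy_field,
        config.threshold_grid_upper,
        config.threshold_grid_lower,
        config.tuning_statistic,
    )
    labels = label_pixels(agg, t_cell, t_bg)
    return labels, report, agg
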