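"""Per-pixel features: entropy (e), gradient (g), intensity (i).

The three features are deliberately minimal and untransformed so that every
classification decision can be traced back to interpretable image
quantities. Feature fields are computed once on the full original image;
the table simply reads them at the self-labeled pixel positions. (Computing
texture on the zeroed mask-product images instead would poison windowed
features at mask borders, so the product-then-analyze step is treated as
bookkeeping, not arithmetic.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .exceptions import ContractError
from .io import IntensityImage
from .self_label import BACKGROUND, CELL, UNLABELED, PixelLabelSet

__all__ = ["FeatureTable", "gradient_magnitude", "extract_features"]

FEATURE_NAMES = ("e", "g", "i")


@dataclass(frozen=True)
class FeatureTable:
    """One row per self-labeled pixel.

    ``coords`` is (n, 2) of (row, col); ``values`` is (n, 3) of (e, g, i);
    ``labels`` is (n,) of {CELL, BACKGROUND}. Rows are in raster order.
    """

    coords: np.ndarray
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if len(self.coords) != len(self.values) or len(self.values) != len(self.labels):
            raise ContractError("coords, values and labels must align")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_cell(self) -> int:
        return int((self.labels == CELL).sum())

    @property
    def n_background(self) -> int:
        return int((self.labels == BACKGROUND).sum())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "row": self.coords[:, 0],
                "col": self.coords[:, 1],
                "e": self.values[:, 0],
                "g": self.values[:, 1],
                "i": self.values[:, 2],
                "label": np.where(self.labels == CELL, "cell", "background"),
            }
        )
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def gradient_magnitude(image: IntensityImage) -> np.ndarray:
    """Sobel gradient magnitude in intensity units per pixel.

    The classic 3x3 Sobel kernels divided by 8, so a linear ramp of slope
    ``s`` per pixel responds with magnitude ``s`` in the interior.
    """
    gx = ndi.sobel(image.pixels, axis=1, mode="reflect") / 8.0
    gy = ndi.sobel(image.pixels, axis=0, mode="reflect") / 8.0
    return np.hypot(gx, gy)


def extract_features(
    image: IntensityImage,
    labels: PixelLabelSet,
    entropy_field: np.ndarray,
    gradient_field: np.ndarray,
) -> FeatureTable:
    """Read (e, g, i) at every CELL or BACKGROUND pixel.

    UNLABELED pixels are excluded. Feature values are exact lookups into
    the supplied fields — no recomputation, no windowed re-masking.
    """
    for name, fld in (("entropy", entropy_field), ("gradient", gradient_field)):
        if np.asarray(fld).shape != image.shape:
            raise ContractError(f"{name} field shape does not match image")
    if labels.labels.shape != image.shape:
        raise ContractError("label grid shape does not match image")

    selected = labels.labels != UNLABELED
    if not selected.any():
        raise ContractError("label set has no labeled pixels")
    rows, cols = np.nonzero(selected)
    values = np.column_stack(
        [
            np.asarray(entropy_field, dtype=np.float64)[rows, cols],
            np.asarray(gradient_field, dtype=np.float64)[rows, cols],
            image.pixels[rows, cols],
        ]
    )
    return FeatureTable(
        coords=np.column_stack([rows, cols]),
        values=values,
        labels=labels.labels[rows, cols].copy(),
    )
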