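"""Image reading, normalization, and output writing.

The unit of processing is an :class:`IntensityImage`: a single-channel 2-D
float array normalized to [0, 1] by the observed per-image min-max.
Normalizing by the observed range rather than the dtype range means a dim
16-bit confocal frame still occupies the full [0, 1] interval, which matters
because the classifier consumes raw intensity as a feature.

Coordinate convention throughout the package: row-major ``(row, col)``,
0-based; masks share the image grid exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile
import imageio.v3 as iio

from .exceptions import ContractError, DegenerateInputError, ImageReadError

MIN_SIDE = 32  # minimum height/width for windowed entropy and pyramidal flow


@dataclass(frozen=True)
class IntensityImage:
    """A normalized single-channel image.

    Parameters
    ----------
    pixels : ndarray of float64, shape (height, width)
        Intensity values in [0, 1].
    source_path : str
        Provenance string ("" for in-memory images).
    bit_depth_original : int
        Bit depth of the source data (8 or 16; 0 for synthetic floats).
    """

    pixels: np.ndarray
    source_path: str = ""
    bit_depth_original: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ContractError(f"expected a 2-D image, got ndim={px.ndim}")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise ContractError(
                f"image {px.shape} smaller than minimum {MIN_SIDE}x{MIN_SIDE}"
            )
        if px.size and (px.min() < -1e-9 or px.max() > 1 + 1e-9):
            raise ContractError("IntensityImage values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def normalize(raw: np.ndarray, source_path: str = "", bit_depth: int = 0) -> IntensityImage:
    """Min-max normalize a raw 2-D array to [0, 1].

    Raises
    ------
    DegenerateInputError
        If the image is constant (max == min): nothing to segment.
    """
    raw = np.asarray(raw, dtype=np.float64)
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        raise DegenerateInputError(
            f"constant image (all pixels == {lo}): zero dynamic range"
        )
    return IntensityImage((raw - lo) / (hi - lo), source_path, bit_depth)


def read_image(path: str | os.PathLike, channel: int | None = None) -> IntensityImage:
    """Read a TIFF/PNG/JPEG image and normalize it to an IntensityImage.

    Multi-channel inputs require ``channel``; the requested plane is
    extracted before normalization. Channel axis is detected as the axis of
    length <= 4 for RGB(A)-style images, or the first axis of a multi-page
    TIFF stack.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ImageReadError(f"no such file: {path}")
    try:
        if path.lower().endswith((".tif", ".tiff")):
            raw = tifffile.imread(path)
        else:
            raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - report the offending path
        raise ImageReadError(f"cannot read {path}: {exc}") from exc

    raw = np.asarray(raw)
    bit_depth = 16 if raw.dtype.itemsize >= 2 and raw.dtype.kind == "u" else 8
    if raw.dtype.kind == "f":
        bit_depth = 0

    if raw.ndim == 3:
        # channel-last (H, W, C<=4) or stack/channel-first (C, H, W)
        axis = 2 if raw.shape[2] <= 4 else 0
        n_channels = raw.shape[axis]
        if channel is None:
            raise ImageReadError(
                f"{path} has {n_channels} channels; pass channel=<index>"
            )
        if not 0 <= channel < n_channels:
            raise ImageReadError(
                f"channel {channel} out of range for {path} ({n_channels} channels)"
            )
        raw = raw[:, :, channel] if axis == 2 else raw[channel]
    elif raw.ndim != 2:
        raise ImageReadError(f"{path}: unsupported dimensionality {raw.ndim}")

    return normalize(raw, source_path=path, bit_depth=bit_depth)


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a binary mask as an 8-bit TIFF with values {0, 255}."""
    tifffile.imwrite(os.fspath(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a mask TIFF back to a boolean array (any nonzero pixel = True)."""
    return np.asarray(tifffile.imread(os.fspath(path))) > 0


def write_label_image(labels: np.ndarray, path: str | os.PathLike) -> None:
    """Write an integer label image as 16-bit TIFF."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ContractError("more than 65535 objects cannot be stored as uint16")
    tifffile.imwrite(os.fspath(path), labels.astype(np.uint16))


def write_overlay(image: IntensityImage, mask: np.ndarray, path: str | os.PathLike) -> None:
    """Render the image in grayscale with object boundaries in yellow (PNG)."""
    from skimage.segmentation import find_boundaries

    mask = np.asarray(mask)
    if mask.shape != image.shape:
        raise ContractError(f"mask shape {mask.shape} != image shape {image.shape}")
    rgb = np.repeat((image.pixels * 255).astype(np.uint8)[:, :, None], 3, axis=2)
    edges = find_boundaries(mask, mode="outer") if mask.any() else np.zeros(mask.shape, bool)
    rgb[edges] = (255, 255, 0)
    iio.imwrite(os.fspath(path), rgb)


@dataclass
class OutputPaths:
    mask: str
    overlay: str
    model: str
    tuning: str = ""


def output_paths(image_path: str, out_dir: str) -> OutputPaths:
    """Derive deterministic output filenames from the input name."""
    stem = os.path.splitext(os.path.basename(image_path))[0] or "image"
    return OutputPaths(
        mask=os.path.join(out_dir, f"{stem}_mask.tif"),
        overlay=os.path.join(out_dir, f"{stem}_overlay.png"),
        model=os.path.join(out_dir, f"{stem}_model.txt"),
        tuning=os.path.join(out_dir, f"{stem}_tuning.txt"),
    )


def write_outputs(
    mask: np.ndarray,
    image: IntensityImage,
    out_dir: str | os.PathLike,
    model_text: str = "",
    tuning_text: str = "",
    name: str | None = None,
) -> OutputPaths:
    """Write the standard per-image output set.

    Writes (a) the binary mask as 8-bit TIFF (0/255), (b) a boundary-overlay
    PNG, and (c) the per-image model and tuning summaries as plain text.
    Filenames derive deterministically from the input image name.
    """
    mask = np.asarray(mask)
    if mask.shape != image.shape:
        raise ContractError(f"mask shape {mask.shape} != image shape {image.shape}")
    out_dir = os.fspath(out_dir)
    if not os.path.isdir(out_dir):
        try:
            os.makedirs(out_dir, exist_ok=True)
        except OSError as exc:
            raise ImageReadError(f"cannot create output directory {out_dir}: {exc}") from exc
    if not os.access(out_dir, os.W_OK):
        raise ImageReadError(f"output directory not writable: {out_dir}")
    paths = output_paths(name or image.source_path or "image", out_dir)
    write_mask(mask, paths.mask)
    write_overlay(image, mask, paths.overlay)
    with open(paths.model, "w") as fh:
        fh.write(model_text)
    if tuning_text:
        with open(paths.tuning, "w") as fh:
            fh.write(tuning_text)
    return paths
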