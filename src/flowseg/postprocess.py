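"""Mask cleanup, watershed declumping, and boundary extraction.

Connectivity convention: 8-connectivity for foreground objects,
4-connectivity for background (the standard digital-topology pairing).
Declumping partitions the existing foreground — it never grows or shrinks
it — by a watershed on the negated Euclidean distance transform seeded at
distance maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import find_contours
from skimage.morphology import disk
from skimage.segmentation import watershed

from .classify import SegmentationMask

__all__ = ["LabeledMask", "clean_mask", "declump", "extract_boundaries"]

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity for objects


@dataclass(frozen=True)
class LabeledMask:
    """Integer-labeled objects: 0 = background, 1..n = objects.

    Ids are canonical: renumbered 1..n by raster order of each object's
    first pixel, so a fixed input yields identical labelings across runs.
    """

    labels: np.ndarray

    @property
    def n_objects(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def areas(self) -> np.ndarray:
        """Pixel area per object, index k-1 for object k."""
        if self.n_objects == 0:
            return np.zeros(0, dtype=np.int64)
        return np.bincount(self.labels.ravel(), minlength=self.n_objects + 1)[1:]

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0

    def area_table(self) -> pd.DataFrame:
        return pd.DataFrame({"object": np.arange(1, self.n_objects + 1), "area_px": self.areas})


def _canonical_ids(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..n by raster order of first occurrence."""
    labels = np.asarray(labels)
    flat = labels.ravel()
    nonzero = np.nonzero(flat)[0]
    if len(nonzero) == 0:
        return np.zeros_like(labels)
    ids, first = np.unique(flat[nonzero], return_index=True)
    order = np.argsort(first)  # by first raster occurrence
    remap = np.zeros(int(flat.max()) + 1, dtype=labels.dtype)
    remap[ids[order]] = np.arange(1, len(ids) + 1)
    return remap[labels]


def clean_mask(
    mask: SegmentationMask | np.ndarray,
    min_object_area: int = 0,
    fill_holes: bool = False,
) -> SegmentationMask:
    """Drop small specks and optionally fill interior holes.

    ``min_object_area=0`` with ``fill_holes=False`` is the identity.
    """
    arr = mask.mask if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
    provenance = mask.provenance if isinstance(mask, SegmentationMask) else ""
    out = arr.copy()
    if min_object_area > 0:
        labels, n = ndi.label(out, structure=_STRUCT8)
        if n:
            areas = np.bincount(labels.ravel(), minlength=n + 1)
            small = areas < min_object_area
            small[0] = False
            out[small[labels]] = False
    if fill_holes:
        # 4-connected background -> holes are 4-components not touching the border
        out = ndi.binary_fill_holes(out)
    return SegmentationMask(mask=out, provenance=provenance)


def declump(
    mask: SegmentationMask | np.ndarray,
    min_distance: int = 10,
    footprint_radius: int = 7,
) -> LabeledMask:
    """Split touching objects by distance-transform watershed.

    Seeds are local maxima of the Euclidean distance transform separated
    by at least ``min_distance`` pixels (maxima searched within a disk
    footprint of ``footprint_radius``); the watershed floods the negated
    distance transform, constrained to the existing foreground. An empty
    mask yields zero objects.
    """
    arr = mask.mask if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
    if not arr.any():
        return LabeledMask(labels=np.zeros(arr.shape, dtype=np.int32))
    distance = ndi.distance_transform_edt(arr)
    peaks = peak_local_max(
        distance,
        min_distance=min_distance,
        footprint=disk(footprint_radius),
        labels=ndi.label(arr, structure=_STRUCT8)[0],
        exclude_border=False,
    )
    markers = np.zeros(arr.shape, dtype=np.int32)
    for k, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = k
    if markers.max() == 0:  # degenerate: no interior maxima found
        labels, _ = ndi.label(arr, structure=_STRUCT8)
    else:
        labels = watershed(-distance, markers=markers, mask=arr, connectivity=2)
        # any foreground left unlabeled (disconnected from all seeds) keeps
        # its own connected-component id
        orphan = arr & (labels == 0)
        if orphan.any():
            extra, n_extra = ndi.label(orphan, structure=_STRUCT8)
            labels = labels + np.where(orphan, extra + labels.max(), 0)
    return LabeledMask(labels=_canonical_ids(labels).astype(np.int32))


def extract_boundaries(mask: SegmentationMask | LabeledMask | np.ndarray) -> list[np.ndarray]:
    """One closed (row, col) contour per object, outer boundary.

    Returns a list of (k, 2) float arrays; closed means first point equals
    last point. Objects are visited in canonical id order.
    """
    if isinstance(mask, SegmentationMask):
        labels, _ = ndi.label(mask.mask, structure=_STRUCT8)
        labels = _canonical_ids(labels)
    elif isinstance(mask, LabeledMask):
        labels = mask.labels
    else:
        arr = np.asarray(mask)
        if arr.dtype == bool:
            labels, _ = ndi.label(arr, structure=_STRUCT8)
            labels = _canonical_ids(labels)
        else:
            labels = arr
    contours: list[np.ndarray] = []
    for k in range(1, int(labels.max(initial=0)) + 1):
        obj = labels == k
        if not obj.any():
            continue
        # pad so border-touching objects still close their contour
        padded = np.pad(obj, 1)
        cs = find_contours(padded.astype(float), 0.5)
        if not cs:
            continue
        outer = max(cs, key=len) - 1.0  # undo padding offset
        if not np.allclose(outer[0], outer[-1]):
            outer = np.vstack([outer, outer[:1]])
        contours.append(outer)
    return contours
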