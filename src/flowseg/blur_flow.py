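"""Surrogate motion via Gaussian blur, and dense Farneback optical flow.

The method treats an image and its Gaussian-blurred copy as two "frames":
blurring redistributes intensity locally while conserving it globally, which
is exactly the constraint dense optical flow assumes, so textured (cell)
regions show apparent motion while flat background does not.

Two numerical choices matter here:

* **Pixel-integrated Gaussian kernel.** The blur kernel weight at integer
  offset k is the integral of the Gaussian over the pixel [k-1/2, k+1/2]
  (a difference of error functions), not the sampled density. For sigma of a
  pixel or more the two agree to high order; for sub-pixel sigma the sampled
  kernel collapses to the exact identity in floating point (off-center
  weights underflow against 1), whereas the integrated kernel retains a
  small, representable redistribution of intensity — so arbitrarily gentle
  blurs still produce a usable flow field. Downstream thresholding is
  percentile-based and therefore indifferent to the absolute flow scale.

* **Farneback flow implemented over quadratic polynomial expansion.** Each
  local neighborhood of each frame is approximated as
  ``f(x) ~ x^T A x + b^T x + c`` by a Gaussian-weighted least-squares fit
  computed with separable correlations; displacement solves ``A d = Δb``
  averaged over a window, iterated coarse-to-fine over an image pyramid.
  Identical frames give an exactly zero field at every level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.special import erf
from skimage.transform import resize

from .config import FlowParams
from .exceptions import ContractError
from .io import IntensityImage

__all__ = ["DisplacementField", "gaussian_blur", "farneback_flow"]


@dataclass(frozen=True)
class DisplacementField:
    """Per-pixel 2-D displacement between two frames.

    ``dx`` is the column (x) component, ``dy`` the row (y) component, both
    in pixels; ``magnitude = sqrt(dx**2 + dy**2)``. Only the magnitude is
    consumed by the self-labeling stage.
    """

    dx: np.ndarray
    dy: np.ndarray

    def __post_init__(self) -> None:
        if self.dx.shape != self.dy.shape:
            raise ContractError("dx and dy must share a shape")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dx, self.dy)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dx.shape


# ---------------------------------------------------------------------------
# Gaussian blur


def _integrated_gaussian_kernel(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """1-D kernel of per-pixel integrals of a zero-mean Gaussian."""
    radius = max(1, int(np.ceil(truncate * sigma)))
    k = np.arange(-radius, radius + 1, dtype=np.float64)
    denom = sigma * np.sqrt(2.0)
    w = 0.5 * (erf((k + 0.5) / denom) - erf((k - 0.5) / denom))
    return w / w.sum()


def gaussian_blur(image: IntensityImage, sigma: float) -> IntensityImage:
    """Gaussian-blur an image with reflective boundaries.

    Reflective (edge-mirroring) extension with a symmetric normalized kernel
    conserves the summed intensity exactly, which is the property that makes
    the blur a valid surrogate "second frame" for optical flow.
    """
    if sigma <= 0:
        raise ContractError("sigma must be > 0")
    kern = _integrated_gaussian_kernel(sigma)
    out = ndi.correlate1d(image.pixels, kern, axis=0, mode="reflect")
    out = ndi.correlate1d(out, kern, axis=1, mode="reflect")
    # convex combination of [0,1] values; clamp float dust only
    np.clip(out, 0.0, 1.0, out=out)
    return IntensityImage(out, image.source_path, image.bit_depth_original)


# ---------------------------------------------------------------------------
# Farneback dense flow


def _poly_expand(f: np.ndarray, n: int, sigma: float):
    """Quadratic polynomial expansion of every pixel neighborhood.

    Returns ``(A, b)`` with ``A`` the (..., 2, 2) symmetric quadratic-form
    coefficients and ``b`` the (..., 2) linear coefficients, both in (x, y)
    = (col, row) order. The Gaussian applicability has std ``sigma`` over a
    window of ``n`` taps per axis.
    """
    half = (n - 1) // 2
    k = np.arange(-half, half + 1, dtype=np.float64)
    a = np.exp(-(k**2) / (2.0 * sigma**2))
    a0, a1, a2 = a, a * k, a * k * k

    # Normal-equation matrix for basis (1, x, y, x^2, y^2, xy) under the
    # separable applicability; only parity-even entries survive.
    m0, m2, m4 = a.sum(), a2.sum(), (a * k**4).sum()
    G = np.zeros((6, 6))
    G[0, 0] = m0 * m0
    G[1, 1] = G[0, 3] = G[3, 0] = m2 * m0
    G[2, 2] = G[0, 4] = G[4, 0] = m0 * m2
    G[3, 3] = m4 * m0
    G[4, 4] = m0 * m4
    G[5, 5] = G[3, 4] = G[4, 3] = m2 * m2
    Ginv = np.linalg.inv(G)

    def corr(img, w_row, w_col):
        tmp = ndi.correlate1d(img, w_row, axis=0, mode="reflect")
        return ndi.correlate1d(tmp, w_col, axis=1, mode="reflect")

    v = np.empty(f.shape + (6,))
    v[..., 0] = corr(f, a0, a0)  # 1
    v[..., 1] = corr(f, a0, a1)  # x
    v[..., 2] = corr(f, a1, a0)  # y
    v[..., 3] = corr(f, a0, a2)  # x^2
    v[..., 4] = corr(f, a2, a0)  # y^2
    v[..., 5] = corr(f, a1, a1)  # xy
    r = v @ Ginv.T

    A = np.empty(f.shape + (2, 2))
    A[..., 0, 0] = r[..., 3]
    A[..., 1, 1] = r[..., 4]
    A[..., 0, 1] = A[..., 1, 0] = 0.5 * r[..., 5]
    b = np.stack([r[..., 1], r[..., 2]], axis=-1)
    return A, b


def _flow_single_level(f1, f2, d, params: FlowParams):
    """Refine displacement d (.., 2) between frames at one pyramid level.

    Per iteration: warp the second frame's expansion by the rounded current
    displacement, form the normal equations ``(A^T A) d = A^T Δb``,
    optionally average them over ``window_size``, and solve with a Tikhonov
    term ``λ = damping * mean structure energy``. The damping keeps
    weak-structure pixels (flat background) near zero displacement — the
    raw system there is near-singular and its solution unbounded — while
    leaving strongly textured pixels essentially unregularized. Zero
    temporal difference gives exactly zero displacement.
    """
    A1, b1 = _poly_expand(f1, params.poly_n, params.poly_sigma)
    A2, b2 = _poly_expand(f2, params.poly_n, params.poly_sigma)
    h, w = f1.shape
    rows, cols = np.mgrid[0:h, 0:w]

    for _ in range(params.iterations):
        dr = np.rint(d)
        c2 = np.clip(cols + dr[..., 0].astype(np.int64), 0, w - 1)
        r2 = np.clip(rows + dr[..., 1].astype(np.int64), 0, h - 1)
        A = 0.5 * (A1 + A2[r2, c2])
        # Δb = -1/2 (b2(x+d̃) - b1(x)) + A d̃, then solve A d = Δb
        db = -0.5 * (b2[r2, c2] - b1) + np.einsum("...ij,...j->...i", A, dr)
        # A is symmetric, so A^T A and A^T Δb expand elementwise
        G11 = A[..., 0, 0] ** 2 + A[..., 0, 1] ** 2
        G12 = A[..., 0, 1] * (A[..., 0, 0] + A[..., 1, 1])
        G22 = A[..., 1, 1] ** 2 + A[..., 0, 1] ** 2
        h1 = A[..., 0, 0] * db[..., 0] + A[..., 0, 1] * db[..., 1]
        h2 = A[..., 0, 1] * db[..., 0] + A[..., 1, 1] * db[..., 1]
        if params.window_size > 1:
            size = params.window_size
            G11 = ndi.uniform_filter(G11, size, mode="reflect")
            G12 = ndi.uniform_filter(G12, size, mode="reflect")
            G22 = ndi.uniform_filter(G22, size, mode="reflect")
            h1 = ndi.uniform_filter(h1, size, mode="reflect")
            h2 = ndi.uniform_filter(h2, size, mode="reflect")
        lam = params.damping * 0.5 * float(G11.mean() + G22.mean()) + 1e-300
        a11 = G11 + lam
        a22 = G22 + lam
        det = a11 * a22 - G12 * G12
        dx = (a22 * h1 - G12 * h2) / det
        dy = (a11 * h2 - G12 * h1) / det
        d = np.stack([dx, dy], axis=-1)
    return d


def _pyramid(f: np.ndarray, levels: int, scale: float, min_side: int = 16):
    """Image pyramid, finest first."""
    pyr = [f]
    for _ in range(levels - 1):
        h, w = pyr[-1].shape
        nh, nw = int(round(h * scale)), int(round(w * scale))
        if min(nh, nw) < min_side:
            break
        pyr.append(
            resize(pyr[-1], (nh, nw), order=1, mode="reflect",
                   anti_aliasing=True, preserve_range=True)
        )
    return pyr


def farneback_flow(
    original: IntensityImage,
    blurred: IntensityImage,
    params: FlowParams | None = None,
) -> DisplacementField:
    """Dense displacement field mapping ``original`` onto ``blurred``.

    Coarse-to-fine estimation: the field is computed at the lowest pyramid
    resolution, upsampled, and refined at each finer level. The result is
    deterministic in the inputs and parameters; identical inputs give an
    exactly zero field.
    """
    params = params or FlowParams()
    if original.shape != blurred.shape:
        raise ContractError(
            f"shape mismatch: {original.shape} vs {blurred.shape}"
        )
    f1 = original.pixels
    f2 = blurred.pixels
    pyr1 = _pyramid(f1, params.pyramid_levels, params.pyr_scale)
    pyr2 = _pyramid(f2, params.pyramid_levels, params.pyr_scale)

    d = np.zeros(pyr1[-1].shape + (2,))
    for level in range(len(pyr1) - 1, -1, -1):
        if d.shape[:2] != pyr1[level].shape:
            old_h, old_w = d.shape[:2]
            new_h, new_w = pyr1[level].shape
            d = resize(d, (new_h, new_w), order=1, mode="edge",
                       anti_aliasing=False, preserve_range=True)
            d[..., 0] *= new_w / old_w
            d[..., 1] *= new_h / old_h
        d = _flow_single_level(pyr1[level], pyr2[level], d, params)
    return DisplacementField(dx=d[..., 0], dy=d[..., 1])
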