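"""Sampling locations for local features.

The staging pipeline prefers *dense sampling* — descriptors on a regular
grid with a fixed stride — because calcification-related brightness
changes are spread over the whole placental image and sparse interest
points miss them.  The classical detectors (Harris, Hessian, their
Laplace-scale-selected and multiscale variants, and difference of
Gaussians) are provided for comparison.

Coordinate convention (shared by every module): 0-based, ``x`` = column,
``y`` = row, pixel centers at integer coordinates.  ``scale`` is a
Gaussian sigma for blob/corner detectors and the patch half-width for
dense sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import GrayImage

__all__ = ["Keypoint", "dense_grid", "detect_dog", "detect_corner", "CORNER_METHODS"]

CORNER_METHODS = (
    "harris",
    "hessian",
    "harris_laplace",
    "hessian_laplace",
    "multiscale_harris",
    "multiscale_hessian",
)


@dataclass(frozen=True)
class Keypoint:
    x: float  # column
    y: float  # row
    scale: float  # sigma or patch half-width
    response: float = 0.0


def _check_bounds(kps: list[Keypoint], height: int, width: int) -> list[Keypoint]:
    for kp in kps:
        assert 0 <= kp.x < width and 0 <= kp.y < height and kp.scale > 0
    return kps


def dense_grid(
    img: GrayImage,
    step: int,
    patch_size: int,
    scales: list[float] | None = None,
) -> list[Keypoint]:
    """Regular-grid keypoints.

    Patches of side ``patch_size`` are anchored at the top-left corner and
    strided by ``step``; only fully-inside windows are kept, so the count
    per axis is ``floor((dim - patch_size)/step) + 1``.  The grid is
    replicated for each entry of ``scales`` (a patch-size multiplier;
    keypoint scale = multiplier * patch_size / 2), scale-major order.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if scales is None:
        scales = [1.0]
    h, w = img.height, img.width
    if patch_size > min(h, w):
        warnings.warn(
            f"patch_size {patch_size} exceeds image extent {h}x{w}; no keypoints",
            stacklevel=2,
        )
        return []
    ys = np.arange(0, h - patch_size + 1, step)
    xs = np.arange(0, w - patch_size + 1, step)
    half = (patch_size - 1) / 2.0
    kps: list[Keypoint] = []
    for s in scales:
        kps.extend(
            Keypoint(x=x + half, y=y + half, scale=s * patch_size / 2.0, response=0.0)
            for y in ys
            for x in xs
        )
    return _check_bounds(kps, h, w)


# ---------------------------------------------------------------------------
# Difference-of-Gaussians blob detector


def _dog_scale_space(px: np.ndarray, n_octaves: int, levels: int):
    sigma0 = 1.6
    n_gauss = n_octaves * levels + 2
    sigmas = sigma0 * 2.0 ** (np.arange(n_gauss) / levels)
    gauss = np.stack([ndimage.gaussian_filter(px, s, mode="nearest") for s in sigmas])
    dog = gauss[1:] - gauss[:-1]
    return dog, sigmas


def detect_dog(
    img: GrayImage,
    n_octaves: int = 4,
    levels_per_octave: int = 3,
    peak_threshold: float = 0.01,
    edge_threshold: float = 10.0,
) -> list[Keypoint]:
    """Difference-of-Gaussians blob detector.

    Keypoints are 3x3x3 local extrema of the DoG scale stack (built on a
    single-resolution sigma ladder, ratio ``2^(1/levels)``) that pass the
    absolute-response threshold and the principal-curvature edge test.
    The returned scale is the sigma of the level; response is |DoG|.
    """
    px = img.pixels
    if min(px.shape) < 8:
        return []
    dog, sigmas = _dog_scale_space(px, n_octaves, levels_per_octave)

    mx = ndimage.maximum_filter(dog, size=3, mode="nearest")
    mn = ndimage.minimum_filter(dog, size=3, mode="nearest")
    is_ext = ((dog == mx) & (dog > 0)) | ((dog == mn) & (dog < 0))
    is_ext &= np.abs(dog) >= peak_threshold
    # exclude stack and image borders (incomplete 3x3x3 neighborhood)
    is_ext[0] = is_ext[-1] = False
    is_ext[:, :1, :] = is_ext[:, -1:, :] = False
    is_ext[:, :, :1] = is_ext[:, :, -1:] = False

    r = edge_threshold
    edge_lim = (r + 1.0) ** 2 / r
    kps: list[Keypoint] = []
    for lvl in np.unique(np.nonzero(is_ext)[0]):
        d = dog[lvl]
        ys, xs = np.nonzero(is_ext[lvl])
        dxx = d[ys, xs + 1] + d[ys, xs - 1] - 2 * d[ys, xs]
        dyy = d[ys + 1, xs] + d[ys - 1, xs] - 2 * d[ys, xs]
        dxy = (
            d[ys + 1, xs + 1] - d[ys + 1, xs - 1] - d[ys - 1, xs + 1] + d[ys - 1, xs - 1]
        ) / 4.0
        det = dxx * dyy - dxy**2
        tr = dxx + dyy
        with np.errstate(divide="ignore", invalid="ignore"):
            ok = (det > 0) & (tr**2 / det < edge_lim)
        for y, x in zip(ys[ok], xs[ok]):
            kps.append(
                Keypoint(float(x), float(y), float(sigmas[lvl]), float(abs(d[y, x])))
            )
    kps.sort(key=lambda kp: (-kp.response, kp.y, kp.x))
    return _check_bounds(kps, *px.shape)


# ---------------------------------------------------------------------------
# Corner / blob-strength detectors


def _harris_response(px: np.ndarray, sigma: float, k: float) -> np.ndarray:
    # scale-normalized derivatives at sigma, integration at 2*sigma
    ix = sigma * ndimage.gaussian_filter(px, sigma, order=(0, 1), mode="nearest")
    iy = sigma * ndimage.gaussian_filter(px, sigma, order=(1, 0), mode="nearest")
    si = 2.0 * sigma
    sxx = ndimage.gaussian_filter(ix * ix, si, mode="nearest")
    syy = ndimage.gaussian_filter(iy * iy, si, mode="nearest")
    sxy = ndimage.gaussian_filter(ix * iy, si, mode="nearest")
    return sxx * syy - sxy**2 - k * (sxx + syy) ** 2


def _second_derivatives(px: np.ndarray, sigma: float):
    """Gaussian second derivatives via two first-derivative passes.

    The truncated even-order derivative kernels do not sum exactly to
    zero, which would leave a spurious response on constant images;
    odd (first-derivative) kernels are exactly constant-annihilating."""
    s = sigma / np.sqrt(2.0)
    dx = ndimage.gaussian_filter(px, s, order=(0, 1), mode="nearest")
    dy = ndimage.gaussian_filter(px, s, order=(1, 0), mode="nearest")
    lxx = ndimage.gaussian_filter(dx, s, order=(0, 1), mode="nearest")
    lyy = ndimage.gaussian_filter(dy, s, order=(1, 0), mode="nearest")
    lxy = ndimage.gaussian_filter(dx, s, order=(1, 0), mode="nearest")
    return lxx, lyy, lxy


def _hessian_response(px: np.ndarray, sigma: float) -> np.ndarray:
    lxx, lyy, lxy = _second_derivatives(px, sigma)
    return sigma**4 * (lxx * lyy - lxy**2)


def _norm_laplacian(px: np.ndarray, sigma: float) -> np.ndarray:
    lxx, lyy, _ = _second_derivatives(px, sigma)
    return sigma**2 * (lxx + lyy)


def _spatial_maxima(resp: np.ndarray, threshold: float):
    """3x3 non-max suppression; strictly positive responses above threshold."""
    mx = ndimage.maximum_filter(resp, size=3, mode="nearest")
    mask = (resp == mx) & (resp > threshold)
    mask[:1, :] = mask[-1:, :] = False
    mask[:, :1] = mask[:, -1:] = False
    return np.nonzero(mask)


def detect_corner(
    img: GrayImage,
    method: str = "harris",
    scales: list[float] | None = None,
    k_harris: float = 0.06,
    threshold: float = 1e-9,
) -> list[Keypoint]:
    """Harris / Hessian corner detection with optional scale selection.

    ``harris`` / ``hessian`` run at a single scale (``scales[0]``).  The
    ``multiscale_*`` variants return the spatial maxima at every scale.
    The ``*_laplace`` variants keep a multiscale detection only where the
    scale-normalized Laplacian magnitude is a local extremum across
    scales (one-sided comparison at the ladder ends).
    """
    if method not in CORNER_METHODS:
        raise ValueError(f"unknown corner method {method!r}")
    if scales is None:
        scales = [2.0] if method in ("harris", "hessian") else [1.0, 2.0, 4.0]
    if not scales:
        raise ValueError("scales must be non-empty")

    px = img.pixels
    resp_fn = _harris_response if "harris" in method else _hessian_response
    if method in ("harris", "hessian"):
        scales = scales[:1]

    responses = [
        resp_fn(px, s, k_harris) if "harris" in method else resp_fn(px, s)
        for s in scales
    ]
    kps: list[Keypoint] = []
    if method.endswith("_laplace"):
        laps = np.stack([np.abs(_norm_laplacian(px, s)) for s in scales])
        for i, (s, resp) in enumerate(zip(scales, responses)):
            ys, xs = _spatial_maxima(resp, threshold)
            lo = laps[i - 1, ys, xs] if i > 0 else -np.inf
            hi = laps[i + 1, ys, xs] if i + 1 < len(scales) else -np.inf
            keep = laps[i, ys, xs] >= np.maximum(lo, hi)
            for y, x in zip(ys[keep], xs[keep]):
                kps.append(Keypoint(float(x), float(y), float(s), float(resp[y, x])))
    else:
        for s, resp in zip(scales, responses):
            ys, xs = _spatial_maxima(resp, threshold)
            for y, x in zip(ys, xs):
                kps.append(Keypoint(float(x), float(y), float(s), float(resp[y, x])))
    kps.sort(key=lambda kp: (-kp.response, kp.y, kp.x))
    return _check_bounds(kps, *px.shape)


def keypoints_to_csv(kps: list[Keypoint], path) -> None:
    """Serialize keypoints as ``x,y,scale,response`` CSV."""
    arr = np.array([[kp.x, kp.y, kp.scale, kp.response] for kp in kps]).reshape(-1, 4)
    np.savetxt(path, arr, delimiter=",", header="x,y,scale,response", comments="")
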