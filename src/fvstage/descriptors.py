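"""Local feature descriptors: SIFT, DAISY, LIOP, raw intensity, and the
SIFT+intensity combination.

All descriptors are computed *upright* (no dominant-orientation
assignment): dense sampling, the pipeline's preferred detector,
conventionally omits orientation, and doing so keeps the descriptor
kinds directly comparable.  Patch boundary handling is clamp-to-edge
everywhere so no descriptor ever contains NaNs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .image_io import GrayImage
from .keypoints import Keypoint, dense_grid

__all__ = [
    "DescriptorSet",
    "sift_descriptor",
    "dense_sift",
    "liop_descriptor",
    "daisy_descriptor",
    "intensity_descriptor",
    "combine_descriptors",
    "compute_descriptors",
]


@dataclass(frozen=True)
class DescriptorSet:
    """A T x D matrix of local descriptors with their image coordinates."""

    vectors: np.ndarray  # (T, D)
    coords: np.ndarray  # (T, 2) as (x, y)
    descriptor_kind: str

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vectors, dtype=np.float64))
        c = np.asarray(self.coords, dtype=np.float64).reshape(-1, 2)
        if v.shape[0] != c.shape[0]:
            raise ValueError("vectors and coords disagree on descriptor count")
        if not np.all(np.isfinite(v)):
            raise ValueError("descriptors must be finite")
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "coords", c)

    @property
    def T(self) -> int:
        return self.vectors.shape[0]

    @property
    def D(self) -> int:
        return self.vectors.shape[1]


def _bilinear(px: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bilinear sample with clamp-to-edge; x = column, y = row."""
    h, w = px.shape
    x = np.clip(x, 0.0, w - 1.0)
    y = np.clip(y, 0.0, h - 1.0)
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx = x - x0
    fy = y - y0
    return (
        px[y0, x0] * (1 - fx) * (1 - fy)
        + px[y0, x1] * fx * (1 - fy)
        + px[y1, x0] * (1 - fx) * fy
        + px[y1, x1] * fx * fy
    )


def _gradients(px: np.ndarray):
    gy, gx = np.gradient(px)
    return gx, gy


def _safe_l2(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


# ---------------------------------------------------------------------------
# SIFT


def sift_descriptor(
    img: GrayImage,
    kp: Keypoint,
    n_spatial_bins: int = 4,
    n_orient_bins: int = 8,
    _grads=None,
) -> np.ndarray:
    """Upright SIFT: a ``n_spatial_bins**2 x n_orient_bins`` histogram of
    Gaussian-weighted gradient orientations over the keypoint's patch
    (side = 2 * scale), trilinearly binned, L2-normalized, clipped at 0.2
    and renormalized.  A constant patch yields the zero vector.
    """
    hist = _sift_raw_histogram(img, kp, n_spatial_bins, n_orient_bins, _grads)
    hist = _safe_l2(hist)
    hist = np.minimum(hist, 0.2)
    return _safe_l2(hist)


def _sift_raw_histogram(
    img: GrayImage,
    kp: Keypoint,
    n_spatial_bins: int = 4,
    n_orient_bins: int = 8,
    _grads=None,
) -> np.ndarray:
    """Unnormalized spatial x orientation gradient histogram."""
    gx, gy = _grads if _grads is not None else _gradients(img.pixels)
    side = 2.0 * kp.scale
    n_samp = max(int(round(side)), n_spatial_bins)
    # unit-ish spaced sample offsets covering [-side/2, side/2]
    offs = (np.arange(n_samp) + 0.5) / n_samp * side - side / 2.0
    u, v = np.meshgrid(offs, offs)  # u: x-offset, v: y-offset
    sx = kp.x + u.ravel()
    sy = kp.y + v.ravel()
    m = np.hypot(_bilinear(gx, sx, sy), _bilinear(gy, sx, sy))
    theta = np.mod(np.arctan2(_bilinear(gy, sx, sy), _bilinear(gx, sx, sy)), 2 * np.pi)
    w = np.exp(-(u.ravel() ** 2 + v.ravel() ** 2) / (2 * (side / 2.0) ** 2))
    wm = w * m

    # fractional bin coordinates
    bx = (u.ravel() + side / 2.0) / side * n_spatial_bins - 0.5
    by = (v.ravel() + side / 2.0) / side * n_spatial_bins - 0.5
    bo = theta / (2 * np.pi) * n_orient_bins  # bin centers at k*2pi/n

    hist = np.zeros(n_spatial_bins * n_spatial_bins * n_orient_bins)
    x0 = np.floor(bx).astype(int)
    y0 = np.floor(by).astype(int)
    o0 = np.floor(bo).astype(int)
    fx, fy, fo = bx - x0, by - y0, bo - o0
    for dx_, wx in ((0, 1 - fx), (1, fx)):
        xb = x0 + dx_
        okx = (xb >= 0) & (xb < n_spatial_bins)
        for dy_, wy in ((0, 1 - fy), (1, fy)):
            yb = y0 + dy_
            oky = okx & (yb >= 0) & (yb < n_spatial_bins)
            for do_, wo in ((0, 1 - fo), (1, fo)):
                ob = np.mod(o0 + do_, n_orient_bins)
                idx = (yb * n_spatial_bins + xb) * n_orient_bins + ob
                contrib = wm * wx * wy * wo
                hist += np.bincount(
                    idx[oky], weights=contrib[oky], minlength=hist.size
                )
    return hist


def dense_sift(
    img: GrayImage,
    step: int = 8,
    patch_sizes: list[int] | None = None,
    n_spatial_bins: int = 4,
    n_orient_bins: int = 8,
) -> DescriptorSet:
    """SIFT at every dense-grid keypoint for every patch size
    (scale-major, raster order within a scale)."""
    if patch_sizes is None:
        patch_sizes = [16]
    grads = _gradients(img.pixels)
    vecs, coords = [], []
    for p in patch_sizes:
        for kp in dense_grid(img, step=step, patch_size=p):
            vecs.append(
                sift_descriptor(img, kp, n_spatial_bins, n_orient_bins, _grads=grads)
            )
            coords.append((kp.x, kp.y))
    d = n_spatial_bins * n_spatial_bins * n_orient_bins
    return DescriptorSet(
        np.array(vecs).reshape(-1, d), np.array(coords).reshape(-1, 2), "sift"
    )


# ---------------------------------------------------------------------------
# LIOP

_PERM_CACHE: dict[int, dict[tuple, int]] = {}


def _perm_index(order: tuple[int, ...]) -> int:
    """Lexicographic index of a permutation among all n! permutations."""
    n = len(order)
    table = _PERM_CACHE.setdefault(
        n, {p: i for i, p in enumerate(permutations(range(n)))}
    )
    return table[order]


def liop_descriptor(
    patch: GrayImage,
    n_neighbors: int = 4,
    n_bins: int = 6,
    radius: float = 6.0,
) -> np.ndarray:
    """Local intensity order pattern over the patch's inscribed circle.

    Each region pixel is assigned an ordinal bin by the rank of its
    intensity (equal-population thresholds over all region pixels, ties
    broken by raster order), and ``n_neighbors`` points are sampled
    anticlockwise on the circle of ``radius`` around it, anchored at the
    pixel's outward radial direction so the construction is rotation
    invariant.  The permutation sorting those samples ascending indexes a
    histogram cell; the (n_bins x n_neighbors!) histogram is
    L2-normalized.  Invariant to monotonic intensity changes (intensity
    ranks and sample orderings are preserved).
    """
    if n_neighbors > 5:
        raise ValueError("n_neighbors > 5 is intractable (factorial growth)")
    px = patch.pixels
    h, w = px.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rr = (min(h, w) - 1) / 2.0
    ys, xs = np.mgrid[0:h, 0:w]
    region = (ys - cy) ** 2 + (xs - cx) ** 2 <= rr**2 + 1e-9
    ry, rx = ys[region], xs[region]
    n_region = ry.size

    # ordinal bin by equal-population intensity rank, stable raster ties
    vals = px[ry, rx]
    ranks = np.empty(n_region, dtype=int)
    ranks[np.argsort(vals, kind="stable")] = np.arange(n_region)
    bins = np.minimum((ranks * n_bins) // n_region, n_bins - 1)

    # outward radial unit vector per pixel (exact swap/negate under 90 deg
    # rotations); the center pixel has no radial direction and is skipped
    dx = rx - cx
    dy = ry - cy
    dist = np.hypot(dx, dy)
    noncenter = dist > 0
    safe = np.where(noncenter, dist, 1.0)
    ux = dx / safe
    uy = dy / safe

    angles = 2 * np.pi * np.arange(n_neighbors) / n_neighbors
    cos_a, sin_a = np.cos(angles), np.sin(angles)
    # sample i offset = radius * Rot(angle_i) @ (ux, uy); anticlockwise
    sx = rx[:, None] + radius * (cos_a[None, :] * ux[:, None] - sin_a[None, :] * uy[:, None])
    sy = ry[:, None] + radius * (sin_a[None, :] * ux[:, None] + cos_a[None, :] * uy[:, None])

    inside = (
        (sx >= 0) & (sx <= w - 1) & (sy >= 0) & (sy <= h - 1)
    ).all(axis=1) & noncenter
    n_fact = math.factorial(n_neighbors)
    hist = np.zeros(n_bins * n_fact)
    if not inside.any():
        warnings.warn(
            "LIOP radius leaves no pixel with a complete neighborhood; zero vector",
            stacklevel=2,
        )
        return hist

    samples = _bilinear(px, sx[inside].ravel(), sy[inside].ravel()).reshape(-1, n_neighbors)
    for b, row in zip(bins[inside], samples):
        order = tuple(np.argsort(row, kind="stable"))
        hist[b * n_fact + _perm_index(order)] += 1.0
    return _safe_l2(hist)


# ---------------------------------------------------------------------------
# DAISY

from scipy import ndimage as _ndi  # noqa: E402  (local alias for clarity)


def daisy_descriptor(
    img: GrayImage,
    kp: Keypoint,
    n_rings: int = 3,
    n_histograms_per_ring: int = 8,
    n_orient_bins: int = 8,
    ring_radii: list[float] | None = None,
    _maps=None,
) -> np.ndarray:
    """DAISY: half-wave-rectified oriented gradient maps smoothed by
    ring-dependent Gaussians (sigma = radius/2), sampled at the keypoint
    and at ``n_histograms_per_ring`` anticlockwise points per ring
    (starting at angle 0).  Each length-``n_orient_bins`` histogram is
    L2-normalized, then all are concatenated: center first, then rings
    inside-out.  Default dimension (3*8+1)*8 = 200.
    """
    if ring_radii is None:
        ring_radii = [5.0, 10.0, 15.0]
    if len(ring_radii) != n_rings:
        raise ValueError("ring_radii must have n_rings entries")
    maps = _maps if _maps is not None else _daisy_maps(
        img.pixels, n_orient_bins, ring_radii
    )
    hists = [
        np.array([_bilinear(m, np.array([kp.x]), np.array([kp.y]))[0] for m in maps[0]])
    ]
    for j, rad in enumerate(ring_radii):
        phis = 2 * np.pi * np.arange(n_histograms_per_ring) / n_histograms_per_ring
        pxs = kp.x + rad * np.cos(phis)
        pys = kp.y + rad * np.sin(phis)
        ring_maps = maps[j + 1]
        for px_, py_ in zip(pxs, pys):
            hists.append(
                np.array(
                    [_bilinear(m, np.array([px_]), np.array([py_]))[0] for m in ring_maps]
                )
            )
    # per-histogram L2, then a global L2 so descriptor norms are comparable
    return _safe_l2(np.concatenate([_safe_l2(hh) for hh in hists]))


def _daisy_maps(px: np.ndarray, n_orient: int, ring_radii: list[float]):
    """Smoothed oriented-gradient maps, one set per ring (plus center).

    The center histogram uses the innermost ring's smoothing."""
    gx, gy = _gradients(px)
    angles = 2 * np.pi * np.arange(n_orient) / n_orient
    oriented = [np.maximum(np.cos(a) * gx + np.sin(a) * gy, 0.0) for a in angles]
    sigmas = [ring_radii[0] / 2.0] + [r / 2.0 for r in ring_radii]
    return [
        [_ndi.gaussian_filter(o, s, mode="nearest") for o in oriented] for s in sigmas
    ]


# ---------------------------------------------------------------------------
# Raw intensity


def intensity_descriptor(img: GrayImage, kp: Keypoint, side: int = 16) -> np.ndarray:
    """Bilinearly resampled ``side x side`` patch (extent = 2 * scale),
    flattened row-major, mean-subtracted and L2-normalized."""
    if side < 2:
        raise ValueError("side must be >= 2")
    extent = 2.0 * kp.scale
    offs = (np.arange(side) + 0.5) / side * extent - extent / 2.0
    u, v = np.meshgrid(offs, offs)
    vals = _bilinear(img.pixels, kp.x + u.ravel(), kp.y + v.ravel())
    vals = vals - vals.mean()
    if np.linalg.norm(vals) < 1e-10:  # constant patch up to rounding noise
        return np.zeros(side * side)
    return _safe_l2(vals)


def combine_descriptors(a: DescriptorSet, b: DescriptorSet) -> DescriptorSet:
    """Row-wise concatenation of two descriptor sets over identical keypoints."""
    if a.T != b.T or not np.allclose(a.coords, b.coords):
        raise ValueError("descriptor sets must share keypoints (same coords, order)")
    return DescriptorSet(
        np.hstack([a.vectors, b.vectors]), a.coords.copy(), "combine"
    )


# ---------------------------------------------------------------------------
# Dispatcher used by the pipeline / CLI


def compute_descriptors(
    img: GrayImage,
    keypoints: list[Keypoint],
    kind: str = "sift",
    liop_patch_side: int = 21,
    intensity_side: int = 16,
) -> DescriptorSet:
    """Compute descriptors of the given kind at arbitrary keypoints."""
    coords = np.array([(kp.x, kp.y) for kp in keypoints]).reshape(-1, 2)
    if kind == "sift":
        grads = _gradients(img.pixels)
        vecs = [sift_descriptor(img, kp, _grads=grads) for kp in keypoints]
        d = 128
    elif kind == "intensity":
        vecs = [intensity_descriptor(img, kp, side=intensity_side) for kp in keypoints]
        d = intensity_side**2
    elif kind == "combine":
        s = compute_descriptors(img, keypoints, "sift")
        i = compute_descriptors(img, keypoints, "intensity",
                                intensity_side=intensity_side)
        return combine_descriptors(s, i)
    elif kind == "daisy":
        ring_radii = [5.0, 10.0, 15.0]
        maps = _daisy_maps(img.pixels, 8, ring_radii)
        vecs = [
            daisy_descriptor(img, kp, ring_radii=ring_radii, _maps=maps)
            for kp in keypoints
        ]
        d = 200
    elif kind == "liop":
        half = liop_patch_side // 2
        px = np.pad(img.pixels, half, mode="edge")
        vecs = []
        for kp in keypoints:
            y0 = int(round(kp.y))
            x0 = int(round(kp.x))
            sub = px[y0 : y0 + 2 * half + 1, x0 : x0 + 2 * half + 1]
            vecs.append(liop_descriptor(GrayImage(sub), radius=min(6.0, half / 2.0)))
        d = 6 * 24
    else:
        raise ValueError(f"unknown descriptor kind {kind!r}")
    return DescriptorSet(np.array(vecs).reshape(-1, d), coords, kind)
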