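"""Image loading and pre-processing.

Every stage of the pipeline consumes a :class:`GrayImage`: a 2-D float
array with intensities in [0, 1].  Raw B-mode ultrasound frames (or the
synthetic stand-ins) are loaded from PNG/TIFF, reduced to one luminance
channel, optionally denoised (speckle suppression) and range-normalized
before any feature is extracted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "GrayImage",
    "load_image",
    "load_manifest",
    "denoise",
    "normalize_intensity",
]

# Rec.601 luma weights for RGB -> gray reduction.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale image with intensities in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"GrayImage requires a 2-D array, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("GrayImage pixels must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("GrayImage pixels must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def load_image(path: str | os.PathLike) -> GrayImage:
    """Load a PNG/TIFF raster as a :class:`GrayImage`.

    Multi-channel images are reduced to luminance with Rec.601 weights.
    Integer dtypes are rescaled so the maximum representable value maps
    to 1.0 (e.g. 255 for uint8, 65535 for uint16).
    """
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize into one error type
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.size == 0:
        raise IOError(f"image file {path!r} is empty")
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] >= 3:
            arr = arr[..., :3].astype(np.float64) @ _LUMA
        else:
            arr = arr[..., 0].astype(np.float64)
    elif arr.ndim != 2:
        raise IOError(f"image file {path!r} has unsupported shape {arr.shape}")

    if np.issubdtype(np.asarray(arr).dtype, np.integer):
        info = np.iinfo(arr.dtype)
        arr = arr.astype(np.float64) / float(info.max)
    else:
        arr = arr.astype(np.float64)
        # Float inputs (and luma-reduced integer RGB) may exceed 1 slightly.
        if arr.max() > 1.0:
            scale = 255.0 if arr.max() <= 255.0 else 65535.0
            arr = arr / scale
    return GrayImage(np.clip(arr, 0.0, 1.0))


def load_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a ``path,stage`` CSV manifest; paths resolve relative to the CSV."""
    df = pd.read_csv(path)
    if not {"path", "stage"}.issubset(df.columns):
        raise ValueError(f"manifest {path!r} must have columns 'path' and 'stage'")
    stages = df["stage"].to_numpy()
    if not np.isin(stages, [0, 1, 2, 3]).all():
        raise ValueError("manifest stages must be integers in {0,1,2,3}")
    base = os.path.dirname(os.fspath(path))
    df = df.copy()
    df["path"] = [
        p if os.path.isabs(p) else os.path.join(base, p) for p in df["path"]
    ]
    return df


def denoise(img: GrayImage, method: str = "median", radius: int = 1) -> GrayImage:
    """Noise reduction: ``median`` (default, speckle-appropriate),
    ``gaussian`` or ``none``."""
    if method == "none":
        return img
    if radius < 1:
        raise ValueError("radius must be >= 1 for median/gaussian denoising")
    if method == "median":
        size = 2 * int(radius) + 1
        out = ndimage.median_filter(img.pixels, size=size, mode="nearest")
    elif method == "gaussian":
        out = ndimage.gaussian_filter(img.pixels, sigma=float(radius), mode="nearest")
    else:
        raise ValueError(f"unknown denoise method {method!r}")
    return GrayImage(np.clip(out, 0.0, 1.0))


def normalize_intensity(img: GrayImage) -> GrayImage:
    """Affine rescale to full [0, 1] range; constant images map to 0."""
    px = img.pixels
    lo, hi = px.min(), px.max()
    if hi - lo <= 0.0:
        return GrayImage(np.zeros_like(px))
    return GrayImage((px - lo) / (hi - lo))
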