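"""Synthetic four-stage texture fixtures.

Clinical placental ultrasound data cannot ship with the package, so this
module generates speckle-textured images whose four classes emulate the
visual progression of placental calcification on B-mode ultrasound:
stage 0 is plain speckle, and later stages add increasingly many, and
increasingly bright, echogenic foci plus ring-like arc segments (stage 3
arcs reach the lower border, as basal-plate calcification does).

The generator reproduces the *statistical* structure the staging method
relies on — four texture classes separated by the density and brightness
of bright structures — not anatomical or acoustic realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .descriptors import DescriptorSet
from .encoding import GMMModel
from .image_io import GrayImage

__all__ = [
    "StageParams",
    "StagedDataset",
    "generate_stage_image",
    "generate_dataset",
    "sample_from_gmm",
]

# Per-stage defaults: (n_foci, focus_brightness, ring_arcs).  Foci count
# and arc count are non-decreasing in stage (calcification progresses
# with maturity).
_STAGE_DEFAULTS = {
    0: (0, 0.0, 0),
    1: (6, 0.35, 0),
    2: (14, 0.5, 2),
    3: (28, 0.65, 4),
}


@dataclass(frozen=True)
class StageParams:
    """Appearance parameters of one synthetic stage image."""

    stage: int
    seed: int
    speckle_scale: float = 2.0
    n_foci: int = 0
    focus_brightness: float = 0.0
    ring_arcs: int = 0

    def __post_init__(self) -> None:
        if self.stage not in (0, 1, 2, 3):
            raise ValueError(f"stage must be 0..3, got {self.stage}")

    @classmethod
    def default(cls, stage: int, seed: int) -> "StageParams":
        if stage not in _STAGE_DEFAULTS:
            raise ValueError(f"stage must be 0..3, got {stage}")
        n_foci, brightness, arcs = _STAGE_DEFAULTS[stage]
        return cls(stage=stage, seed=seed, n_foci=n_foci,
                   focus_brightness=brightness, ring_arcs=arcs)


@dataclass(frozen=True)
class StagedDataset:
    images: list
    labels: np.ndarray
    seeds: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != labels.size:
            raise ValueError("images and labels must have equal length")
        if not np.isin(labels, [0, 1, 2, 3]).all():
            raise ValueError("labels must be stages 0..3")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "seeds", np.asarray(self.seeds, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.images)


def _add_blob(canvas: np.ndarray, cy: float, cx: float, sigma: float,
              amp: float) -> None:
    h, w = canvas.shape
    r = int(3 * sigma) + 1
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] += amp * np.exp(
        -((ys - cy) ** 2 + (xs - cx) ** 2) / (2 * sigma**2)
    )


def generate_stage_image(params: StageParams, height: int = 128,
                         width: int = 128) -> GrayImage:
    """Render one stage image: smoothed multiplicative (exponential)
    speckle, plus stage-dependent bright foci and arc segments.

    Deterministic given ``params.seed``.  Stage-3 arcs are placed so they
    reach the lower image border.
    """
    if height < 64 or width < 64:
        raise ValueError("images must be at least 64x64")
    rng = np.random.default_rng(params.seed)

    # multiplicative speckle: exponential field smoothed to the speckle scale
    speckle = ndimage.gaussian_filter(
        rng.exponential(1.0, (height, width)), params.speckle_scale, mode="reflect"
    )
    lo, hi = speckle.min(), speckle.max()
    base = 0.12 + 0.3 * (speckle - lo) / max(hi - lo, 1e-12)
    # pin the speckle mean so stage ordering is driven by the additive
    # bright structures, not by per-image speckle fluctuations
    base *= 0.25 / base.mean()

    extra = np.zeros_like(base)
    for _ in range(params.n_foci):
        cy = rng.uniform(4, height - 4)
        cx = rng.uniform(4, width - 4)
        sigma = rng.uniform(1.2, 2.5)
        amp = params.focus_brightness * rng.uniform(0.7, 1.0)
        _add_blob(extra, cy, cx, sigma, amp)

    for a in range(params.ring_arcs):
        # arcs on a circle around the image center; stage 3 arcs use a
        # radius that touches the lower border
        if params.stage == 3:
            radius = (height - 2) / 2.0
        else:
            radius = rng.uniform(0.25, 0.42) * min(height, width)
        phi0 = rng.uniform(0, 2 * np.pi)
        span = rng.uniform(0.5, 1.2)
        if params.stage == 3 and a == 0:
            phi0, span = np.pi / 2 - 0.4, 0.8  # bottom of the circle
        n_pts = max(int(radius * span), 8)
        phis = phi0 + np.linspace(0, span, n_pts)
        cy0, cx0 = (height - 1) / 2.0, (width - 1) / 2.0
        amp = max(params.focus_brightness, 0.3) * 0.8
        for phi in phis:
            _add_blob(extra, cy0 + radius * np.sin(phi), cx0 + radius * np.cos(phi),
                      1.5, amp / 3.0)

    return GrayImage(np.clip(base + extra, 0.0, 1.0))


def generate_dataset(n_per_stage: int = 30, height: int = 128, width: int = 128,
                     master_seed: int = 0) -> StagedDataset:
    """Balanced labeled dataset: ``4 * n_per_stage`` images, stage-major
    order, per-image seeds derived from ``master_seed`` via a counter."""
    if n_per_stage < 1:
        raise ValueError("n_per_stage must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    seeds = ss.generate_state(4 * n_per_stage).astype(np.int64) % (2**31)
    images, labels = [], []
    i = 0
    for stage in range(4):
        for _ in range(n_per_stage):
            params = StageParams.default(stage, int(seeds[i]))
            images.append(generate_stage_image(params, height, width))
            labels.append(stage)
            i += 1
    return StagedDataset(images, np.array(labels), seeds)


def sample_from_gmm(gmm: GMMModel, T: int, seed: int) -> DescriptorSet:
    """Draw T descriptors from the mixture (component by weight, then a
    diagonal Gaussian draw); used to exercise the encoders."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(gmm.K, size=T, p=gmm.weights)
    X = rng.normal(gmm.means[comp], np.sqrt(gmm.variances[comp]))
    return DescriptorSet(X, np.zeros((T, 2)), "synthetic")
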