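"""Multi-layer (spatial-pyramid) encoding.

A single image-level encoding discards where in the image the local
descriptors came from.  The multi-layer scheme partitions the image into
nested grids — the full image (1,1) plus finer subdivisions — encodes
each region independently against the shared vocabulary, and
concatenates the region blocks, so spatial layout enters the final
representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors import DescriptorSet
from .encoding import (
    EncodedVector,
    GMMModel,
    encode_bovw,
    encode_fv,
    encode_vlad,
    normalize_fv,
)

__all__ = ["PyramidLayout", "partition_regions", "encode_multilayer"]

_ENCODERS = {"fv": encode_fv, "vlad": encode_vlad, "bovw": encode_bovw}


@dataclass(frozen=True)
class PyramidLayout:
    """Grid shapes of the pyramid layers, e.g. [(1,1), (2,2)].

    The (1,1) layer — the whole image — must be present."""

    layers: tuple = ((1, 1), (2, 2))

    def __post_init__(self) -> None:
        layers = tuple((int(r), int(c)) for r, c in self.layers)
        if (1, 1) not in layers:
            raise ValueError("pyramid layout must include the full-image (1,1) layer")
        if any(r < 1 or c < 1 for r, c in layers):
            raise ValueError("grid dims must be >= 1")
        object.__setattr__(self, "layers", layers)

    @property
    def n_regions(self) -> int:
        return sum(r * c for r, c in self.layers)


def partition_regions(
    height: int, width: int, layout: PyramidLayout
) -> list[tuple[int, int, int, int]]:
    """Half-open rectangles ``(y0, y1, x0, x1)`` tiling the image per layer.

    Boundaries sit at rounded equal fractions, so within a layer the
    regions are pairwise disjoint and cover every pixel exactly once.
    Regions come in layer order, raster order within a layer.
    """
    regions = []
    for r, c in layout.layers:
        if r > height or c > width:
            raise ValueError(f"grid ({r},{c}) finer than image {height}x{width}")
        ybounds = [int(round(i * height / r)) for i in range(r + 1)]
        xbounds = [int(round(j * width / c)) for j in range(c + 1)]
        for i in range(r):
            for j in range(c):
                regions.append((ybounds[i], ybounds[i + 1], xbounds[j], xbounds[j + 1]))
    return regions


def encode_multilayer(
    gmm: GMMModel,
    descriptors: DescriptorSet,
    height: int,
    width: int,
    layout: PyramidLayout | None = None,
    encoder: str = "fv",
    normalize: bool = True,
    alpha: float = 0.5,
) -> EncodedVector:
    """Encode each pyramid region independently and concatenate.

    Descriptors belong to the region containing their keypoint center.
    Empty regions contribute an exactly-zero block.  With ``normalize``,
    fv/vlad blocks get the signed-power + L2 treatment per region and the
    concatenated vector a final global L2; bovw blocks are L1 histograms.
    """
    if encoder not in _ENCODERS:
        raise ValueError(f"unknown encoder {encoder!r}")
    if layout is None:
        layout = PyramidLayout()
    enc = _ENCODERS[encoder]
    block_len = {"fv": 2 * gmm.K * gmm.d, "vlad": gmm.K * gmm.d, "bovw": gmm.K}[encoder]
    xs, ys = descriptors.coords[:, 0], descriptors.coords[:, 1]
    blocks = []
    for y0, y1, x0, x1 in partition_regions(height, width, layout):
        inside = (ys >= y0) & (ys < y1) & (xs >= x0) & (xs < x1)
        if not inside.any():
            blocks.append(np.zeros(block_len))
            continue
        block = enc(gmm, descriptors.vectors[inside])
        if normalize and encoder in ("fv", "vlad"):
            block = normalize_fv(block, alpha=alpha)
        blocks.append(block.values)
    values = np.concatenate(blocks)
    if normalize:
        n = np.linalg.norm(values)
        if n > 0:
            values = values / n
    return EncodedVector(
        values,
        encoder,
        gmm.K,
        gmm.d,
        normalized=normalize,
        n_regions=layout.n_regions,
    )
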