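"""Enhanced standard image: frequency-band fusion of the selective pair.

The enhanced standard image recombines the soft-tissue-selective and the
bone-selective images band by band on a Laplacian pyramid: low-frequency
bands lean on the soft-tissue source (global soft-tissue contrast),
high-frequency bands on the bone source (trabecular and cortical detail).
Each pyramid level is a convex blend, so the fused image never leaves the
range spanned by the two sources.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import DualEnergyPair
from .registration import ImagePyramid, build_laplacian_pyramid, reconstruct_pyramid
from .subtraction import CancellationParams, log_subtract


@dataclass(frozen=True)
class BandWeights:
    """Per-level convex blend weights, coarse to fine.

    ``alphas[k]`` weights the soft-tissue-optimized source at pyramid level
    k (the bone source gets ``1 - alphas[k]``); the first entry is the
    low-pass residual.  Defaults put the residual fully on the soft source
    and shift toward the bone source with increasing frequency.
    """

    alphas: tuple = (1.0, 0.9, 0.7, 0.4, 0.2)

    def __post_init__(self) -> None:
        a = np.asarray(self.alphas, float)
        if (a < 0).any() or (a > 1).any():
            raise ValueError("alphas must lie in [0, 1]")

    @property
    def betas(self) -> tuple:
        return tuple(1.0 - a for a in self.alphas)

    @property
    def level_count(self) -> int:
        # pyramid levels excluding the separately-weighted residual
        return len(self.alphas) - 1


def window_level(image: np.ndarray, center: float | None = None,
                 width: float | None = None) -> np.ndarray:
    """Linear display windowing clamped to [0, 1].

    With no window given, auto mode stretches the 0.5–99.5 percentile range;
    a constant image maps to 0.5.
    """
    image = np.asarray(image, float)
    if center is None or width is None:
        lo, hi = np.percentile(image, [0.5, 99.5])
        if hi <= lo:
            return np.full_like(image, 0.5)
        center, width = (hi + lo) / 2.0, hi - lo
    if width <= 0:
        raise ValueError("window width must be positive")
    return np.clip((image - (center - width / 2.0)) / width, 0.0, 1.0)


def blend_pyramids(soft_pyr: ImagePyramid, bone_pyr: ImagePyramid,
                   weights: BandWeights) -> np.ndarray:
    """Level-wise convex blend of two pyramids, then synthesis."""
    n = soft_pyr.level_count
    if bone_pyr.level_count != n:
        raise ValueError("pyramids must share a level count")
    if len(weights.alphas) != n:
        raise ValueError(
            f"need {n} weight pairs (incl. residual), got {len(weights.alphas)}")
    # stack stores finest band first, residual last; weights run coarse→fine
    alphas = list(reversed(weights.alphas))
    blended = [a * s + (1.0 - a) * b
               for a, s, b in zip(alphas, soft_pyr.levels, bone_pyr.levels)]
    return reconstruct_pyramid(ImagePyramid(blended, soft_pyr.base_shape))


def enhanced_standard(pair: DualEnergyPair, params: CancellationParams,
                      weights: BandWeights | None = None,
                      levels: int = 4) -> np.ndarray:
    """Fuse the tissue-selective images into one enhanced standard image.

    Both sources are display-normalized first so their bands are on one
    scale, decomposed into ``levels`` pyramid bands plus the residual, blended
    per level, synthesized, and clipped to [0, 1].
    """
    weights = weights or BandWeights()
    if weights.level_count != levels:
        raise ValueError("weights do not match the requested level count")
    soft = window_level(log_subtract(pair.image_high, pair.image_low,
                                     params.w_soft))
    bone = window_level(log_subtract(pair.image_high, pair.image_low,
                                     params.w_bone))
    soft_pyr = build_laplacian_pyramid(soft, levels + 1)
    bone_pyr = build_laplacian_pyramid(bone, levels + 1)
    fused = blend_pyramids(soft_pyr, bone_pyr, weights)
    return np.clip(fused, 0.0, 1.0)
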