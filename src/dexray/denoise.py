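"""Edge-preserving wavelet-domain noise reduction.

Subtraction amplifies quantum noise, so the tissue-selective images are
denoised in an undecimated (stationary) wavelet domain: directional detail
bands are soft-thresholded while the approximation band is left untouched.
Shift invariance matters here — a decimated transform would turn the
residual subtraction artifacts into blocking patterns.  Thresholds are
attenuated near strong edges so rib borders and fissures survive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pywt
from scipy.ndimage import gaussian_filter


@dataclass(frozen=True)
class WaveletStack:
    """Undecimated 2-D wavelet coefficients.

    ``details[k]`` holds the (horizontal, vertical, diagonal) bands of
    level k, finest first; all bands share the (padded) image shape.
    """

    approx: np.ndarray
    details: list
    wavelet: str
    pad: tuple  # ((top, bottom), (left, right)) symmetric padding applied
    undecimated: bool = True

    @property
    def level_count(self) -> int:
        return len(self.details)


@dataclass(frozen=True)
class DenoiseConfig:
    """Shrinkage parameters.

    ``gamma`` in [0, 1] scales thresholds down where the local gradient is
    high (edge preservation); noise sigma is estimated as
    MAD(finest diagonal band) / 0.6745 unless given explicitly.
    """

    wavelet: str = "bior2.2"
    levels: int = 3
    rule: str = "bayes"        # 'bayes' or 'universal'
    gamma: float = 0.7
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be at least 1")
        if not (0 <= self.gamma <= 1):
            raise ValueError("gamma must lie in [0, 1]")
        if self.rule not in ("bayes", "universal"):
            raise ValueError("rule must be 'bayes' or 'universal'")


def _pad_to_multiple(image: np.ndarray, levels: int):
    mult = 2 ** levels
    h, w = image.shape
    ph = (-h) % mult
    pw = (-w) % mult
    pad = ((0, ph), (0, pw))
    if ph or pw:
        image = np.pad(image, pad, mode="symmetric")
    return image, pad


def swt_analyze(image: np.ndarray, config: DenoiseConfig) -> WaveletStack:
    """Stationary wavelet analysis with symmetric padding to a size the
    transform accepts.  Finest-level details come first in the stack."""
    image = np.asarray(image, float)
    if config.wavelet not in pywt.wavelist(kind="discrete"):
        raise ValueError(f"unknown wavelet {config.wavelet!r}")
    padded, pad = _pad_to_multiple(image, config.levels)
    coeffs = pywt.swt2(padded, config.wavelet, level=config.levels,
                       norm=False, trim_approx=True)
    # pywt orders detail tuples from coarsest to finest; store finest first
    approx = coeffs[0]
    details = [tuple(c) for c in reversed(coeffs[1:])]
    return WaveletStack(approx, details, config.wavelet, pad)


def swt_synthesize(stack: WaveletStack) -> np.ndarray:
    """Exact inverse of ``swt_analyze`` (padding removed)."""
    coeffs = [stack.approx] + [tuple(d) for d in reversed(stack.details)]
    out = pywt.iswt2(coeffs, stack.wavelet, norm=False)
    (_, pb), (_, pr) = stack.pad
    h = out.shape[0] - pb
    w = out.shape[1] - pr
    return out[:h, :w]


def _mad_sigma(stack: WaveletStack) -> float:
    """Donoho noise estimate from the finest diagonal band."""
    d = stack.details[0][2]
    return float(np.median(np.abs(d - np.median(d))) / 0.6745)


def _soft(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _band_threshold(band: np.ndarray, sigma: float, rule: str) -> float:
    if rule == "universal":
        return sigma * np.sqrt(2.0 * np.log(band.size))
    # BayesShrink: T = sigma^2 / sigma_signal
    sig_x2 = max(float(np.mean(band ** 2)) - sigma ** 2, 0.0)
    if sig_x2 <= 0:
        return float(np.max(np.abs(band)))  # band is pure noise: kill it
    return sigma ** 2 / np.sqrt(sig_x2)


def denoise_image(image: np.ndarray, config: DenoiseConfig | None = None,
                  denoiser: "Callable | None" = None) -> np.ndarray:
    """Wavelet shrinkage with edge-adaptive thresholds.

    Directional detail bands are soft-thresholded with a per-band threshold
    (universal or BayesShrink) scaled by ``(1 - gamma * edge_weight)``,
    where the edge weight is the normalized local gradient magnitude of the
    input.  The approximation band passes through unchanged, so large-scale
    anatomy is never altered.  A ``denoiser`` callable, if given, replaces
    the shrinkage entirely (pluggable back end).
    """
    cfg = config or DenoiseConfig()
    image = np.asarray(image, float)
    if (image <= 0).any():
        raise ValueError("image must be strictly positive")
    if denoiser is not None:
        return denoiser(image)

    stack = swt_analyze(image, cfg)
    sigma = cfg.sigma if cfg.sigma is not None else _mad_sigma(stack)
    if sigma <= 0:
        return image.copy()

    smooth = gaussian_filter(image, 1.5, mode="nearest")
    gy, gx = np.gradient(smooth)
    grad = np.hypot(gy, gx)
    edge_w = grad / max(float(grad.max()), 1e-30)
    edge_w, _ = _pad_to_multiple(edge_w, cfg.levels)
    atten = 1.0 - cfg.gamma * edge_w

    new_details = []
    for lvl, bands in enumerate(stack.details):
        # unnormalized SWT doubles the band gain per level, and so the
        # noise standard deviation within the band
        sigma_lvl = sigma * 2.0 ** lvl
        out_bands = []
        for band in bands:
            t = _band_threshold(band, sigma_lvl, cfg.rule)
            out_bands.append(_soft(band, t * atten))
        new_details.append(tuple(out_bands))
    shrunk = WaveletStack(stack.approx, new_details, stack.wavelet, stack.pad)
    return swt_synthesize(shrunk)
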