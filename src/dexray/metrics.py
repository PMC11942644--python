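"""Image-quality metrics used by the tests and the evaluation pipeline."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion

from .phantom import LUNG, NODULE, RIB, MaterialPhantom


def gradient_magnitude(image: np.ndarray) -> np.ndarray:
    gy, gx = np.gradient(np.asarray(image, float))
    return np.hypot(gy, gx)


def region_contrast(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean gradient magnitude over a labelled region."""
    return float(gradient_magnitude(image)[mask].mean())


def region_gradient_energy(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean squared gradient magnitude over a region."""
    return float((gradient_magnitude(image)[mask] ** 2).mean())


def edge_band(mask: np.ndarray, width: int = 3) -> np.ndarray:
    """Band of ``width`` px straddling a region's border."""
    return binary_dilation(mask, iterations=width) & ~binary_erosion(
        mask, iterations=width, border_value=1)


def rib_edge_energy(image: np.ndarray, phantom: MaterialPhantom,
                    width: int = 3) -> float:
    """Gradient energy inside a band around rib borders — the locus of
    motion artifacts in the subtracted image."""
    return region_gradient_energy(image, edge_band(phantom.mask(RIB), width))


def psnr(reference: np.ndarray, image: np.ndarray,
         data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB against a clean reference."""
    reference = np.asarray(reference, float)
    mse = float(np.mean((reference - np.asarray(image, float)) ** 2))
    if mse == 0:
        return float("inf")
    rng = data_range if data_range is not None else float(
        reference.max() - reference.min())
    return 10.0 * np.log10(rng ** 2 / mse)


def nodule_cnr(image: np.ndarray, phantom: MaterialPhantom) -> float:
    """Contrast-to-noise of the nodule insert against surrounding lung.

    The background is the surrounding lung field *including* overlying rib
    shadows: anatomical clutter is the noise that limits nodule conspicuity
    on a projection radiograph, and suppressing it is what the tissue-
    selective images are for.  The nodule ROI itself avoids overlying bone.
    """
    nod = phantom.mask(NODULE)
    if not nod.any():
        raise ValueError("phantom has no nodule insert")
    ring = binary_dilation(nod, iterations=8) & phantom.mask(LUNG, RIB)
    clear = nod & (phantom.bone_thickness < 1e-3)
    if clear.any():
        nod = clear
    bg = image[ring]
    return float(abs(image[nod].mean() - bg.mean()) / max(bg.std(), 1e-12))
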