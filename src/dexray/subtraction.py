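"""Weighted log-subtraction and cancellation-parameter selection.

The subtracted image is ``exp(log I_H - w * log I_L)``.  Under the
monochromatic two-material model, log-transmission is affine in the two
thickness maps, so the weight ``w* = mu_high / mu_low`` of a material
removes that material's contribution exactly: subtracting at bone's ratio
yields the soft-tissue-selective image and at soft tissue's ratio the
bone-selective image.  Selection of the weight is cast as deterministic
minimization of a cancellation objective over a grid, either in oracle
"residual" mode (ground-truth thickness maps available, simulation only) or
in blind "histogram" mode driven by gradient structure of the subtracted
image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .phantom import AttenuationTable, DualEnergyPair


@dataclass(frozen=True)
class CancellationParams:
    """Subtraction weights: ``w_soft`` produces the soft-tissue-selective
    image (bone cancelled), ``w_bone`` the bone-selective image (soft tissue
    cancelled).  Because bone's attenuation ratio across energies is smaller
    than soft tissue's, ``w_soft < w_bone``."""

    w_soft: float
    w_bone: float

    def __post_init__(self) -> None:
        # w = 0 is permitted as the degenerate identity (output = I_H)
        for name in ("w_soft", "w_bone"):
            v = getattr(self, name)
            if not (0 <= v < 2):
                raise ValueError(f"{name} must lie in [0, 2), got {v}")


@dataclass(frozen=True)
class SelectiveImageSet:
    """Conventional (high-energy), soft-tissue-selective and bone-selective
    images on one grid, plus the weights that produced them."""

    conventional: np.ndarray
    soft_selective: np.ndarray
    bone_selective: np.ndarray
    params: CancellationParams

    def __post_init__(self) -> None:
        shp = self.conventional.shape
        for img in (self.soft_selective, self.bone_selective):
            if img.shape != shp:
                raise ValueError("selective images must share one grid")
            if (img <= 0).any():
                raise ValueError("selective images must be strictly positive")


@dataclass(frozen=True)
class ObjectiveCurve:
    """Objective values over an ascending weight grid with the argmin weight
    (ties broken toward the smaller weight)."""

    w_grid: np.ndarray
    scores: np.ndarray
    argmin: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.w_grid) <= 0):
            raise ValueError("w_grid must be strictly ascending")


def log_subtract(image_high: np.ndarray, image_low: np.ndarray,
                 w: float) -> np.ndarray:
    """Element-wise ``exp(log I_H - w * log I_L)``; always positive."""
    if image_high.shape != image_low.shape:
        raise ValueError("images must share one shape")
    if not np.isfinite(w):
        raise ValueError("w must be finite")
    if (image_high <= 0).any() or (image_low <= 0).any():
        raise ValueError("images must be strictly positive")
    return np.exp(np.log(image_high) - w * np.log(image_low))


def analytic_cancellation_weight(atten: AttenuationTable, material: str) -> float:
    """Closed-form weight that cancels ``material`` under the monochromatic
    model: the ratio of its attenuation coefficients, mu_high / mu_low."""
    if material not in ("soft", "bone"):
        raise ValueError("material must be 'soft' or 'bone'")
    return atten.mu(material, "high") / atten.mu(material, "low")


def analytic_params(atten: AttenuationTable) -> CancellationParams:
    """Both analytic weights: cancelling bone gives w_soft, cancelling soft
    tissue gives w_bone."""
    return CancellationParams(
        w_soft=analytic_cancellation_weight(atten, "bone"),
        w_bone=analytic_cancellation_weight(atten, "soft"),
    )


def _other(material: str) -> str:
    return "bone" if material == "soft" else "soft"


def _residual_score(pair: DualEnergyPair, w: float, material: str,
                    target_mask: np.ndarray | None) -> float:
    """Oracle objective: variance of the log-subtracted image within the
    cancelled material's true footprint, after removing the component
    explained (linearly) by the other material's ground-truth thickness.
    Zero exactly when the material is fully cancelled."""
    ph = pair.phantom
    if ph is None and target_mask is None:
        raise ValueError("residual mode needs a phantom or an explicit mask")
    thick = {"soft": None, "bone": None}
    if ph is not None:
        thick = {"soft": ph.soft_thickness, "bone": ph.bone_thickness}
    mask = target_mask
    if mask is None:
        mask = thick[material] > 1e-6
    if not mask.any():
        raise ValueError("residual mode mask is empty")
    if pair.noise_budget is not None:
        # photon-starved pixels carry log-noise far beyond the quadratic
        # approximation; keep only pixels with adequate expected counts
        # (an absolute floor, tightened proportionally at high budgets)
        thr = max(50.0, 0.02 * pair.noise_budget)
        ok = (pair.image_high * pair.noise_budget >= thr) \
            & (pair.image_low * pair.noise_budget >= thr)
        if (mask & ok).any():
            mask = mask & ok
    logs = (np.log(pair.image_high) - w * np.log(pair.image_low))[mask]
    cov = thick[_other(material)]
    if cov is not None:
        x = cov[mask]
        design = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(design, logs, rcond=None)
        logs = logs - design @ coef
    score = float(np.var(logs))
    # Poisson counting noise inflates Var(log I) by ~1/(N*I) per image and
    # the low-energy term scales with w^2, which would bias the argmin
    # downward; subtract the plug-in estimate of that contribution
    if pair.noise_budget is not None:
        n = pair.noise_budget
        noise = np.mean(1.0 / (n * pair.image_high[mask])
                        + w ** 2 / (n * pair.image_low[mask]))
        score -= float(noise)
    return score


def _edge_footprints(pair: DualEnergyPair):
    """Blind per-material edge footprints from the local gradient ratio.

    At an edge produced by a single material, grad(log I_H) / grad(log I_L)
    equals that material's attenuation ratio, i.e. its cancellation weight.
    Edge pixels are split by a two-means clustering of this local ratio:
    the low-ratio cluster is attributed to bone, the high-ratio cluster to
    soft tissue.
    """
    from scipy.ndimage import binary_erosion

    log_h = gaussian_filter(np.log(pair.image_high), 1.0)
    log_l = gaussian_filter(np.log(pair.image_low), 1.0)
    ghy, ghx = np.gradient(log_h)
    gly, glx = np.gradient(log_l)
    mag2 = gly ** 2 + glx ** 2
    # restrict to the body interior: the skin outline is the strongest edge
    # in the frame and carries no cancellation information
    body = pair.image_high < 0.95 * float(pair.image_high.max())
    body = binary_erosion(body, iterations=5, border_value=1)
    edges = body & (mag2 > np.quantile(mag2[body], 0.90))
    ratio = np.where(mag2 > 0, (ghy * gly + ghx * glx) / np.maximum(mag2, 1e-30), 0.0)
    r = ratio[edges]
    # pure single-material edges sit at the extremes of the ratio
    # distribution (mixing always produces intermediate ratios), so the
    # cluster centers are anchored at extreme quantiles, and only pixels
    # close to a center are kept — mixed pixels carry no clean signal
    c_lo, c_hi = np.quantile(r, 0.02), np.quantile(r, 0.98)
    tol = max(0.03, 0.10 * (c_hi - c_lo))
    bone_fp = np.zeros_like(edges)
    soft_fp = np.zeros_like(edges)
    bone_fp[edges] = np.abs(ratio[edges] - c_lo) <= tol
    soft_fp[edges] = np.abs(ratio[edges] - c_hi) <= tol
    return {"bone": bone_fp, "soft": soft_fp}


def _histogram_score(pair: DualEnergyPair, w: float, material: str,
                     footprint: np.ndarray) -> float:
    """Blind objective: gradient-magnitude energy of the subtracted image on
    the cancelled material's footprint proxy, plus a small histogram-
    dispersion (IQR) penalty.  Lower is better."""
    logs = np.log(pair.image_high) - w * np.log(pair.image_low)
    gy, gx = np.gradient(gaussian_filter(logs, 1.0))
    energy = float(np.mean((gy ** 2 + gx ** 2)[footprint]))
    q75, q25 = np.percentile(logs[footprint], [75, 25])
    return energy + 0.005 * float(q75 - q25) ** 2


def cancellation_objective(pair: DualEnergyPair, w: float,
                           mode: str = "histogram", material: str = "bone",
                           target_mask: np.ndarray | None = None) -> float:
    """Score a cancellation weight for removing ``material``; lower is better.

    ``residual`` mode is the simulation oracle (requires ground truth);
    ``histogram`` mode is blind and data-driven.
    """
    if material not in ("soft", "bone"):
        raise ValueError("material must be 'soft' or 'bone'")
    if mode == "residual":
        return _residual_score(pair, w, material, target_mask)
    if mode == "histogram":
        fp = target_mask if target_mask is not None else _edge_footprints(pair)[material]
        return _histogram_score(pair, w, material, fp)
    raise ValueError(f"unknown mode {mode!r}")


def optimize_cancellation(pair: DualEnergyPair, mode: str = "histogram",
                          material: str = "bone",
                          w_min: float = 0.05, w_max: float = 1.50,
                          step: float = 0.005,
                          target_mask: np.ndarray | None = None) -> ObjectiveCurve:
    """Exhaustive grid search of the cancellation objective.

    Deterministic; ties are broken toward the smaller weight (argmin takes
    the first minimizing grid point).
    """
    if not (w_min < w_max) or step <= 0:
        raise ValueError("need w_min < w_max and step > 0")
    grid = np.arange(w_min, w_max + step / 2, step)
    if grid.size == 0:
        raise ValueError("empty weight grid")
    if mode == "histogram" and target_mask is None:
        footprint = _edge_footprints(pair)[material]
        scores = np.array([_histogram_score(pair, w, material, footprint)
                           for w in grid])
    else:
        scores = np.array([cancellation_objective(pair, w, mode, material,
                                                  target_mask)
                           for w in grid])
    return ObjectiveCurve(grid, scores, float(grid[int(np.argmin(scores))]))


def make_selective_set(pair: DualEnergyPair,
                       params: CancellationParams) -> SelectiveImageSet:
    """Build the three-image set: conventional = I_H, plus the two
    subtracted tissue-selective images."""
    return SelectiveImageSet(
        conventional=np.asarray(pair.image_high, float),
        soft_selective=log_subtract(pair.image_high, pair.image_low, params.w_soft),
        bone_selective=log_subtract(pair.image_high, pair.image_low, params.w_bone),
        params=params,
    )
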