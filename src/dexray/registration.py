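"""Multi-resolution diffeomorphic registration of the exposure pair.

Inter-exposure motion (breathing, cardiac) misaligns the low-energy frame
with the high-energy frame and turns into bright/dark edge artifacts after
subtraction.  This module estimates a dense displacement field with
log-domain demons run coarse-to-fine over a Laplacian-pyramid scaffold.
The velocity field is exponentiated by scaling-and-squaring, which keeps
the mapping diffeomorphic (positive Jacobian determinant).  Because the two
exposures differ in contrast, the demons force is computed on locally
standardized images, never on raw intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter, zoom

from ._warp import compose_fields, warp_image


@dataclass(frozen=True)
class ImagePyramid:
    """Laplacian band-pass stack, finest band first, low-pass residual last."""

    levels: list
    base_shape: tuple

    @property
    def level_count(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class DisplacementField:
    """Dense per-pixel motion in (row, column) pixel units."""

    dy: np.ndarray
    dx: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        if self.dy.shape != self.dx.shape:
            raise ValueError("dy and dx must share one shape")
        if not (np.isfinite(self.dy).all() and np.isfinite(self.dx).all()):
            raise ValueError("displacement field must be finite")

    @property
    def shape(self) -> tuple:
        return self.dy.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dy, self.dx)


@dataclass(frozen=True)
class RegistrationConfig:
    level_count: int = 3
    iterations: int = 50
    sigma_fluid: float = 2.0      # px, smoothing of each demons update
    sigma_elastic: float = 1.5    # px, smoothing of the velocity field
    squaring_steps: int = 6       # minimum scaling-and-squaring steps
    tolerance: float = 1e-3       # mean update magnitude, px
    standardize_window: int = 15  # px, local standardization window

    def __post_init__(self) -> None:
        if self.squaring_steps < 4:
            raise ValueError("squaring_steps must be at least 4")
        for name in ("level_count", "iterations", "sigma_fluid",
                     "sigma_elastic", "tolerance", "standardize_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------- pyramid

def _downsample(img: np.ndarray) -> np.ndarray:
    return gaussian_filter(img, 1.0, mode="nearest")[::2, ::2]


def _upsample(img: np.ndarray, shape: tuple) -> np.ndarray:
    factors = (shape[0] / img.shape[0], shape[1] / img.shape[1])
    return zoom(img, factors, order=3, mode="nearest", grid_mode=True)


def build_laplacian_pyramid(image: np.ndarray, level_count: int) -> ImagePyramid:
    """Gaussian blur/downsample analysis with band-pass residuals.

    Level k holds the detail lost between Gaussian levels k and k+1; the
    final level is the coarsest low-pass image.  ``reconstruct_pyramid`` is
    the exact synthesis inverse.
    """
    image = np.asarray(image, float)
    if level_count < 1:
        raise ValueError("level_count must be at least 1")
    if min(image.shape) < 2 ** (level_count - 1):
        raise ValueError("image too small for the requested level count")
    levels = []
    g = image
    for _ in range(level_count - 1):
        down = _downsample(g)
        levels.append(g - _upsample(down, g.shape))
        g = down
    levels.append(g)
    return ImagePyramid(levels, image.shape)


def reconstruct_pyramid(pyr: ImagePyramid) -> np.ndarray:
    """Exact synthesis: successively upsample and add the detail bands."""
    g = pyr.levels[-1]
    for band in reversed(pyr.levels[:-1]):
        g = band + _upsample(g, band.shape)
    return g


# ----------------------------------------------------------- registration

def _local_standardize(img: np.ndarray, window: int) -> np.ndarray:
    """Zero-mean unit-variance in a sliding window; removes the cross-energy
    contrast difference so it cannot masquerade as motion."""
    mean = uniform_filter(img, window, mode="nearest")
    var = uniform_filter(img ** 2, window, mode="nearest") - mean ** 2
    return (img - mean) / np.sqrt(np.maximum(var, 1e-12))


def exponentiate_velocity(vy: np.ndarray, vx: np.ndarray,
                          min_steps: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """Scaling-and-squaring exponential of a stationary velocity field.

    The field is scaled down until its largest vector is below 0.5 px, then
    repeatedly composed with itself, which keeps the result invertible.
    """
    max_mag = float(np.max(np.hypot(vy, vx)))
    steps = min_steps
    if max_mag > 0:
        steps = max(min_steps, int(np.ceil(np.log2(max(max_mag / 0.5, 1.0)))))
    dy = vy / (2.0 ** steps)
    dx = vx / (2.0 ** steps)
    for _ in range(steps):
        dy, dx = compose_fields(dy, dx, dy, dx)
    return dy, dx


def _demons_update(fixed: np.ndarray, warped: np.ndarray) -> tuple:
    """Thirion demons force with the standard normalization."""
    diff = fixed - warped
    gy, gx = np.gradient(warped)
    g2 = gy ** 2 + gx ** 2
    denom = g2 + diff ** 2
    scale = np.where(denom > 1e-9, diff / np.maximum(denom, 1e-9), 0.0)
    return scale * gy, scale * gx


def register_diffeomorphic(fixed: np.ndarray, moving: np.ndarray,
                           config: RegistrationConfig | None = None
                           ) -> DisplacementField:
    """Estimate the field that maps ``moving`` onto ``fixed``.

    Log-domain demons over a coarse-to-fine pyramid of locally standardized
    images; the returned displacement is the exponential of the accumulated
    velocity, so its Jacobian determinant is positive everywhere.  If the
    iteration budget runs out before the mean update magnitude drops below
    tolerance, the best field found is returned with ``converged=False``.
    """
    cfg = config or RegistrationConfig()
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must share one shape")
    f = _local_standardize(np.log(np.maximum(np.asarray(fixed, float), 1e-12)),
                           cfg.standardize_window)
    m = _local_standardize(np.log(np.maximum(np.asarray(moving, float), 1e-12)),
                           cfg.standardize_window)

    # Gaussian pyramids (coarse last) shared with the Laplacian scaffold
    f_levels, m_levels = [f], [m]
    for _ in range(cfg.level_count - 1):
        if min(f_levels[-1].shape) < 16:
            break
        f_levels.append(_downsample(f_levels[-1]))
        m_levels.append(_downsample(m_levels[-1]))

    vy = np.zeros_like(f_levels[-1])
    vx = np.zeros_like(f_levels[-1])
    converged = True
    for f_lv, m_lv in zip(reversed(f_levels), reversed(m_levels)):
        if vy.shape != f_lv.shape:
            sy = f_lv.shape[0] / vy.shape[0]
            sx = f_lv.shape[1] / vy.shape[1]
            vy = _upsample(vy, f_lv.shape) * sy
            vx = _upsample(vx, f_lv.shape) * sx
        level_ok = False
        for _ in range(cfg.iterations):
            dy, dx = exponentiate_velocity(vy, vx, cfg.squaring_steps)
            warped = warp_image(m_lv, np.stack([dy, dx]))
            uy, ux = _demons_update(f_lv, warped)
            uy = gaussian_filter(uy, cfg.sigma_fluid, mode="nearest")
            ux = gaussian_filter(ux, cfg.sigma_fluid, mode="nearest")
            vy = gaussian_filter(vy + uy, cfg.sigma_elastic, mode="nearest")
            vx = gaussian_filter(vx + ux, cfg.sigma_elastic, mode="nearest")
            if float(np.mean(np.hypot(uy, ux))) < cfg.tolerance:
                level_ok = True
                break
        converged = converged and level_ok

    dy, dx = exponentiate_velocity(vy, vx, cfg.squaring_steps)
    return DisplacementField(dy, dx, converged=converged)


def warp(image: np.ndarray, disp) -> np.ndarray:
    """Resample an image along a displacement field; shared with the
    phantom module's ``apply_motion``."""
    return warp_image(image, disp)


def jacobian_determinant(disp) -> np.ndarray:
    """Jacobian determinant of (identity + field) at interior pixels."""
    if hasattr(disp, "dy"):
        dy, dx = disp.dy, disp.dx
    else:
        dy, dx = disp[0], disp[1]
    dyy, dyx = np.gradient(dy)
    dxy, dxx = np.gradient(dx)
    return (1.0 + dyy) * (1.0 + dxx) - dyx * dxy
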