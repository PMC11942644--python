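"""Shared displacement-field resampling used by simulation and registration."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates


def _field_arrays(disp) -> tuple[np.ndarray, np.ndarray]:
    """Accept a DisplacementField-like object or a (2, H, W) / (H, W, 2) array."""
    if hasattr(disp, "dy") and hasattr(disp, "dx"):
        return np.asarray(disp.dy, float), np.asarray(disp.dx, float)
    arr = np.asarray(disp, float)
    if arr.ndim == 3 and arr.shape[0] == 2:
        return arr[0], arr[1]
    if arr.ndim == 3 and arr.shape[-1] == 2:
        return arr[..., 0], arr[..., 1]
    raise ValueError("displacement must have a (2, H, W) or (H, W, 2) layout")


def warp_image(image: np.ndarray, disp) -> np.ndarray:
    """Pull-back resampling: out(p) = in(p + d(p)).

    Bilinear interpolation, edge-replicated borders.  Displacements are in
    (row, column) pixel units on the 0-based, row-major grid.
    """
    dy, dx = _field_arrays(disp)
    image = np.asarray(image, float)
    if dy.shape != image.shape or dx.shape != image.shape:
        raise ValueError("displacement field shape must match image shape")
    if not (np.isfinite(dy).all() and np.isfinite(dx).all()):
        raise ValueError("displacement field must be finite")
    rr, cc = np.mgrid[0:image.shape[0], 0:image.shape[1]].astype(float)
    return map_coordinates(image, [rr + dy, cc + dx], order=1, mode="nearest")


def compose_fields(outer_dy, outer_dx, inner_dy, inner_dx):
    """Compose two displacement fields: result(p) = inner(p) + outer(p + inner(p))."""
    rr, cc = np.mgrid[0:inner_dy.shape[0], 0:inner_dy.shape[1]].astype(float)
    coords = [rr + inner_dy, cc + inner_dx]
    oy = map_coordinates(outer_dy, coords, order=1, mode="nearest")
    ox = map_coordinates(outer_dx, coords, order=1, mode="nearest")
    return inner_dy + oy, inner_dx + ox
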