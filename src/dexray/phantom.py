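"""Parametric two-material chest phantom and paired-exposure simulation.

The phantom is a 2-D projection model: every pixel carries an equivalent
thickness (cm) of soft tissue and of bone, plus a categorical anatomy label.
Paired low/high-energy exposures are simulated with a monochromatic
Beer-Lambert forward model at the effective energy of each beam, optional
inter-exposure motion, Poisson counting noise, automatic exposure control,
and entrance-surface-dose accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from ._warp import warp_image

# anatomy label codes
BACKGROUND = 0
LUNG = 1
MEDIASTINUM = 2
RIB = 3
SPINE = 4
CLAVICLE = 5
SCAPULA = 6
NODULE = 7

LABEL_NAMES = {
    BACKGROUND: "background",
    LUNG: "lung",
    MEDIASTINUM: "mediastinum",
    RIB: "rib",
    SPINE: "spine",
    CLAVICLE: "clavicle",
    SCAPULA: "scapula",
    NODULE: "nodule",
}

BONE_LABELS = (RIB, SPINE, CLAVICLE, SCAPULA)

#: detector signals are floored at this fraction of dynamic range before any
#: logarithm, so log-subtraction never sees a zero
SIGNAL_FLOOR = 1e-6


@dataclass(frozen=True)
class MaterialPhantom:
    """Ground-truth projected thickness maps for a two-material chest.

    Attributes
    ----------
    soft_thickness, bone_thickness : ndarray
        Per-pixel equivalent material thickness in cm; same shape.
    pixel_pitch : float
        Detector pixel pitch in mm.
    anatomy_labels : ndarray of int
        Per-pixel categorical map using the module label codes.
    """

    soft_thickness: np.ndarray
    bone_thickness: np.ndarray
    pixel_pitch: float
    anatomy_labels: np.ndarray

    def __post_init__(self) -> None:
        s, b = self.soft_thickness, self.bone_thickness
        if s.shape != b.shape or s.shape != self.anatomy_labels.shape:
            raise ValueError("thickness and label maps must share one shape")
        if not (np.isfinite(s).all() and np.isfinite(b).all()):
            raise ValueError("thickness maps must be finite")
        if (s < 0).any() or (b < 0).any():
            raise ValueError("thickness maps must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.soft_thickness.shape

    def mask(self, *labels: int) -> np.ndarray:
        return np.isin(self.anatomy_labels, labels)


@dataclass(frozen=True)
class AttenuationTable:
    """Linear attenuation coefficients (cm^-1) at the two effective energies.

    ``low`` refers to the 60 kVp beam, ``high`` to the 120 kVp beam.  Bone
    attenuates more and its coefficient falls faster with energy than soft
    tissue's (photoelectric dominance), so mu_bone_high / mu_bone_low <
    mu_soft_high / mu_soft_low — this ratio ordering is what makes the two
    cancellation weights distinct.
    """

    mu_soft_low: float = 0.25
    mu_soft_high: float = 0.18
    mu_bone_low: float = 0.90
    mu_bone_high: float = 0.40

    def __post_init__(self) -> None:
        vals = (self.mu_soft_low, self.mu_soft_high,
                self.mu_bone_low, self.mu_bone_high)
        if any(v <= 0 for v in vals):
            raise ValueError("attenuation coefficients must be positive")
        if not (self.mu_bone_low > self.mu_bone_high
                and self.mu_soft_low > self.mu_soft_high):
            raise ValueError("coefficients must decrease with beam energy")
        if not (self.mu_bone_high / self.mu_bone_low
                < self.mu_soft_high / self.mu_soft_low):
            raise ValueError("bone must harden faster than soft tissue")

    def mu(self, material: str, beam: str) -> float:
        return getattr(self, f"mu_{material}_{beam}")


@dataclass(frozen=True)
class AcquisitionSettings:
    """Paired-exposure acquisition parameters.

    Defaults reproduce the clinical protocol: 60/120 kVp, fixed tube
    currents of 250/200 mA, a 150 ms inter-exposure interval and a 180 cm
    source-to-image distance.
    """

    kvp_low: float = 60.0
    kvp_high: float = 120.0
    ma_low: float = 250.0
    ma_high: float = 200.0
    exposure_time_low: float = 10.0   # ms
    exposure_time_high: float = 8.0   # ms
    interval: float = 150.0           # ms between exposures
    sid: float = 180.0                # cm
    photon_budget: float = 1e4        # expected photons/pixel at zero thickness
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("kvp_low", "kvp_high", "ma_low", "ma_high",
                     "exposure_time_low", "exposure_time_high",
                     "interval", "sid", "photon_budget"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def mas_low(self) -> float:
        return self.ma_low * self.exposure_time_low / 1000.0

    @property
    def mas_high(self) -> float:
        return self.ma_high * self.exposure_time_high / 1000.0


@dataclass(frozen=True)
class DualEnergyPair:
    """A co-registered low/high-energy exposure pair.

    ``image_low`` and ``image_high`` are normalized detector signals in
    (0, 1] before noise; both are clamped to a strictly positive floor so
    logarithms are always defined.  ``true_motion`` records the displacement
    applied between the exposures when the pair was simulated; ``phantom``
    keeps the ground-truth thickness maps for oracle-mode objectives.
    """

    image_low: np.ndarray
    image_high: np.ndarray
    settings: AcquisitionSettings = field(default_factory=AcquisitionSettings)
    true_motion: "np.ndarray | None" = None
    phantom: MaterialPhantom | None = None
    noise_budget: float | None = None  # photons/pixel if Poisson noise applied

    def __post_init__(self) -> None:
        if self.image_low.shape != self.image_high.shape:
            raise ValueError("low/high images must share one shape")
        if (self.image_low <= 0).any() or (self.image_high <= 0).any():
            raise ValueError("pair images must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image_high.shape


@dataclass(frozen=True)
class PhantomConfig:
    """Geometric and thickness parameters of the chest phantom (cm unless noted)."""

    torso_soft_thickness: float = 20.0
    lung_soft_thickness: float = 7.0
    mediastinum_extra: float = 4.0
    rib_thickness: float = 0.8
    rib_count: int = 7
    rib_width_frac: float = 0.035     # rib band width, fraction of height
    rib_slope: float = 0.18           # vertical drop per unit column (oblique ribs)
    spine_thickness: float = 3.0
    spine_width_frac: float = 0.08
    clavicle_thickness: float = 1.0
    scapula_thickness: float = 0.5
    nodule_diameter_frac: float = 0.06
    nodule_extra_soft: float = 1.5
    nodule_centers: tuple = ((0.38, 0.30),)  # (row_frac, col_frac); () for none
    include_scapulae: bool = True
    mirror: bool = False
    edge_softness_px: float = 2.0     # gaussian taper of soft-tissue borders
    lung_softness_px: float = 3.0     # taper of the projected lung border
    bone_softness_px: float = 1.0     # cortical bone edges stay sharp
    pixel_pitch: float = 0.14         # mm


def _ellipse(shape, center, semi_axes):
    """Smooth-edged ellipse indicator via squared normalized radius."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    r2 = (((rr - center[0] * h) / (semi_axes[0] * h)) ** 2
          + ((cc - center[1] * w) / (semi_axes[1] * w)) ** 2)
    return r2 <= 1.0


def _soften(mask: np.ndarray, sigma: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter
    if sigma <= 0:
        return mask.astype(float)
    return gaussian_filter(mask.astype(float), sigma)


def build_chest_phantom(width: int, height: int,
                        config: PhantomConfig | None = None) -> MaterialPhantom:
    """Build a deterministic parametric chest phantom.

    The phantom contains a soft-tissue torso ellipse, two lung fields of
    reduced soft thickness, oblique periodic rib bands, a vertical spine
    column, clavicles, optional scapular shadows and optional soft-tissue
    nodule inserts.  Identical configs yield identical phantoms.
    """
    if width < 64 or height < 64:
        raise ValueError("phantom dimensions must be at least 64 px")
    cfg = config or PhantomConfig()

    shape = (height, width)
    soft = np.zeros(shape)
    bone = np.zeros(shape)
    labels = np.full(shape, BACKGROUND, dtype=np.int8)

    torso = _ellipse(shape, (0.52, 0.5), (0.46, 0.42))
    soft += cfg.torso_soft_thickness * _soften(torso, cfg.edge_softness_px)
    labels[torso] = MEDIASTINUM

    # mediastinum is wider than the spine column, so inner lung borders do
    # not touch the spine edges
    lungs = np.zeros(shape, bool)
    for side in (-1, 1):
        lung = _ellipse(shape, (0.45, 0.5 + side * 0.20), (0.30, 0.14))
        lungs |= lung
    # lungs replace most of the torso thickness with air-filled parenchyma
    soft -= ((cfg.torso_soft_thickness - cfg.lung_soft_thickness)
             * _soften(lungs, cfg.lung_softness_px))
    labels[lungs] = LUNG

    # mediastinum: thicker central column between the lungs
    medi = _ellipse(shape, (0.55, 0.5), (0.32, 0.09)) & ~lungs & torso
    soft += cfg.mediastinum_extra * _soften(medi, cfg.edge_softness_px)

    # nodules: extra soft tissue inside the lung fields
    for rf, cf in cfg.nodule_centers:
        nod = _ellipse(shape, (rf, cf),
                       (cfg.nodule_diameter_frac / 2, cfg.nodule_diameter_frac / 2))
        nod &= lungs
        soft += cfg.nodule_extra_soft * _soften(nod, cfg.edge_softness_px)
        labels[nod] = NODULE

    # oblique rib bands across the lung fields and lateral torso
    rr, cc = np.mgrid[0:height, 0:width].astype(float)
    band_period = 0.82 * height / max(cfg.rib_count, 1)
    half_w = cfg.rib_width_frac * height / 2
    # oblique coordinate: ribs droop toward the lateral edges
    obl = rr + cfg.rib_slope * np.abs(cc - 0.5 * width)
    phase = np.mod(obl - 0.12 * height, band_period)
    in_band = np.minimum(phase, band_period - phase) <= half_w
    rib_region = in_band & torso & (rr > 0.10 * height) & (rr < 0.80 * height)
    rib_region &= np.abs(cc - 0.5 * width) > cfg.spine_width_frac * width / 2
    rib_profile = _soften(rib_region, cfg.bone_softness_px)
    bone += cfg.rib_thickness * rib_profile
    # rib labels mark ribs overlying flat lung parenchyma (the region used
    # for rib-conspicuity metrics), clear of the lung-border taper
    from scipy.ndimage import binary_erosion
    lung_interior = binary_erosion(lungs, iterations=int(3 * cfg.lung_softness_px))
    labels[rib_region & lung_interior & (labels != NODULE)] = RIB

    # spine: vertical column behind the mediastinum
    spine = (np.abs(cc - 0.5 * width) <= cfg.spine_width_frac * width / 2) & torso
    bone += cfg.spine_thickness * _soften(spine, cfg.bone_softness_px)
    labels[spine] = SPINE

    # clavicles: near-horizontal bands high in the thorax
    for sign in (-1, 1):
        clav_c = rr - (0.13 * height + 0.10 * sign * (cc - 0.5 * width))
        clav = (np.abs(clav_c) <= 0.015 * height) & torso
        clav &= (cc - 0.5 * width) * sign > 0.03 * width
        bone += cfg.clavicle_thickness * _soften(clav, cfg.bone_softness_px)
        labels[clav] = CLAVICLE

    if cfg.include_scapulae:
        for sign in (-1, 1):
            scap = _ellipse(shape, (0.33, 0.5 + sign * 0.40), (0.17, 0.05)) & torso
            bone += cfg.scapula_thickness * _soften(scap, cfg.bone_softness_px)
            labels[scap & ~np.isin(labels, (RIB, CLAVICLE))] = SCAPULA

    soft = np.clip(soft, 0.0, None)
    bone = np.clip(bone, 0.0, None)
    # labelled bone must carry bone thickness even after tapering
    bone_lbl = np.isin(labels, BONE_LABELS)
    bone[bone_lbl] = np.maximum(bone[bone_lbl], 1e-3)

    if cfg.mirror:
        soft, bone, labels = soft[:, ::-1], bone[:, ::-1], labels[:, ::-1]

    return MaterialPhantom(soft, bone, cfg.pixel_pitch, labels)


def simulate_transmission(phantom: MaterialPhantom, atten: AttenuationTable,
                          beam: str) -> np.ndarray:
    """Monochromatic Beer-Lambert transmission for one beam.

    Per pixel ``I = exp(-mu_soft * t_soft - mu_bone * t_bone)``; the result
    lies in (0, 1] and log(I) is exactly affine in the two thickness maps.
    """
    if beam not in ("low", "high"):
        raise ValueError(f"beam must be 'low' or 'high', got {beam!r}")
    mu_s = atten.mu("soft", beam)
    mu_b = atten.mu("bone", beam)
    return np.exp(-mu_s * phantom.soft_thickness - mu_b * phantom.bone_thickness)


def apply_motion(image: np.ndarray, disp) -> np.ndarray:
    """Resample an image along a displacement field (bilinear, edge-replicated).

    Shares one implementation with the registration module's ``warp``.
    """
    return warp_image(image, disp)


def add_noise(image: np.ndarray, photon_budget: float,
              seed: "int | np.random.Generator") -> np.ndarray:
    """Poisson counting noise: counts ~ Poisson(budget * I), renormalized.

    The output is floored at ``SIGNAL_FLOOR`` so downstream logarithms are
    always defined.
    """
    if photon_budget <= 0:
        raise ValueError("photon_budget must be positive")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(photon_budget * image)
    return np.maximum(counts / photon_budget, SIGNAL_FLOOR)


def simulate_pair(phantom: MaterialPhantom,
                  atten: AttenuationTable | None = None,
                  settings: AcquisitionSettings | None = None,
                  motion=None,
                  noisy: bool = True) -> DualEnergyPair:
    """Simulate a full dual-energy pair: transmission, motion, noise.

    The high-energy exposure is the fixed frame; inter-exposure motion is
    applied to the low-energy exposure.  With ``noisy=False`` the pair
    satisfies the two-material log-linear model exactly.
    """
    atten = atten or AttenuationTable()
    settings = settings or AcquisitionSettings()
    i_low = simulate_transmission(phantom, atten, "low")
    i_high = simulate_transmission(phantom, atten, "high")
    if motion is not None:
        i_low = apply_motion(i_low, motion)
    if noisy:
        low_rng, high_rng = np.random.default_rng(settings.seed).spawn(2)
        i_low = add_noise(i_low, settings.photon_budget, low_rng)
        i_high = add_noise(i_high, settings.photon_budget, high_rng)
    i_low = np.maximum(i_low, SIGNAL_FLOOR)
    i_high = np.maximum(i_high, SIGNAL_FLOOR)
    return DualEnergyPair(i_low, i_high, settings,
                          true_motion=motion, phantom=phantom,
                          noise_budget=settings.photon_budget if noisy else None)


def random_smooth_motion(shape: tuple, amplitude: float, seed,
                         sigma: float = 20.0,
                         bulk_fraction: float = 0.7) -> np.ndarray:
    """Random inter-exposure motion field, (2, H, W), max magnitude
    ``amplitude`` px.

    Breathing/cardiac motion between the two exposures is modelled as a
    bulk chest translation (``bulk_fraction`` of the amplitude, random
    direction) plus a smooth low-frequency residual deformation.
    """
    from scipy.ndimage import gaussian_filter
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi)
    field = gaussian_filter(rng.standard_normal((2, *shape)),
                            (0, sigma, sigma), mode="nearest")
    mag = np.hypot(field[0], field[1]).max()
    if mag > 0:
        field *= (1.0 - bulk_fraction) * amplitude / mag
    field[0] += bulk_fraction * amplitude * np.sin(theta)
    field[1] += bulk_fraction * amplitude * np.cos(theta)
    return field


def auto_exposure(phantom: MaterialPhantom, atten: AttenuationTable,
                  settings: AcquisitionSettings,
                  target_signal: float, tol: float = 0.01) -> AcquisitionSettings:
    """Scale exposure times so the median lung signal hits the target.

    Emulates automatic exposure control: the detector signal is modelled as
    transmission scaled linearly by exposure time relative to the incoming
    settings, and each beam's time is solved for by bisection on the median
    signal over the lung-labelled region (1% tolerance).  Settings already
    within tolerance are returned unchanged.
    """
    if not (0 < target_signal < 1):
        raise ValueError("target_signal must lie in (0, 1)")
    lung = phantom.mask(LUNG, NODULE)
    if not lung.any():
        raise ValueError("phantom has no lung-labelled pixels")

    # detector gain normalized so the default technique maps transmission
    # directly to signal; signal then scales linearly with mAs
    ref = AcquisitionSettings()
    rel_mas = {"low": settings.mas_low / ref.mas_low,
               "high": settings.mas_high / ref.mas_high}
    scales = {}
    for beam in ("low", "high"):
        med = float(np.median(simulate_transmission(phantom, atten, beam)[lung]))
        med *= rel_mas[beam]
        if abs(med - target_signal) <= tol * target_signal:
            scales[beam] = 1.0
            continue
        lo, hi = 1e-9, 1e9
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if mid * med < target_signal:
                lo = mid
            else:
                hi = mid
            if abs(mid * med - target_signal) <= tol * target_signal:
                break
        scales[beam] = mid
    if scales["low"] == 1.0 and scales["high"] == 1.0:
        return settings
    return replace(settings,
                   exposure_time_low=settings.exposure_time_low * scales["low"],
                   exposure_time_high=settings.exposure_time_high * scales["high"])


@dataclass(frozen=True)
class EsdResult:
    """Entrance surface dose per exposure and total, mGy."""

    esd_low: float
    esd_high: float

    @property
    def total(self) -> float:
        return self.esd_low + self.esd_high


def estimate_esd(settings: AcquisitionSettings,
                 calibration: "Mapping[float, float] | Callable[[float], float]",
                 backscatter_factor: float = 1.35,
                 focus_skin_distance: float | None = None) -> EsdResult:
    """Entrance surface dose from exposure parameters.

    ESD = tube output (uGy per mAs at 1 m, from ``calibration`` keyed or
    called by kVp) x mAs x inverse-square distance correction x backscatter
    factor, converted to mGy.  The focus-skin distance defaults to the SID
    minus a 20 cm patient thickness.
    """
    fsd = focus_skin_distance if focus_skin_distance is not None else settings.sid - 20.0
    if fsd <= 0:
        raise ValueError("focus-skin distance must be positive")

    def output(kvp: float) -> float:
        out = calibration(kvp) if callable(calibration) else calibration[kvp]
        if out <= 0:
            raise ValueError("calibration output must be positive")
        return out

    def one(kvp: float, mas: float) -> float:
        return output(kvp) * mas * (100.0 / fsd) ** 2 * backscatter_factor / 1000.0

    return EsdResult(one(settings.kvp_low, settings.mas_low),
                     one(settings.kvp_high, settings.mas_high))
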