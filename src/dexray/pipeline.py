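"""End-to-end orchestration: simulate → register → denoise → subtract → enhance.

A single seed drives all stochastic stages through named substreams, so a
run is bit-reproducible from its config alone; every run writes a manifest
(config hash, seed, package versions, per-stage timings, output hashes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .denoise import DenoiseConfig, denoise_image
from .enhance import BandWeights, enhanced_standard, window_level
from .io import write_image
from .phantom import (AcquisitionSettings, AttenuationTable, PhantomConfig,
                      apply_motion, build_chest_phantom, random_smooth_motion,
                      simulate_pair)
from .registration import RegistrationConfig, register_diffeomorphic
from .subtraction import (CancellationParams, SelectiveImageSet,
                          analytic_params, make_selective_set,
                          optimize_cancellation)


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline parameterization with lossless YAML round-tripping."""

    width: int = 256
    height: int = 256
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    atten: AttenuationTable = field(default_factory=AttenuationTable)
    settings: AcquisitionSettings = field(default_factory=AcquisitionSettings)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    band_alphas: tuple = (1.0, 0.9, 0.7, 0.4, 0.2)
    motion_amplitude: float = 2.0   # px of simulated inter-exposure motion
    noisy: bool = True
    do_register: bool = True
    do_denoise: bool = True
    weight_mode: str = "residual"   # 'analytic' | 'residual' | 'histogram'
    seed: int = 0
    verbosity: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj
        return yaml.safe_dump(clean(self.to_dict()), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)

        def tup(x):
            return tuple(tuple(i) if isinstance(i, list) else i for i in x)

        if "phantom" in d:
            ph = dict(d["phantom"])
            if "nodule_centers" in ph:
                ph["nodule_centers"] = tup(ph["nodule_centers"])
            d["phantom"] = PhantomConfig(**ph)
        for key, typ in (("atten", AttenuationTable),
                         ("settings", AcquisitionSettings),
                         ("registration", RegistrationConfig),
                         ("denoise", DenoiseConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "band_alphas" in d:
            d["band_alphas"] = tuple(d["band_alphas"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text) or {})


@dataclass(frozen=True)
class PipelineResult:
    selective: SelectiveImageSet
    enhanced: np.ndarray
    params: CancellationParams
    manifest: dict


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig,
                 out_dir: "Path | str | None" = None) -> PipelineResult:
    """Run the full four-image pipeline on a simulated pair.

    Stages: phantom simulation (optional motion + Poisson noise), motion
    registration of the low-energy frame onto the high-energy frame,
    wavelet denoising of both frames, cancellation-weight selection,
    log-subtraction into the tissue-selective pair, and frequency-band
    fusion into the enhanced standard image.  With ``out_dir`` set, the
    four display-windowed images and a JSON manifest are written as DICOM.
    """
    cfg = config
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg.to_yaml().encode()).hexdigest(),
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 4), **info}
        return done

    rng = np.random.default_rng(cfg.seed)
    motion_seed, noise_seed = (int(s.integers(2 ** 31)) for s in rng.spawn(2))

    done = stage("simulate")
    phantom = build_chest_phantom(cfg.width, cfg.height, cfg.phantom)
    motion = None
    if cfg.motion_amplitude > 0:
        motion = random_smooth_motion(phantom.shape, cfg.motion_amplitude,
                                      motion_seed)
    settings = dataclasses.replace(cfg.settings, seed=noise_seed)
    pair = simulate_pair(phantom, cfg.atten, settings, motion=motion,
                         noisy=cfg.noisy)
    done(low=_hash(pair.image_low), high=_hash(pair.image_high))

    i_low, i_high = pair.image_low, pair.image_high
    if cfg.do_register:
        done = stage("register")
        disp = register_diffeomorphic(i_high, i_low, cfg.registration)
        i_low = np.maximum(apply_motion(i_low, disp), 1e-6)
        done(converged=bool(disp.converged),
             max_disp=float(disp.magnitude().max()))
    if cfg.do_denoise and cfg.noisy:
        done = stage("denoise")
        i_low = np.maximum(denoise_image(i_low, cfg.denoise), 1e-6)
        i_high = np.maximum(denoise_image(i_high, cfg.denoise), 1e-6)
        done()

    pair = dataclasses.replace(pair, image_low=i_low, image_high=i_high)

    done = stage("weights")
    if cfg.weight_mode == "analytic":
        params = analytic_params(cfg.atten)
    else:
        w_soft = optimize_cancellation(pair, cfg.weight_mode, "bone").argmin
        w_bone = optimize_cancellation(pair, cfg.weight_mode, "soft").argmin
        params = CancellationParams(w_soft=w_soft, w_bone=w_bone)
    done(w_soft=params.w_soft, w_bone=params.w_bone)

    done = stage("subtract")
    selective = make_selective_set(pair, params)
    done()

    done = stage("enhance")
    enhanced = enhanced_standard(pair, params, BandWeights(cfg.band_alphas),
                                 levels=len(cfg.band_alphas) - 1)
    done()

    outputs = {
        "conventional": window_level(selective.conventional),
        "enhanced": enhanced,
        "soft_selective": window_level(selective.soft_selective),
        "bone_selective": window_level(selective.bone_selective),
    }
    manifest["outputs"] = {k: _hash(v) for k, v in outputs.items()}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, img in outputs.items():
            kvp = (cfg.settings.kvp_high if name != "soft_selective"
                   else cfg.settings.kvp_low)
            write_image(out_dir / f"{name}.dcm", img, {
                "kvp": kvp,
                "exposure_time": cfg.settings.exposure_time_high,
                "pixel_spacing": cfg.phantom.pixel_pitch,
            })
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (out_dir / "config.yaml").write_text(cfg.to_yaml())

    return PipelineResult(selective, enhanced, params, manifest)
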