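# dexray

Dual-energy subtraction (DES) chest radiography toolkit: simulation of
paired low/high-kVp exposures, weighted log-subtraction into tissue-selective
images, cancellation-parameter optimization, diffeomorphic motion
registration, wavelet noise reduction, frequency-band image fusion, and
random-effects pooling of observer-preference scores.

## The problem

A dual-exposure DES system acquires two chest radiographs in quick
succession — 60 kVp and 120 kVp, 150 ms apart.  Because bone and soft
tissue attenuate X-rays differently at the two energies, a weighted
combination of the log-transmissions can cancel either material:

```
I_subtracted = exp( log I_H − w · log I_L )
```

Under a monochromatic two-material model, `log I = −μ_soft·t_soft −
μ_bone·t_bone` per beam, so the weight `w* = μ_high/μ_low` of a material
removes it exactly: subtracting at bone's ratio yields the
**soft-tissue-selective** image (ribs suppressed, nodules unobscured), and
at soft tissue's ratio the **bone-selective** image.  Two practical
problems dominate image quality: inter-exposure motion (breathing, cardiac)
turns into bright/dark rib-edge artifacts, and subtraction amplifies
quantum noise.  This package addresses both — log-domain diffeomorphic
demons registration on a Laplacian-pyramid scaffold, and stationary-wavelet
shrinkage with edge-adaptive thresholds — and additionally fuses the two
selective images band-by-band into an **enhanced standard** image that
favours soft-tissue contrast at low spatial frequencies and bone detail at
high frequencies.

Because no image data ship with the package, a parametric two-material
chest phantom (torso, lungs, oblique ribs, spine, clavicles, scapulae,
nodule inserts) provides ground-truth thickness maps; every pipeline claim
is tested against this ground truth.

The evaluation side mirrors how such systems are scored by radiologists:
five-point preference ratings (1 = strongly prefer conventional, 3 = no
preference, 5 = strongly prefer DES) per anatomic region, pooled across
readers with a DerSimonian–Laird random-effects model,

```
w_i = 1/v_i,   Q = Σ w_i (y_i − ȳ_FE)²,
τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)),
μ̂ = Σ y_i/(v_i+τ²) / Σ 1/(v_i+τ²),   CI = μ̂ ± 1.96·(Σ 1/(v_i+τ²))^(−1/2)
```

with a region called significant when the 95% CI excludes the neutral
score 3.  The published summary tables of the volunteer reader study this
pipeline was evaluated with (score histograms, pooled means, CIs for three
comparison sessions) ship as package data.

## Worked example

```python
import dexray
from dexray.enhance import window_level
from dexray.metrics import region_contrast
from dexray.readerstudy import count_significant, published_estimates

phantom = dexray.build_chest_phantom(256, 256)
atten = dexray.AttenuationTable()
pair = dexray.simulate_pair(phantom, atten, noisy=False)

w_soft = dexray.optimize_cancellation(pair, "residual", "bone").argmin
w_bone = dexray.optimize_cancellation(pair, "residual", "soft").argmin
print(f"recovered w_S = {w_soft:.3f}  (analytic {0.40/0.90:.3f})")
print(f"recovered w_B = {w_bone:.3f}  (analytic {0.18/0.25:.3f})")

sel = dexray.make_selective_set(pair, dexray.CancellationParams(w_soft, w_bone))
rib = phantom.mask(3)
ratio = (region_contrast(window_level(sel.soft_selective), rib)
         / region_contrast(window_level(sel.conventional), rib))
print(f"rib contrast remaining in soft image: {100*ratio:.1f}%")

for session in ("enhanced", "soft", "bone"):
    ests = published_estimates(session)
    print(f"{session}: {count_significant(ests)} of {len(ests)} regions significant")
```

prints

```
recovered w_S = 0.445  (analytic 0.444)
recovered w_B = 0.720  (analytic 0.720)
rib contrast remaining in soft image: 2.6%
enhanced: 9 of 13 regions significant
soft: 4 of 8 regions significant
bone: 4 of 5 regions significant
```

The grid search lands on the analytic cancellation ratios to within one
grid step; at that weight the soft-tissue-selective image retains under 3%
of the conventional image's rib contrast; and the CI-exclusion rule applied
to the published tables reproduces the reported significant-region counts
for all three comparison sessions.

## Command line

`dex` exposes the pipeline as subcommands: `simulate`, `register`,
`denoise`, `subtract`, `optimize-w`, `enhance`, `pipeline` (the full
four-image chain with a reproducibility manifest) and `reader-pool`.
Images travel as 16-bit TIFF/PNG or minimal MONOCHROME2 DICOM with KVP,
ExposureTime and PixelSpacing populated from the acquisition settings.

```sh
dex pipeline --seed 1 --out run/
dex reader-pool --scores scores.tsv --session 3 --out pooled/
```

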