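# Methods

This note records the models, parameter choices and numerical decisions
behind `dexray`, and what the synthetic tests do and do not establish.

## Forward model and phantom

The simulator uses a monochromatic effective-energy approximation: one
linear attenuation coefficient per material per beam, so transmission is
`I = exp(−μ_soft t_soft − μ_bone t_bone)` and log-transmission is exactly
affine in the two thickness maps.  Real 60/120 kVp beams are polychromatic
and beam hardening makes the effective μ depth-dependent; the approximation
is deliberate, because it gives the cancellation weight a closed form
(`w* = μ_high/μ_low`) that serves as the analytic oracle for the optimizer.
Default coefficients are μ_soft = (0.25, 0.18) cm⁻¹ and μ_bone =
(0.90, 0.40) cm⁻¹ for (low, high) — plausible magnitudes for tissue and
cortical bone at these beam qualities, but only their ratios matter to the
subtraction math: they put the two cancellation weights at 4/9 ≈ 0.444
(bone) and 0.72 (soft tissue), comfortably separated.

The chest phantom is a 2-D projection model: a 20 cm soft-tissue torso
ellipse, lung fields of 7 cm equivalent thickness, a 4 cm mediastinal
column, oblique 0.8 cm rib bands, a 3 cm spine, clavicles, scapulae and an
optional soft-tissue nodule insert.  Structure borders are tapered with
Gaussian profiles; the lung border uses a broader taper (3 px) than bone
edges (1 px), reflecting the gradual projected chest-wall transition versus
sharp cortical margins.  Two labelling choices matter to the metrics:

- **Rib labels** mark ribs overlying flat lung parenchyma only, clear of
  the lung-border taper.  This is the ROI a reader uses to judge rib
  suppression; including the lung border would measure the (huge, bone-free)
  soft-tissue gradient instead of residual rib structure.
- The **mediastinum is wider than the spine column**, so inner lung borders
  do not touch spine edges — without this gap every strong edge mixes both
  materials and no blind weight estimate is possible.

Noise is Poisson counting noise only (default budget 10⁴ photons per
open-field pixel; no electronic term), and detector signals are floored at
10⁻⁶ of dynamic range before any logarithm.  Inter-exposure motion is
modelled as a bulk chest translation (70% of the amplitude, random
direction) plus a smooth random residual field — pure zero-mean smooth
fields rarely displace the ribs and make motion-correction claims
unmeasurable.  Automatic exposure control solves for the exposure time by
bisection on the median lung-region signal (1% tolerance), with detector
gain normalized so the default technique maps transmission directly to
signal.  Entrance surface dose uses the standard tube-output ×
inverse-square × backscatter model (backscatter factor 1.35, focus–skin
distance = SID − 20 cm); output calibration is user-supplied per kVp.

## Cancellation-parameter selection

The deployed system selects `w` with a trained classifier; here selection
is a deterministic grid search (default w ∈ [0.05, 1.50], step 0.005) over
one of two objectives:

- **residual** (oracle, simulation only): variance of the log-subtracted
  image within the cancelled material's true footprint after removing the
  component linearly explained by the other material's thickness.  Exactly
  zero at `w*` in the noiseless model and convex quadratic in `w`.  Under
  Poisson noise the log-noise variance contributes `1/(N·I_H) + w²/(N·I_L)`
  per pixel, which grows with `w` and would bias the argmin low; the
  objective subtracts a plug-in estimate of that term and excludes
  photon-starved pixels (expected counts below max(50, 0.02·N), e.g. the
  spine behind the mediastinum in the low-energy frame).
- **histogram** (blind): at an edge generated by a single material, the
  local ratio `∇log I_H · ∇log I_L / |∇log I_L|²` equals that material's
  cancellation weight.  Edge pixels inside the body (the skin outline is
  excluded) are clustered by this ratio; because mixed edges always yield
  intermediate ratios, cluster centres are anchored at the 2nd/98th
  percentiles and only pixels near a centre are kept.  The objective is
  gradient-magnitude energy of the subtracted image on the cancelled
  material's footprint plus a small (0.005×) squared-IQR histogram
  dispersion penalty.  The blind mode expects denoised input — the pipeline
  runs it after wavelet denoising — and on a noiseless phantom its argmin
  agrees with the oracle's within 0.02.

## Registration

A classical stand-in with the same contract as the system's learned
registration: log-domain diffeomorphic demons run coarse-to-fine over a
Gaussian/Laplacian pyramid (3 levels, 50 iterations per level, σ_fluid =
2 px, σ_elastic = 1.5 px), with the velocity field exponentiated by
scaling-and-squaring (≥ 6 steps, step count raised until the scaled field
is below 0.5 px) so the Jacobian determinant stays positive.  The two
exposures differ in contrast, so the demons force is computed on locally
standardized (15 px window) log-images, never raw intensities.  Remaining
cross-energy structure still induces a small spurious field (~0.5 px mean
on an aligned noiseless pair); with genuine 2–3 px motion the field is
recovered to a few hundredths of a pixel in the mean and the rib-edge
artifact energy of the subtracted image drops to ~6% of its unregistered
value.  Non-convergence within the iteration budget returns the best field
with a flag, never an exception.

## Denoising

Undecimated (stationary) wavelet shrinkage with `bior2.2`, 3 levels —
shift invariance avoids turning subtraction artifacts into blocking
patterns.  Noise σ is estimated as MAD(finest diagonal band)/0.6745; the
unnormalized SWT doubles band gain per level, so σ is scaled by 2^level
per band.  Thresholds follow BayesShrink by default (universal rule
available) and are attenuated by `1 − γ·edge_weight` (γ = 0.7) where the
edge weight is the normalized local gradient magnitude — rib edges and
fissures keep their sharpness.  The approximation band is never touched.
A pluggable `denoiser` callable lets a learned model replace the shrinkage
without changing the interface.

## Enhanced standard image

The fusion blends Laplacian pyramids of the two *windowed tissue-selective*
images (not the raw energy frames): level k of the output is
`α_k·soft_k + (1−α_k)·bone_k` with defaults α = 1.0 (residual), 0.9, 0.7,
0.4, 0.2 coarse→fine, then synthesis and clipping to [0, 1].  Convexity
holds per level and, for uniform weights, pointwise after synthesis;
non-uniform weights can overshoot the sources' range after synthesis, which
is why the output is clipped rather than re-windowed.  Nodule conspicuity
is measured as contrast-to-noise with the background ring *including*
overlying rib clutter — anatomical noise is what limits detection on a
projection radiograph, and it is the only reading under which "better
soft-tissue visibility than conventional" is a falsifiable claim: against
a bone-free background, CNR is invariant to the monotone mapping between
the conventional and soft-selective images.  At the 256 px reference
resolution the default blend shows both higher rib-edge gradient energy
and higher nodule CNR than the conventional image, and swapping α and β
moves both metrics in the opposite directions.

## Reader-study pooling

Per-reader mean scores with variance-of-mean s²/n (floored at 10⁻⁶ so
constant raters still contribute) are pooled with DerSimonian–Laird and a
normal-quantile 95% CI; REML and Knapp–Hartung adjustments are out of
scope.  A CI endpoint exactly at the neutral score 3 counts as not
significant.  Report rows round means to 1 decimal and CIs to 2, half away
from zero.

The score generator draws a latent rating `3 + δ + b_i + 0.7·ε` per
participant and discretizes it at thresholds (1.5, 2.5, 3.5, 4.5).  Default
reader biases are (−0.05, −0.02, 0.02, 0.05): modest fixed calibration
differences among four radiologists.  Under these conditions (k = 4,
n = 52) the pooled estimate recovers the discretized latent mean with
negligible bias and its 95% CI covers the truth ≈96% of the time; larger
fixed biases push DL into overcoverage because fixed between-reader spread
inflates τ², and even homogeneous readers sit slightly above nominal
(~95.9%) because τ̂² truncation at zero only ever widens the CI.  The
generator emulates ordinal scoring and reader heterogeneity; it does not
model participant-level correlation across regions, reader learning over
sessions, or ties to actual image content, so passing tests validate the
pooling machinery, not any claim about real reader behaviour.

## Problem sizes and determinism

Imaging checks run on 256×256 phantoms (192×192 for the 20-seed Monte-Carlo
weight recovery); pooling checks use 500–1000 replicates.  All stochastic
stages draw from seeded generators — the pipeline derives per-stage
substreams from one seed, and two runs with the same config are
bit-identical (verified via output hashes in the run manifest).

## Known limitations

- Monochromatic beams: no beam hardening, scatter, detector MTF or grid
  modelling; anti-scatter grid and exposure geometry are metadata only.
- The registration, denoising and weight-selection components are classical
  stand-ins honouring the published contracts of their learned
  counterparts, not reconstructions of them.
- The enhanced-standard fusion is this package's own concrete realization
  of a qualitatively described, patented algorithm; whether the vendor
  blends raw energy frames or selective images is unstated, and the
  selective-image choice here is a declared design decision.
- Published pooled means cannot be recomputed from the packaged aggregate
  histograms (per-reader data are not public); only the significance
  counting and formatting rules are testable against the tables.
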