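# Methods

This note documents the models, algorithms, parameters and design choices
behind `fluospect`.  Section order follows the processing chain.

## Respiratory model

Each breathing cycle is a raised cosine
`a(phi) = A (1 - cos 2*pi*phi)/2`, `phi in [0,1)`, starting and ending at
end-exhale, so concatenated cycles are phase-continuous across parameter
switches.  The intra-cycle waveform of real breathing has a longer
end-exhale dwell; the raised cosine was chosen because it is smooth,
analytic and invertible (the analytic gating fraction
`arccos(0.6)/pi = 29.5%` at threshold 0.2 follows directly).  Six patterns
are provided: stable (period 5 s, diaphragm amplitude 2.0 cm, AP expansion
1.2 cm), period change (5 s to 3 s at half scan), amplitude change (2.0 to
3.0 cm), baseline shift (+1.0 cm), and per-cycle random draws (small: peak
2.0–2.5 cm, baseline 0–0.5 cm; large: amplitude 0.5–2.0 cm, period 3–7 s,
baseline 0–1.0 cm).  Switches take effect at the first cycle boundary at or
after the switch instant.  AP expansion is always 0.6 x diaphragm
displacement ("scaled AP").  The per-sample ground truth used to score
binning is the within-cycle normalized amplitude `(1 - cos 2*pi*phi)/2`.

## Phantom and ground-truth motion

Organs are quadric primitives on an isotropic voxel grid (defaults
128x128x100 at 4.7 mm; desk scale 64x64x48 at 6 mm): elliptic-cylinder
body, two lung ellipsoids, a liver ellipsoid capped at the lung base (the
diaphragm boundary the fluoroscopic tracking relies on), a posterior spine
cylinder, an anterior sternum bar, and a 30 mm sphere inside the liver.
150 MBq is split so the sphere's mean voxel activity is `r` times the liver
background's (uptake ratios 1:2 … 1:5).  Attenuation is tabulated at
140 keV and at a single 60 keV-effective x-ray energy (lung = 0.25 x water,
bone > water).

The deformation is the same anatomical extrapolation the reconstruction
later uses: the superior–inferior (SI) component equals the diaphragm shift
below the lungs and tapers linearly to zero at the lung apex; the
anterior–posterior (AP) component is zero at (and posterior of) the spine
and grows linearly to the full AP shift at the anterior surface.  Two
deliberate refinements:

* the AP ramp continues at full strength into the air in front of the
  anterior surface — a pull-back field truncated at the body contour cannot
  move the contour, so the chest would never actually rise;
* the liver (dilated by 3 voxels) translates as a rigid block with the ramp
  value at its centroid.  The pure ramp has uniform compressive divergence
  (~6% at 2 cm amplitude) that would spuriously inflate pull-back activity
  sums; the rigid liver keeps activity conserved to <2% under warping and
  matches the rigid-liver assumption of the compensation method itself.
  The reconstruction-side MVF keeps the pure ramp, so the small model
  mismatch between true motion and compensating field is retained.

Warping is pull-back (`out(p) = in(p + d(p))`) with linear (or nearest)
interpolation; out-of-grid samples read zero.

## Projection operators

Both detector layers share a parallel-beam geometry whose in-plane
resampling onto the rotated (gantry) frame is a sparse matrix with bilinear
weights.  Every projector is therefore a composition of operations with
*exact* adjoints (sparse transpose, symmetric zero-padded Gaussian kernels,
diagonal attenuation weights) — adjointness holds to machine precision,
which MLEM and SART correctness depend on.  Cone-beam geometry would enter
through this same interface; the compensation method itself is
geometry-agnostic.

*X-ray*: line integrals of the posed attenuation map, converted to detector
expectation `flux(dose) * exp(-integral)`; flux is linear in the per-frame
dose.  Noise is Gaussian with `sigma = sigma0 + c*sqrt(mu)`, truncated at
zero — an electrical floor plus a Poisson-like term.  Defaults
(`sigma0 = 2`, `c = 1`, flux 2000 at 1 µGy/frame) are configuration: they
place the 1–1000 µGy total-dose sweep between boundary-invisible and
organs-visible, the regime the method is designed for.

*Gamma*: rotate activity and attenuation to the detector frame; per depth
plane, attenuate by `exp(-integral of mu to the detector)` (half-voxel
self-term), blur with a Gaussian PSF of `fwhm = 3.8 mm + 0.37 mm/cm *
depth` (3.8 mm intrinsic; ~7.5 mm at 10 cm), sum planes, and scale by
sensitivity x time x 64% flat-panel transmission.  Planes sharing a
(0.1-voxel-quantized) sigma are summed before blurring — the blur is
linear, so this is exact and ~3x faster.  Sensitivity (1.5e-4 counts per
Bq·s) is configuration chosen so a 5-min 150 MBq desk scan detects ~8e5
counts, a level at which gating is visibly noise-limited.

*List mode* is emulated by subframes at the fluoroscopic sampling interval
(0.2 s at 5 Hz), fine enough to inherit per-instant bin labels.  Both
simulators quantize the instantaneous diaphragm amplitude to 0.5 mm (well
below the 6 mm voxel) and cache posed volumes and projections per
(angle, amplitude level); the step-and-shoot schedule is
`angle = floor(t / T * n_angles)`.

## Motion extraction and binning

The surrogate is the row center-of-mass of a horizontal detector band
("strip").  Auto-placement centers the strip on the row whose summed
intensity varies most over time — the band modulated by the moving
lung–liver boundary; a gradient rule is the single-frame fallback.  Strip
height is 50 rows, shrunk to ~40% of the detector on small grids.  The
gantry background is removed by a centered moving average (10 s window,
truncated at the edges); a per-gantry-angle mean is available as an
alternative that is exact for step-and-shoot schedules.  Peaks (prominence
>= 0.3 x robust amplitude, separation >= 0.6 cycles) define the upper
envelope; per-cycle minima define the floor — necessary for baseline-shift
patterns, where troughs are not at zero.  The normalized signal is clipped
to [0,1] and split into B equal-width bins (bin 1 = end-exhale reference,
top bin closed); gating accepts `normalized <= 0.2`.  Nuclear subframes
inherit the label of the nearest preceding fluoroscopic frame.

## Per-bin CBCT and the motion vector field

Frames are log-transformed (`-ln(max(frame, 1)/flux0)`), averaged per
(bin, angle), and reconstructed with OS-SART: interleaved angle subsets
(default 6), relaxation 1.0, SART row/column normalization, nonnegativity
clamp, 50 iterations.  Bins with partial angular coverage are reconstructed
as-is; empty bins are dropped and the remaining bins renumbered.

Because the low-dose reconstructions cannot support free-form registration,
per-bin motion is summarized by two scalars: the SI shift of the lung–liver
boundary and the AP shift of the sternum, each estimated by template
matching of a 1D mean-intensity profile inside an anatomical search box
against the bin-1 reconstruction.  The reference profile is extended by the
search radius so every candidate lag is scored on a full-length overlap
(short-overlap normalized correlation is spuriously high on flat anatomy),
and the peak is refined on a 0.05-voxel grid with an interpolated reference
(a parabola through ZNCC samples is biased on asymmetric peaks).  The
diaphragm window is kept below the lung taper so everything inside it moves
rigidly.  Scalars are extrapolated to full fields with the anatomical rules
above; inverse fields negate the shifts (valid for this parametric family).
Fields are mean-filtered over 3 voxels spatially and 3 bins temporally
(truncated at the end bins, bin 1 re-zeroed).  A "prior 4D scan" MVF is
emulated by scaling so the maximum-amplitude bin loses exactly 2 mm (SI)
and 1 mm (AP).

## SPECT reconstruction

Classic MLEM, 25 iterations, no subsets, per-angle acquisition times folded
into the system matrix; sensitivity `s = A^T 1`; ratio guard
`eps = 1e-12 x mean expectation`; zero-sensitivity voxels stay zero.  The
Poisson log-likelihood is tracked and non-decreasing.  Gating rescales
per-angle times to the accepted durations and fails informatively when
fewer than half the angles retain frames.  The MVF mode, per iteration and
bin: warp the estimate to the bin pose (forward field), forward-project
with the bin-warped attenuation, backproject the measured/estimated ratio,
warp the error image back (inverse field), then average error images over
bins weighted by bin acquisition time (plain averaging is a config toggle).
The sensitivity is the matching time-weighted average of warped-back
per-bin sensitivities, which makes the update reduce *exactly* to plain
MLEM for identity fields and keeps it an EM-style multiplicative surrogate.

## Metrics and experiments

All metrics are evaluated in the reference (end-exhale) pose: activity
recovery = recovered/true sphere activity; relative noise = background
std/mean; CNR = (sphere mean − background mean)/background std with the
background VOI = liver minus the 1-voxel-dilated sphere; max-CNR over the
25 iterations removes convergence-rate differences between modes (Rose
criterion: CNR >= 4 detectable).  The experiment driver splits a master
seed into per-(realization, stage) 31-bit seeds via `SeedSequence`, so runs
are bitwise reproducible; noise realizations redraw only the noise.

## Problem sizes

The package's default "desk" configuration is 64x64x48 voxels at 6 mm with
60 gantry angles and a 300 s scan at 5 Hz; the clinical-scale setup
(128x128x100 at 4.7 mm, 120 angles) is available as the `full`
configuration.  The test suite and the acceptance script use desk scale
with 5 noise realizations for the stable-breathing mode comparison and 2-3
for the baseline-shift robustness check; the toy oracles use 2x2x1 and
6-ray explicit-matrix systems.

## Known limitations

* Parallel-beam geometry (no cone-beam divergence, no detector offset).
* No scatter, septal penetration, beam hardening, detector lag or dead
  time; the energy window is implicit.
* Rigid SI+AP liver motion only; no hysteresis between inhale and exhale
  paths; no cardiac motion.
* The synthetic phantom's organ contrast is idealized, so motion-extraction
  accuracy on real low-dose fluoroscopy will be lower at equal dose; the
  dose sweep still reproduces the qualitative boundary-visibility regimes.
* Absolute CNR values depend on the configured count level and are not
  comparable to scanner measurements; mode *orderings* and trends are the
  meaningful outputs.
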