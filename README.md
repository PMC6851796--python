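# fluospect

Respiratory-motion-compensated **interventional liver SPECT** with a
dual-layer detector: simulation and reconstruction in one package.

## The problem

In hepatic radioembolization, a pretreatment 99mTc-MAA SPECT scan predicts
where the therapeutic microspheres will deposit.  Performing that scan in
the intervention room requires fast acquisitions, and respiratory motion
(~2 cm diaphragm excursion) blurs the liver activity, degrading both the
quantitative accuracy (activity recovery in a lesion) and the visual quality
(contrast-to-noise ratio, CNR).  Conventional amplitude **gating** rejects
most counts and becomes noise-limited in a 5-minute scan.

A dual-layer detector — an x-ray flat panel mounted in front of a gamma
camera on a c-arm — measures fluoroscopic and nuclear projections
*simultaneously*.  The breathing signal can then be extracted from the
fluoroscopic frames themselves, both data streams binned by respiratory
amplitude, per-bin cone-beam CT volumes reconstructed and registered, and
the resulting **motion vector field (MVF)** used in a motion-compensated
MLEM reconstruction that uses *all* counts.

## What the package does

Everything is generated internally; no external data are needed.

1. **`respiration`** — parametric diaphragm-displacement signals: stable
   breathing (5 s cycle, 2.0 cm diaphragm / 1.2 cm AP expansion) plus five
   irregular patterns (phase change, amplitude change, baseline shift,
   small/large random variations).
2. **`phantom`** — voxelized torso phantom (body, lungs, liver, spine,
   sternum, 30 mm liver sphere at a configurable uptake ratio; 150 MBq
   total) with an analytic respiratory deformation as ground truth.
3. **`fluoro`** — parallel-beam x-ray projections with the compound
   dose–noise model `sigma(mu) = sigma0 + c*sqrt(mu)`; total dose 1–1000 µGy,
   sampling 1–5 Hz.
4. **`nuclear`** — attenuated, depth-dependent-PSF gamma projections with
   Poisson noise, 64% flat-panel transmission, list-mode emulated by fine
   subframes.
5. **`motion`** — strip center-of-mass breathing-signal extraction,
   background removal, peak normalization, equal-width amplitude binning and
   gating (threshold 0.2).
6. **`cbct`** — per-bin OS-SART reconstruction (50 iterations), per-bin
   diaphragm (SI) and sternum (AP) shift estimation, anatomical
   extrapolation to a full motion vector field, spatial/temporal smoothing.
7. **`spect`** — MLEM (25 iterations, no subsets) in four modes: no
   compensation, gating, MVF compensation, and a static reference; the MVF
   mode warps the estimate to each bin pose, forward-projects with bin-warped
   attenuation, and averages the warped-back error images over bins.
8. **`metrics` / `experiment` / `cli`** — activity recovery, relative noise,
   CNR and max-CNR curves, aggregation over noise realizations, and a
   config-driven experiment driver with deterministic seed splitting.

## Worked example

```python
from fluospect.experiment import desk_config, run_realization

cfg = desk_config(n_realizations=1)   # 64x64x48 @ 6 mm, 60 angles, 5-min
art = run_realization(cfg, 0)
for mode, rep in art.reports.items():
    v, it = rep.max_cnr
    print(f"{mode:9s} max CNR {v:5.2f} at iteration {it:2d}  "
          f"recovery {rep.activity_recovery[-1]:.3f}")
```

prints (one noise realization, stable breathing, 1:5 uptake):

```
none      max CNR  6.28 at iteration 25  recovery 0.549
gated     max CNR 10.62 at iteration 14  recovery 0.802
mvf       max CNR 11.69 at iteration 23  recovery 0.768
reference max CNR 13.29 at iteration 21  recovery 0.797
```

Reading: motion blur halves the sphere recovery without compensation;
gating restores recovery but its CNR is noise-limited and peaks early;
MVF compensation comes closest to the no-motion reference in visual
quality while using all counts.

The same pipeline is available from the shell:

```bash
fluospect simulate --out-dir run/          # phantom + both projection sets
fluospect extract-motion --out-dir run/    # breathing signal + bins
fluospect recon-cbct --out-dir run/        # per-bin CBCT volumes
fluospect estimate-mvf --out-dir run/      # motion vector field
fluospect recon-spect --out-dir run/ --mode mvf
fluospect evaluate --out-dir run/
fluospect run-experiment --seed 1 --out-dir exp/   # everything, all modes
```

## Limitations

Parallel-beam geometry stands in for the cone-beam flat panel (the method
under test is geometry-agnostic); scatter, beam hardening and Monte Carlo
photon transport are out of scope; the liver moves rigidly (SI + AP) as in
the motion model the method itself assumes.  See `docs/methods.md` for the
full model description and design rationale.
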