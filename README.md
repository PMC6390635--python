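# issdiff

Anisotropic diffusion–clearance modelling of MRI tracer transport in the
brain interstitial space (ISS).

## The problem

Drugs delivered directly into the brain's interstitial space spread by
diffusion through a tortuous extracellular network and are simultaneously
removed by uptake, binding and drainage. Tracer-based MRI follows this
process *in vivo*: a gadolinium chelate (e.g. Gd-DTPA) is injected at a
point, serial T1-weighted volumes are acquired, and the signal-intensity
increment ΔSI of each voxel — proportional to local tracer concentration —
is tracked over hours. `issdiff` is for researchers who need to turn such
image series into quantitative transport parameters, and to validate that
inversion on synthetic data with known ground truth.

## The model

Concentration C(x, y, z, t) in a homogeneous anisotropic medium obeys

    ∂C/∂t = Dx ∂²C/∂x² + Dy ∂²C/∂y² + Dz ∂²C/∂z² − k C + Q/α

with axis-aligned effective diffusivities Dx, Dy, Dz (mm²/s), first-order
clearance rate k (1/s), ISS volume fraction α = V_ISS/V_tissue, and source
term Q. For an instantaneous point source of mass M the free-space solution
is an anisotropic Gaussian with exponential decay:

    C = M / (8 α (π t)^{3/2} √(Dx Dy Dz))
        · exp(−x²/4Dxt − y²/4Dyt − z²/4Dzt) · e^{−kt}

a constant-rate infusion is its Duhamel superposition over the release
window. The package provides:

- **`issdiff.model`** — the closed forms, total-mass conservation, and the
  derived metrics: average D (root-sum-of-squares by default; RMS and mean
  selectable), half-life t½ = ln 2 / k, tortuosity λ = √(D_free/D_eff).
- **`issdiff.solver`** — an explicit finite-difference solver for the full
  PDE on a bounded grid, the independent numerical oracle.
- **`issdiff.phantom`** — a digital MRI phantom emulating the acquisition
  protocol (9 scans, 10–360 min post-injection, 0.5 mm voxels, Rician
  acquisition noise) with a serialisable ground-truth record.
- **`issdiff.imaging`** — NIfTI I/O, pre/post subtraction, linear
  ΔSI-to-concentration calibration, spacetime sample extraction, and
  contour parameter maps.
- **`issdiff.estimation`** — bounded nonlinear least squares for
  (Dx, Dy, Dz, k) plus the source amplitude A = M/α, with multistart,
  Jacobian/delta-method standard errors, a Monte-Carlo recovery harness,
  and per-ROI tile fits.

A thin CLI (`issdiff phantom|simulate|fit|recover|maps`) wraps these for
shell use; the primary interface is the Python API (see `examples/`).

## Worked example

`examples/03_phantom_pipeline.py` generates a noiseless phantom from known
truth, runs the full image pipeline, and fits:

```
ground truth:     Dx = 1.000e-04, Dy = 1.500e-04, Dz = 8.000e-05 mm^2/s, k = 1.400e-05 /s
Diffusion-clearance fit
  Dx = 1.0000e-04 mm^2/s (SE 4.40e-21)
  Dy = 1.5000e-04 mm^2/s (SE 5.06e-21)
  Dz = 8.0000e-05 mm^2/s (SE 4.52e-21)
  k  = 1.4000e-05 1/s    (SE 7.18e-21)
  A  = 1.0000e+02 nmol (M/alpha)
  average D (rss) = 1.9723e-04 mm^2/s
  t_1/2 = 4.9511e+04 s
  RSS = 1.4465e-28 over 3000 samples; converged=True
```

Every parameter is recovered exactly (the pipeline is the identity at zero
noise), the fitted amplitude A = M/α = 20 nmol / 0.2 = 100 nmol, and the
clearance half-life of ≈ 4.95 × 10⁴ s (~13.8 h) follows from k.
`examples/04_recovery_study.py` repeats this with 5% Rician noise: the
diffusivities recover to a few percent while k is weakly identified at that
noise level (see `docs/methods.md` for the identifiability analysis).

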