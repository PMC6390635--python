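# Methods

## Model and assumptions

`issdiff` models a tracer released into the brain interstitial space (ISS)
as obeying an anisotropic diffusion–reaction equation with constant
coefficients,

∂C/∂t = Dx ∂²C/∂x² + Dy ∂²C/∂y² + Dz ∂²C/∂z² − kC + Q/α,

on free space with decay at infinity. The assumptions are: homogeneous
tissue (no regional barriers), a diagonal diffusion tensor aligned with the
image axes, first-order clearance lumping all removal routes (capillary
uptake, binding, CSF/lymphatic drainage), no bulk flow, and no endogenous
production (appropriate for an exogenous chelate such as Gd-DTPA). The
source is divided by the ISS volume fraction α because tracer released into
the ISS is confined to that fraction of tissue volume.

For an instantaneous point source the solution is an anisotropic Gaussian
with variance 2·D_axis·t per axis, scaled by e^{−kt}; its whole-space
integral is (M/α)e^{−kt}, which `total_dissolved_mass` exposes and the test
suite verifies against adaptive quadrature (the integrand is separable, so
the 3-D integral is computed as a product of three 1-D adaptive
quadratures). A constant-rate infusion is handled by Duhamel superposition:
the concentration is the integral over release times τ of the instantaneous
kernel evaluated at elapsed time t − τ with mass rate C₀q, integrated by
adaptive quadrature (default relative tolerance 1e-8). For numerical
safety the Gaussian is always evaluated in log space; exponents below the
double-precision underflow limit return 0 rather than NaN.

Units are fixed throughout: mm, s, mm²/s, 1/s; concentration in mM
(≡ nmol/mm³) and amount in nmol, so no implicit conversions occur.

Derived metrics: average D defaults to the root-sum-of-squares
√(Dx²+Dy²+Dz²) of the axis diffusivities, with "rms" (√(ΣD²/3), which
equals D in an isotropic medium) and "mean" selectable — reports always
label the convention; half-life t½ = ln2/k; tortuosity λ = √(D_free/D_eff)
with the free-solution diffusivity supplied by the user (the standard ISS
definition).

## Finite-difference oracle

The solver marches forward-time central-space (FTCS) on a regular grid with
Dirichlet-zero faces, chosen over implicit schemes for its transparency and
an exactly testable stability bound dt ≤ 1/(2ΣD_a/Δa² + k) (used with a
0.9 safety factor). A bolus is deposited as M/(α·voxel volume) into its
containing voxel; this single-voxel delta makes the near field wrong at
very early times, so closed-form comparisons start once the diffusion
length √(2D_min t) spans ≥ 3 voxels, and errors are measured ≥ 3 voxels
from the faces. Because the faces impose C = 0 where the true solution
merely decays, a domain-size advisory (half-width ≥ 6√(2·D_max·T)) is
emitted as a warning. Output times snap to the nearest completed step —
recorded in the result — rather than interpolating. Under these rules the
scheme agrees with the closed form within 2% relative L2 at 0.05 mm
spacing and refines at empirical order ≈ 2; a discrete audit confirms that
dissolved mass plus the accumulated clearance integral equals the deposit
to < 0.5% while mass has not reached the boundary.

## Digital phantom

The phantom emulates the tracer-MRI protocol the estimator assumes: a
pre-injection volume (constant baseline, default 100 signal units —
arbitrary, it cancels in subtraction) and nine post-injection volumes at
10, 30, 60, 90, 120, 180, 240, 300 and 360 min on a 0.5 mm grid (default
41³ field). Each post frame is baseline + C/κ + noise, with κ the linear
concentration-per-signal calibration (default 0.05 mM/SU, an arbitrary but
self-consistent pair with the extraction stage). The default truth is
anisotropic, Dx = 1.0, Dy = 1.5, Dz = 0.8 ×10⁻⁴ mm²/s, k = 1.4×10⁻⁵ 1/s,
α = 0.2, with an instantaneous 20 nmol source (a 2 µl bolus of a nominal
10 mM infusate) at the field centre; a continuous-infusion truth is
available for robustness studies.

Noise is Rician by default (magnitude MRI): √((v+n₁)² + n₂²) with
independent N(0, σ²) components, fully determined by the recorded seed.
σ defaults to 5% of the peak noiseless ΔSI **outside the source-containing
voxel**. The in-voxel value of the point-source field at the first scan is
a near-singular artifact of the δ-source idealisation (about twice the
largest value anywhere else) and is excluded from analysis as the needle
track, so the peak observable enhancement is the meaningful signal scale;
σ then tracks source strength, making recovery statistics invariant to the
(unknown) infusate molarity, which scales signal and noise together.

What the phantom deliberately does not emulate: pulse-sequence physics and
T1 relaxivity saturation (the signal model is exactly linear), anatomical
heterogeneity and regional barriers, registration error (frames are
generated co-registered; the registration hook is a pass-through that only
warns on header mismatch), and partial-volume effects beyond voxel-centre
sampling. Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness to
these real-data effects.

## Estimation

Samples (x, y, z, t, C) relative to the known injection site and time are
fitted by bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`, unweighted, per the protocol's practice)
to the instantaneous-source closed form. Because M and α enter only
through M/α, a single experiment cannot separate them: the fitter estimates
a lumped amplitude A = M/α, and reports α = M/Â only when the injected
mass is supplied (`fixed_mass_alpha`). Dx, Dy, Dz and A are optimised in
log space (positivity and scale robustness); k stays linear with a k ≥ 0
bound. Initial guesses are moment-based — per-axis D from the growth of
the concentration-weighted second moment between the two widest-separated
frames, k from the log-linear decay of the per-frame peak corrected for
t^{−3/2} spreading, amplitude by inverting the closed form at the
earliest-frame peak — and a seeded multistart (default 8) perturbs them by
up to ×/÷3. Standard errors use σ̂² = RSS/(n−p) with covariance
σ̂²(JᵀJ)⁻¹ at the optimum, delta-method-propagated to the natural scale
and to the average D; a near-rank-deficient Jacobian attaches an
identifiability warning instead of raising. Fits require at least six
samples spanning two distinct times and positions — fewer is refused —
following the more-than-five-measurement-groups rule of the underlying
protocol.

Sample extraction keeps voxels whose concentration exceeds a threshold,
defaulting to 3× the background SD of ΔSI estimated from the corner
sub-cubes (suppressing the Rician floor), excludes a 0.5 mm radius around
the source (exactly the needle/source voxel, where the point-source field
is singular), and subsamples to at most 4000 rows with a seeded generator.

## Identifiability of the clearance rate at protocol noise

At the default 5% Rician noise the diffusivities recover with a few
percent median error, but k does not, and this is a property of the
experiment rather than of the estimator: over the 6-hour protocol the
clearance factor e^{−kt} spans only 0.008–0.30 of decay, and the late
frames whose amplitudes would pin it lie below the noise floor. A
Fisher-information (Cramér–Rao) computation using *every* voxel of all
nine frames with ideal Gaussian weighting — an upper bound on any
estimator operating on these images — gives SE(k)/k ≈ 0.5 at this noise
level. Threshold-based extraction can only do worse, and fitted k
typically collapses to its lower bound. The Monte-Carlo recovery harness
reports this honestly; estimating k to ~15% under this protocol requires
roughly an order of magnitude lower noise, longer follow-up, or an
estimator that aggregates total signal per frame rather than per-voxel
samples.

## Monte-Carlo design

`recovery_experiment` derives each replicate's seed from (master seed,
replicate index) only, so sweeps over noise level reuse the same
underlying noise draws scaled by σ (common random numbers). This is the
standard variance-reduction pairing and is what makes the
error-vs-noise-level monotonicity check meaningful at modest replicate
counts (25 for the headline study; 6 per level in the noise sweep —
problem sizes chosen to keep the studies desk-scale while leaving the
medians stable).

## Numerical choices and edge cases

- Continuous-source quadrature failure raises an error carrying the
  achieved tolerance rather than returning a silently inaccurate value.
- Negative ΔSI is retained through subtraction (keeping the stage exactly
  linear) and clamped to zero only after calibration, honouring C ≥ 0.
- Out-of-linear-range ΔSI values are flagged in a mask, not altered.
- Optimisation bounds: D ∈ [1e-7, 1e-1] mm²/s, k ∈ [0, 1e-2] 1/s,
  A ∈ [1e-6, 1e9] nmol; estimates at a bound are flagged in the result.
- ROI tile fits skip tiles failing the six-sample minimum with a warning
  and never abort the remaining tiles; an all-skipped tiling yields an
  empty map with a warning, not an error.

## Known limitations

Single-compartment, first-order clearance; diagonal diffusion tensor; no
bulk flow or off-diagonal coupling; registration and relaxivity
nonlinearity out of scope; source position and release time are treated as
known (an experimentally controlled injection). The average-D "rss"
default follows the convention of the underlying protocol's reports even
though it exceeds each axis value (√3·D in the isotropic case); use "rms"
for an isotropy-consistent average.
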