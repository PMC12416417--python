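# Methods

## Problem setting

Single-distance propagation-based phase-contrast imaging records, at a
distance `L` behind the sample, the intensity modulations produced by the
transverse gradients of the wavefront phase. For a homogeneous-object
material pair with refractive index `n = 1 - δ + iβ`, the sample-exit
wavefront is summarized by one scalar field, the effective absorption
`a(x, y)` (natural-log scale; `a = 0` is full transmission):

    I(x, y, 0) = exp(-a),        φ(x, y) = -(δ_av/β_av) · a / 2,

with the optical constants taken at the effective average beam energy and
with the embedding fluid's refractive index subtracted (only index
*differences* refract). Retrieval inverts the propagated intensity
`I(x, y, L)` for `a`; reconstruction is then ordinary parallel-beam
absorption tomography.

## Forward models

**Linearized (TIE).** `I_L = I_0 - (L/k) div(I_0 grad φ)`. The divergence
is discretized in conservative staggered form (fluxes on half-integer
faces), so total intensity is conserved exactly under both boundary rules.
Two face-intensity rules are exposed:

* `arithmetic` (default) — strictly linear in `I_0`;
* `logmean` — the logarithmic mean `(I_b - I_a)/(ln I_b - ln I_a)`, for
  which `div(I grad(c ln I)) = c Lap(I)` holds *exactly* on the grid. This
  makes the homogeneous (Paganin) form of the forward model,
  `I_0 - C Lap(I_0)` with `C = L δ/(2 k β h²)`, identical to the TIE
  divergence form, and makes the retrieval filter a machine-precision
  inverse.

A third stencil (`wide`, plain centered differences for both derivative
applications) matches the discretization used by the eikonal model's shift
field and is the right linear model to compare that model against.

**Paganin retrieval.** Fourier division by `1 + C Λ(q)` where
`Λ = (2 - 2 cos q_x h) + (2 - 2 cos q_y h)` is the discrete-Laplacian
symbol (not the continuum `q²`), so the forward/inverse pair is exact on
the grid. Data are edge-padded before the FFT (default: half the smaller
image dimension, capped at 256 px). Non-positive filtered intensities
raise with a pixel count rather than being clamped.

**Eikonal (ray-splat).** Each wavefront pixel's four corners are
ray-traced to the detector with the shift `s = (L/k) grad φ` (pixel units,
centered differences; corner shifts by bilinear interpolation of the
pixel-centered field). The pixel's intensity is deposited over the
detector cells its deformed quadrilateral overlaps, in proportion to exact
clipped polygon area (Sutherland–Hodgman). Folded (negative-area) quads are
re-oriented and deposited additively — caustics brighten instead of
breaking, which is precisely the regime the linearized model cannot
represent. Rays leaving the grid accumulate in an `escaped` counter so the
conservation identity `Σ detector + escaped = Σ input` is testable to
rounding. Interference between distinct ray paths is discarded (incoherent
near-field limit of the stationary-phase reduction); the Hessian-amplitude
form of the coherent sum is out of scope.

**Polychromatic discretization.** The beam spectrum is split into
contiguous equal-area bands; band `i` carries weight `f_i = 1/n_bands`,
its weighted-mean energy `ω_i`, and constants `(δ_i, β_i)` at `ω_i`. The
common absorption variable rescales per band as
`a_i = a · (β_i ω_i)/(β_av ω_av)` (from `μ = 2kβ` with `k ∝ E`), giving
`I_i = f_i exp(-a_i)` and `φ_i = -(δ_i/β_i) a_i / 2`; a single band at the
effective energy reduces exactly to the monochromatic formulas. Optical
constants are user-supplied tables (CSV, log-log interpolated); no
external database is required.

## Inversion

The misfit `Σ (F(a) - data)²` is minimized per projection by
Polak–Ribière nonlinear CG with Armijo backtracking (Barzilai–Borwein
initial step, restart on non-descent, steepest-descent fallback on
line-search failure; deterministic throughout). The gradient of the
eikonal model uses a Gauss–Newton-style linearization: the exact transpose
of the splat at frozen shifts for the attenuation chain, plus a
transport-of-divergence approximation `dF[ds] ≈ S[-div(I ds)]` for the
refraction chain, with all stencil transposes exact (verified by
dot-product tests; finite-difference checks are exact against this
linearized objective, which is the objective the check is defined for).

Two preconditioners address the problem's condition number:

* **Spectral.** The gradient is filtered by `(1 + C Λ(q))^-p`. The
  Gauss–Newton Hessian is `≈ diag(I²)(1 + C q²)²`, so `p = 2` equalizes
  per-mode convergence (the first step lands near the closed-form Paganin
  solution) and is the fastest choice on clean, model-consistent data.
  The default `p = 3` adds one extra power of high-frequency damping; on
  measured or simulated data containing signal the transport models cannot
  represent (residual diffraction fringes at sharp interfaces), the least-
  squares fit otherwise pushes that misfit into high-frequency artifacts
  in `a`. The exact-inversion tests use `p = 2`; everything touching
  wave-optics data uses the default.
* **Hierarchical.** A dyadic coarse-to-fine schedule: data are 2×2
  box-averaged per level with the pixel size doubled (propagation distance
  unchanged; shifts in pixel units halve per level, so the coarsest
  problem is phase-free), the coarsest level is initialized with
  `-ln(data)`, and each finer level starts from the bilinearly upsampled
  coarser solution. Defaults: 7 levels, 30 CG iterations per level, 5
  spectral bands. Images not divisible by `2^(levels-1)` are edge-padded
  and cropped on return.

The stagnation tolerance defaults to `1e-10` relative misfit decrease;
high-precision convergence experiments set it to 0, since the splat
objective is piecewise-smooth (kinks where ray-traced corners cross cell
borders) and CG can stall and restart across kinks.

## Scintillator light deconvolution

The PSF ansatz `p(r) = (1-f) δ(r) + f g e^{-αr}/r` separates direct light
from the internally reflected, diffused fraction `f`; `1/r` is the 2-D
geometric spread, `α` the escape/absorption damping, and `g` is fixed by
unit kernel sum (so the tail mass is exactly `f`). The tail is defined for
`r ≥ 1` px; the central pixel carries the direct term. Default support is
the radius enclosing 99.9% of the tail mass; an undersized support raises
rather than silently truncating. Deconvolution divides by the kernel's
transfer function after edge-replicate padding by the support; the DC gain
is exactly 1 and the transfer function stays well away from zero for
`f < 1/2`, so no regularization is needed.

Fitting proceeds in two stages from a slit-collimated spot image: a
log-linear fit of `ln(r·halo(r))` for starting values, then joint
nonlinear refinement of `(f, α)` against the full model — the measured
direct spot (rescaled by `1/(1-f)`, self-halo-corrected in a second pass)
convolved with the tail, evaluated on the radial profile (default) or on
every halo pixel (`method='image'`). Radial bins are labeled by their
pixels' mean radius; partial edge bins would otherwise bias the steep
inner profile by several percent. Asymptotic standard errors come from the
Jacobian at the solution. In the pipeline, the kernel deconvolves the raw
projections *and* the flats before normalization.

## Synthetic data and what it does not emulate

Phantoms are unions of analytic elliptical primitives (optionally extruded
over detector rows), so projections are exact chord-length integrals with
no ray-marching error. Interfaces ramp linearly over a configurable edge
width (default 2 px, realized as nested sub-ellipses so projections stay
analytic): a sub-pixel-sharp edge is not representable by *any*
pixel-discretized forward model, and real interfaces imaged at tens of
microns per pixel are not mathematically sharp either. The bone-like
template is a dense convex shell with an internal array of dense discs
(refractive "lenses", the trabecular streak mechanism) plus weak-contrast
soft blobs; constants default to bone-minus-ethanol values at 109 keV with
`δ/β ≈ 1e3` and smooth power-law energy dependence (`δ ∝ E⁻²`,
`β ∝ E⁻³·⁵`).

The wave-optics oracle is band-limited angular-spectrum propagation at
each band's exact wavelength, with unitarity to rounding and a warning
when the transfer function is undersampled. The detector simulation
composes per-band Fresnel intensities, equal-area spectral weights,
Gaussian source-penumbra blur (from the confusion width
`source_fwhm · L / source_distance`), optional scintillator-halo
convolution, and Poisson noise from a single seeded generator; flats are
generated identically without the sample. Tomographic comparisons
supersample the simulation grid 4× and bin to detector pixels, because
physical detectors integrate sub-pixel fringes rather than point-sampling
them.

Not emulated: partial transverse coherence beyond Gaussian source blur,
detector MTF beyond the halo model, ring artifacts, rotation-axis error,
cone-beam geometry. Passing tests therefore demonstrate correctness of the
transport models and inversion on near-field, short-coherence data, not
robustness to those instrumental effects.

## Validation experiment design

* **Quadratic linear-limit scaling** is measured on a very smooth Gaussian
  phantom (σ = 24 px on 512², deflections up to 12 px at `a_max = 0.3`)
  against the wide-stencil TIE. The splat's piecewise-constant density
  representation adds a sub-pixel transport error `~ q² t(1-t)/2` that is
  first-order in amplitude for deflections below one pixel, so the scan
  must extend well into the multi-pixel regime for the physical
  second-order term to dominate the fit.
* **Wave-optics agreement** (≤3% RMS away from caustics) uses a smooth
  strong-gradient 256² blob at feature Fresnel number ≈ 600, 15 spectral
  bands on both sides; caustic pixels are flagged by the transport
  Jacobian `det(1 + ∂s/∂x)` leaving `[0.5, 2]` and dilated by 2 px.
* **Weak-phase recovery** (RMSE < 1% of the absorption range) runs at
  `L = 2 m`, 28 µm pixels — a deep-near-field, standard-beamline setting
  where residual diffraction fringes, which no transport model represents,
  are negligible.
* **Artifact suppression** compares the full eikonal pipeline against the
  Paganin baseline on a 256², 360-angle scan of the bone-shell phantom
  with ~2 px border deflections and ~70% peak absorption at `L = 8 m`,
  quasi-monochromatic around 109 keV with `δ/β = 992` — the
  monochromatic head-to-head that isolates the nonlinearity correction
  from spectral effects. Both methods retrieve a 32-row extruded strip per
  projection; the center row forms the sinogram. Scored on the standard
  deviation over the uniform embedding-fluid region inside the shell bore
  (streaks) and on slice RMSE against the analytic ground-truth density.

## Known limitations

* Sub-pixel transport: for deflections ≲ 1 px the area-weighted splat
  carries an `O(h)`-per-unit-shift representation error relative to exact
  transport; it is invisible against detector noise in practice but sets
  the noiseless model-fidelity floor.
* Near-caustic data contain genuine diffraction structure that the
  incoherent splat cannot reproduce; the spectral preconditioner keeps the
  least-squares fit from converting it into high-frequency artifacts, but
  rim-adjacent pixels remain the least accurate.
* The hierarchical schedule trades deep convergence for robustness:
  bilinear upsampling injects small high-frequency errors that the damped
  finest level polishes slowly; exact-inversion experiments therefore use
  a single level with more iterations.
* The solver assumes one dominant-gradient material pair (one `δ/β`);
  multi-material beam hardening beyond the band rescaling is not modeled.
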