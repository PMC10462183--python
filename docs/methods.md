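# Methods

This note documents the models implemented in `glycoscope`, the choices made
where the procedure was open, and what the synthetic-data tests do and do not
demonstrate about real data.

## Scanning-angle interference microscopy (SAIM)

### Forward model

A fluorophore at height `H` (nm) above the oxide surface of a silicon wafer
is excited by an s-polarized (TE) laser at incidence angle `θ_b` (measured in
the imaging buffer from the wafer normal). The direct and substrate-reflected
fields interfere, giving excitation probability

```
f(θ, H) = |1 + r_TE(θ) e^{iφ(θ,H)}|²
        = 1 + 2 Re(r) cos φ − 2 Im(r) sin φ + Re(r)² + Im(r)²,
φ(θ, H) = (4π / λ) n_b H cos θ_b,
```

with `r_TE` the TE reflection coefficient of the buffer / oxide / silicon
stack, computed from the oxide's 2×2 characteristic matrix

```
M = [[cos β, −i sin β / p₁], [−i p₁ sin β, cos β]],   β = k_ox d_ox cos θ_ox,
r_TE = [(m₁₁ + m₁₂ p₀) p₂ − (m₂₁ + m₂₂ p₀)] / [(m₁₁ + m₁₂ p₀) p₂ + (m₂₁ + m₂₂ p₀)],
```

where `p₀ = n_Si cos θ_Si`, `p₁ = n_ox cos θ_ox`, `p₂ = n_b cos θ_b` and the
refraction angles follow Snell's law through the stack. Silicon is absorbing:
`n_Si` is complex with `Im ≥ 0`, and complex cosines take the branch with
`Im(n cos θ) ≥ 0` so the transmitted wave decays into the substrate. The
tests validate this formula against an independently coded Airy
recursive-Fresnel summation to 1e−10 over wavelengths 488/560/642 nm, angles
0–60°, and oxide thicknesses 0–3000 nm, and against the analytic limits
(`d_ox = 0` → Fresnel; half-wave film invisible; perfect-mirror `r → −1`).

A measured pixel follows the affine model `I_j = A·f(θ_j, H) + B`, where `A`
absorbs illumination, dye density and detection efficiency, and `B` the
background. The standard acquisition grid is 32 angles evenly spaced from 5
to 43.75°.

Refractive indices are instrument-specific and configurable. The shipped
defaults are literature values (buffer ≈ 1.33, thermal oxide ≈ 1.46, silicon
4.37+0.08i / 4.04+0.03i / 3.85+0.02i at 488/560/642 nm); every test and the
acceptance script pin their own values so no result depends on the defaults.
Only TE polarization is modeled (the instrument maintains s-polarization with
a vortex half-wave plate); TM, aperture integration and emission-side
interference are out of scope.

### Inverse problem

The fit minimizes `Σ_j (I_j − A f(θ_j, H) − B)²` over `(H, A, B)`. Because
the model is linear in `(A, B)` at fixed `H`, the pair is profiled out in
closed form (2×2 normal equations), leaving a 1-D objective in `H`. That
profile oscillates with period `λ / (2 n_b cos θ)` ≈ 210–225 nm on the
standard grid, so single-start local optimization is unreliable. The fitter:

1. scans `H` on a coarse grid (default 1 nm steps over bounds [0, 300] nm),
2. keeps the best `n_seeds` (default 3) local minima of the coarse profile,
3. polishes each seed with a golden-section search bracketed one coarse step
   to either side, run for a fixed iteration count that brings the bracket
   below `xtol` (default 1e−5 nm, capped at 200 iterations).

Golden-section was chosen over a derivative-based step because the profiled
objective's curvature changes sign across the fringe and a fixed-iteration
bracketed search is exactly reproducible; the raw coarse seeds are retained
in the candidate set, so the returned optimum is provably no worse than any
seed. Among candidates whose SSE ties within 1e−9 relative, the smallest `H`
wins (determinism). Heights beyond the bounds alias into the admissible
window through the fringe period; the package reports the in-bounds solution
and leaves period disambiguation to the experiment design (the ~1900 nm
oxide and 300 nm window match practical glycocalyx imaging).

A pixel with constant intensities has unidentifiable `H` and is flagged
degenerate (`converged = False`); a negative fitted amplitude also clears the
converged flag. The quality mask additionally requires `A` above a
configurable floor (default 0). Determinism is bitwise: all per-pixel
reductions accumulate in a fixed order independent of how pixels are blocked,
so results are identical across repeated runs and worker counts.

Glycocalyx thickness is the mean dye-layer height minus the mean
fibronectin-reference height over a square subregion (default 100×100 px),
using only quality-masked pixels. ROI placement is user-supplied; the
package does not decide where cells are. Non-converged pixels are excluded
from subregion means via the quality mask.

## Phasor FLIM

A decay `I(t)` acquired over repetition period `T` maps to
`G = Σ I cos(nωt)/ΣI`, `S = Σ I sin(nωt)/ΣI` with `ω = 2πn/T`, `t` at bin
centers, harmonic `n = 1` by default. Mono-exponential decays lie on the
universal semicircle `(G−½)² + S² = ¼`; the phasor of a folded periodic
exponential equals the continuous closed form `G = 1/(1+(ωτ)²)`,
`S = ωτ/(1+(ωτ)²)` exactly, and bin-center sampling introduces only
`O((ωΔt)²)` error (≈2e−5 at 256 bins / 80 MHz). Note that arbitrary
non-negative signals are *not* confined to the semicircle — only mixtures of
exponential components are; the containment test uses such mixtures.

Calibration against a mono-exponential standard (Coumarin 6, τ = 2.5 ns)
multiplies each pixel's `z = G + iS` by `z_theory(τ_ref)/z_measured`,
removing the instrument phase delay and modulation loss in one complex
factor. The laser repetition rate is configurable (default 80 MHz, typical
of Ti:Sapphire two-photon sources).

The bound-NADH fraction `FB` of a pixel is the normalized orthogonal
projection of its calibrated phasor onto the chord from the free-NADH
endpoint to the bound-NADH endpoint, clipped to [0, 1]. Endpoints are
supplied either as explicit `(G, S)` pairs or as lifetimes (defaults 0.4 ns
free, 3.4 ns bound — commonly used values, configurable, never baked into
results).

Compartment segmentation follows a diffuse-background-subtraction scheme: a
large-kernel Gaussian (default σ = 16 px, much wider than an organelle)
estimates the cytosolic background, and residual signal above an Otsu
threshold inside the cell region is called mitochondrial; the rest of the
cell region is cytosolic. The masks are disjoint by construction. Vendor raw
formats are out of scope; ingestion is from TIFF time-bin stacks.

## Isotopologue arithmetic

For a metabolite with `n` carbons and isotopologue signals `M₀..Mₙ`:
relative amount `= Σ Mᵢ`; fractional contribution
`FC = Σ i·Mᵢ / (n Σ Mᵢ)`. FC is scale-invariant, always in [0, 1], and for a
binomially labeled skeleton (each carbon ¹³C with probability `p`) equals
`p` exactly by the binomial mean identity. Normalization to protein
concentration and cell number divides amounts and leaves FC unchanged.
Natural-abundance ¹³C correction is deliberately not applied — FC values on
real data therefore include the ~1.1% per-carbon natural background; treat
small FC differences accordingly. Missing isotopologue columns are treated
as zero signal with a warning.

## Synthetic data

Generators are pure functions of (parameters, seed) using
`numpy.random.default_rng`; regeneration is bitwise identical.

* **Height phantoms** — flat fields, half-plane steps, hemispherical bleb
  caps (Poisson-placed, emulating bleb-covered cell surfaces), and ridge
  networks (thresholded band-pass Gaussian field, skeletonized and dilated,
  emulating interconnected ridge-like projections).
* **SAIM stacks** — the exact forward model per pixel plus independent
  Poisson shot noise (physical for photon counting) or Gaussian read noise.
  Default study conditions in tests: the 32-angle 5–43.75° grid, ~1900 nm
  oxide, amplitudes giving ~10⁴ expected counts per pixel at high flux.
* **FLIM decays** — two-component exponential mixtures folded to the 12.5 ns
  period, with intensity-weighted bound fraction, an optional circular
  instrument time shift (mass-conserving fractional-bin interpolation), and
  multinomial photon sampling (total per pixel exact).
* **Isotopologues** — binomial ladders with optional lognormal multiplicative
  noise (mean-1 parameterization) at a stated CV, the standard model for
  multiplicative MS signal variation.

What the phantoms do *not* emulate: optical sectioning and PSF blur, camera
read noise beyond additive Gaussian, inter-channel drift, detector IRF shape
beyond a pure time shift, autofluorescence, chromatographic peak overlap, and
natural-abundance isotope background. Passing tests therefore demonstrate the
correctness of the computations under their stated models, not robustness to
every instrumental artifact of real acquisitions.

## Problem sizes and numerical choices

Test and acceptance runs use 100×100-pixel stacks for the thickness round
trip (one full subregion), 200 random pixels for recovery statistics, 256–
1024 time bins for phasor checks, and 32×32 FB images — sizes chosen so the
full suite completes in well under a minute on one core while keeping
Monte-Carlo error far below the tolerances checked. SSE values are clamped
at zero against roundoff; profile denominators are guarded against exact
zero (constant model curves); ties are broken toward smaller height. Empty
decay pixels yield NaN phasors rather than errors, and empty masks export
zero-count rows.
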