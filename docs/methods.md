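# Methods

## The model

The package implements a local interaction–redistribution model for
the areal phytomass density ρ(**r**, t) of a patch-forming dryland
grass:

∂ₜρ = −ρ(η − κρ + ρ²) + (Δ − Γρ)∇²ρ − αρ∇⁴ρ.

The kinetics −ρ(η − κρ + ρ²) balances growth against death (aridity
η > 0) with a facilitative quadratic term (κ) and cubic saturation.
Spatial redistribution has a linear seed-dispersion part (Δ∇²ρ) and
biomass-dependent parts (−Γρ∇²ρ, −αρ∇⁴ρ) representing the shortening
of the effective interaction range as local biomass grows.  Because
the diffusivities depend on ρ, no Lyapunov functional exists: the
dynamics is nonvariational, and only in the ρ-independent-coefficient
limit does it reduce to a variational Swift–Hohenberg form.

Assumptions inherited from this construction: no allometry (plant age
and size do not alter the interaction kernels), no life/death cycle
(a stable structure persists indefinitely), isotropic flat terrain,
periodic boundaries in all simulations.

Analytical structure used throughout:

- uniform states: bare soil ρ = 0 plus, for κ > 0 and η ≤ κ²/4, the
  vegetated pair ρ_s± = (κ ± √(κ² − 4η))/2, which coalesce at the fold
  (ρ_L, η_L) = (κ/2, κ²/4);
- dispersion about a uniform state: σ(k) = f′(ρ_s) − (Δ − Γρ_s)k² −
  αρ_s k⁴, with a finite-wavelength maximum k_c = √((Γρ_s − Δ)/(2αρ_s))
  whenever Γρ_s > Δ;
- marginality (max_k σ = 0) along the vegetated branch reduces to the
  cubic 4αρ²(κ − 2ρ) + (Γρ − Δ)² = 0; all real roots in (0, κ) are
  reported with η_c = κρ_c − ρ_c², sorted, none silently preferred
  (more than one threshold can exist).  Each returned root is verified
  against |σ(k_c)| < 10⁻⁸.

A note on conventions: the source material states the Turing
bifurcation "for η > η_L" although the uniform vegetated branch exists
only for η ≤ η_L.  The package takes no side: thresholds are reported
on the branch (η_c < η_L) and the bifurcation-diagram export carries
explicit stability flags instead of a direction convention.

## Reference parameters

All worked examples use η = 0.1 (0.08 for branch analysis), κ = 0.6,
Δ = 0.02, Γ = 0.5, α = 0.125, grid spacing dx = 0.5, time step
dt = 0.03 — the parameter set of the published figures.  At these
values the Turing threshold sits at ρ_c ≈ 0.512, η_c ≈ 0.045, and the
intrinsic wavelength is ≈ 4.6 length units.

## Numerics

**Schemes.**  Default: explicit Euler with 5-point periodic Laplacian
(biharmonic = Laplacian applied twice), matching the published step
count and dt.  Optional: a semi-implicit spectral scheme that treats
Δ∇² and a stabilising split of the biharmonic term (−αc∇⁴ with
c = κ) implicitly using the *discrete stencil symbol*, so both schemes
share one spatial discretisation; they agree to < 10⁻³ relative L2 at
t = 10 in the cross-check test.

**Step-size control.**  The explicit scheme is checked against a von
Neumann bound evaluated at the amplitude of the initial condition.
Freezing the bound at the theoretical maximum ρ = κ would reject step
sizes (including the reference dt = 0.03 at dx = 0.5) that integrate
stably in practice, because the worst-case amplitude never coincides
with the worst-case wavenumber in real fields.  Runaway integrations
are still caught by a finiteness guard that raises `BlowUpError`
naming the step.  Biomass is never clipped: the equation does not
guarantee positivity, and the minimum value is reported instead of
hidden.

**What counts as "a patch".**  Structures are 8-connected components
above half the *reference plateau* — the peak of a relaxed 1-D
localized solution at the same parameters (≈ 0.67 at the reference
set), computed once and cached.  This operationalises patch counting
without a published definition.

**Patch fate classification** (stability scan): after 5000 steps at
dt = 0.03, "decays" if the global maximum is < 10⁻³, "replicates" if
the patch count is ≥ 2, else "stable".  The default initial condition
is a Gaussian patch of e-folding radius 10 length units and amplitude
0.4: broad enough to feel the curvature instability.  With it the
classification is monotone along η (replicates ≤ 0.10, a narrow stable
window near 0.103, decay above ≈ 0.107), and the window bounds are
reported as midpoints of the bracketing grid values.  Two caveats are
intrinsic to the model, not the implementation: an equilibrium-sized
spot is stable over the whole range up to η ≈ 0.135 (self-replication
needs a broad patch), and at η ≲ 0.045 a broad patch grows as one
connected mass (front invasion) rather than splitting, so scans should
start above that regime.  A non-monotone label sequence is reported
with `consistent=False` and no bounds rather than guessed at.

## Synthetic scenes

The generator emulates the statistical structure of the tussock
imagery it replaces: patch centers from a homogeneous Poisson process
(default rate 0.002 per cell, ≈ 2000 patches on a 1000² grid), a
splitting fraction of 10% (the published initial condition used
185/1849) with stage s drawn uniformly and orientation uniform on
[0, π) to keep the scene isotropic.  A stage-s patch is the union of
two disks separated by s × max_separation, from one disk (s = 0) to
two disjoint disks (s = 1); the union area is continuous in s.
Overlapping patches are merged — the process is pure Poisson, with no
hard-core thinning — and the ground truth records merged components.

Field mode stamps smooth Gaussian bumps of amplitude 0.4 (the order of
the vegetated density; the published stamp amplitude is unspecified)
on a periodic domain.  Image mode renders sharp disks darker than a
bright background (default contrast 0.35 at background 0.75) with
additive Gaussian speckle, clipped to [0, 1], at 0.08 m/pixel, and is
*not* periodic — stamps are clipped at borders, as in a real photo.

Not emulated: terrain heterogeneity, illumination gradients, shadows,
plant morphology, young sub-resolution recruits.  Passing detection
tests on these scenes therefore demonstrates the correctness of the
chain on its stated contract (dark compact patches, moderate speckle),
not robustness to real-image nuisances.

## Statistics

- **NND**: minimal boundary-to-boundary Euclidean distance between
  patch boundary pixel centers; a patch is "valid" only if its NND
  does not exceed its distance to the nearest image edge (an off-image
  structure could otherwise be closer).  The KD-tree implementation is
  tested for exact equality against an O(n²b²) brute force.
- **Root sphere**: radius = mean r_eq + mean NND/2; area = πr²; ratio
  to the mean canopy area.  From the published survey means this gives
  1.415 m, 6.29 m², ratio 6.62 (the source rounds to 1.4 m / 6.3 m²
  and prints "6.7-fold"; the computed value is reported, not forced).
- **Spectrum**: mean-subtracted 2-D FFT of the largest centered square
  crop, amplitudes averaged over annuli one fundamental (2π/(N·dx))
  wide; the peak search excludes the DC and fundamental annuli, where
  domain-scale trends live; angular convention L = 2π/k throughout.
  No taper by default (a Hann option exists).
- **Voronoi**: cells kept only if bounded with all vertices inside the
  analysis window; per-cell vertex count and area (convex polygon),
  modal vertex count, six-sided fraction, mean area and its
  circle-equivalent radius.
- **Fits**: closed-form MLEs — Rayleigh σ̂ = √(Σx²/2n);
  inverse-Gaussian μ̂ = x̄, λ̂ = n/Σ(1/xᵢ − 1/μ̂) — with log-likelihood
  and a Kolmogorov–Smirnov statistic reported descriptively (no
  p-value claims).

## The extended-field experiment

The headline simulation statistic reruns the published recipe: a
1000 × 1000 scene (dx = 0.5) from the Poisson process above,
integrated for 5000 steps at dt = 0.03, thresholded at half the
reference plateau, segmented, and measured.  Lengths are reported in
grid cells — at the stated density the mean center-to-center spacing
is ≈ 11 cells, which is the only reading consistent with the published
mean NND of 9.5 (the dx-scaled value, also reported, is half that.)
Across seeds the measured mean boundary-to-boundary NND is ≈ 8 cells
(s.d. ≈ 3.4) over ≈ 1800 structures: inside one published standard
deviation of 9.5 (s.d. 4.7), with the residual offset attributable to
the equilibrium spot diameter of this reconstruction (the published
equation itself is not legible in the source, so the spot size could
not be matched exactly; boundary-to-boundary distances shift by one
spot diameter).

## Problem sizes

Tests run the full 1000² extended field once; the remaining
simulations use 64–200² grids and ≤ 5000 steps, sized so the complete
suite stays in the minutes range on one CPU while still exercising the
full-scale experiment.

## Known limitations

- Periodic wrap-around components in field-mode ground truth are not
  merged across the boundary (rare at the default dilution).
- The stability-scan boundaries are bracketing midpoints, not
  root-polished values; refine the η grid for sharper bounds.
- `analyze_image` computes the spectrum from the binary mask, not the
  grayscale; for patterns fainter than the binarization contrast the
  spectrum should be computed directly on the preprocessed image via
  `radial_spectrum`.
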