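# Methods

## Model and procedure

A soft specimen under uniaxial tension is observed through four surface
markers whose global 2D coordinates are known before and after each
elongation step. The four markers are taken as the nodes of one first-order
isoparametric quadrilateral element: geometry and displacement are
interpolated bilinearly in natural coordinates (ξ, η) ∈ [−1, 1]²,

    N_k(ξ, η) = ¼ (1 + ξ_k ξ)(1 + η_k η),   (ξ_k, η_k) ∈ {(−1,−1), (1,−1), (1,1), (−1,1)},

with the corner signs matching the counterclockwise vertex order. The
deformation gradient at a point is

    F(ξ, η) = I + (∂u/∂ξη) J⁻¹,    J = ∂X/∂(ξ, η),

where u is the interpolated vertex displacement and J the Jacobian of the
initial configuration. Strain follows from F by one of three measures
(small: sym F − I; Green–Lagrange: (FᵀF − I)/2; Biot: √(FᵀF) − I), the
principal strains ε₁ ≥ ε₂ come from the closed-form 2×2 symmetric
eigendecomposition, and Poisson's ratio is ν = −ε₂/ε₁. Elongation is
reported as 100·ε₁, which coincides with grip-to-grip engineering strain
for an aligned specimen and is misalignment-free in general.

The assumptions, in decreasing order of importance:

1. **Homogeneity** — the material between the markers deforms affinely.
   Any non-affine (hourglass) content makes the single-element strain an
   average; the heterogeneity diagnostic (maximum Frobenius distance
   between the Gauss-point tensors and the centroid tensor) quantifies it,
   and is exactly zero for an affine step.
2. **Plane kinematics** — only in-plane strain is measured; through-thickness
   contraction is invisible to the method.
3. **No rotation during deformation** (small measure only) — the default
   small-strain measure is exact under any *common* rigid motion of both
   configurations, but a rotation acquired *between* the reference and the
   deformed image biases it. The Biot measure is rotation-polar by
   construction: its principal values are stretch − 1, so −ε₂/ε₁ is the
   engineering ν regardless of such rotation. Green–Lagrange is likewise
   rotation-invariant, but its principal-value ratio is a finite-strain
   quantity, not the engineering ν (at 40% stretch with ν = 0.2 it gives
   0.16, because ε_GL = (λ² − 1)/2); it is provided for strain reporting,
   not for ν extraction at large strain.

Small strain is the default because the validation values it must reproduce
(ε₁ = 0.4, ε₂ = −0.08, ν = 0.2 at 40% axial strain) are defined on the
engineering scale, and because per-step rotation is negligible in a gripped
tension test.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| strain measure | `small` | — | engineering-scale validation values; see above |
| evaluation mode | `centroid` (ξ=η=0) | — | single-value-per-element reporting; `gauss_mean` averages the 2×2 Gauss points and is the QC option |
| tol | 1e-6 | strain | floor on \|ε₁\| below which ν is undefined (undeformed specimen); also the floor on naive-method denominators |
| pixel_scale | user input | mm/px | from a reference distance; deliberately never estimated implicitly, so calibration stays auditable |
| camera_origin_offset | (0, 0) | mm | the method uses only coordinate differences, which are offset-invariant |
| flip_camera_y | true | — | image rows increase downward; ingest flips to the mathematical convention to avoid a silent sign error in θ |

Degenerate inputs: self-intersecting marker sets are rejected; simple but
non-convex ("dart") quads are accepted as long as the Jacobian at the
evaluation point is positive (evaluation at a folded point raises an error
naming the offending (ξ, η); in centroid mode an unevaluable Gauss-point
diagnostic saturates the heterogeneity score to ∞ rather than failing the
step). Equibiaxial strain (ε₁ = ε₂) legitimately yields ν = −1 and attaches
a warning, since the principal direction is then undefined. Vertices are
canonically reordered counterclockwise from the lexicographically smallest
initial vertex, with the deformed quad following by marker label, which
makes every result invariant to marker relabeling and input order.

## Calibration

θ (stage–camera angle) is estimated from an axis sweep by total least
squares — the dominant singular vector of the centred camera track — because
both camera coordinates carry comparable error. The angle of an undirected
line lives on a half-circle, so estimates are normalised to (−π/2, π/2] and
several per-axis estimates are averaged in the doubled-angle representation.
The sweep generator and the estimator share one sign convention (a track
synthesised at angle θ re-estimates to θ); on physical hardware the sign
must be checked once against a known stage motion, exactly as the camera
y-flip must.

## What the synthetic generator emulates — and what it does not

`apply_deformation` produces a homogeneous stretch diag(1 − ν·ε, 1 + ε)
along a material axis tilted by θ from the global y-axis, optionally
composed with a rigid rotation/translation and additive iid Gaussian
coordinate noise (centroiding error). Defaults mirror the physical regime
the method targets: a 10 × 3 mm marked footprint, axial strains up to ~0.5,
misalignments up to ~32°, ν near 0.44. The noise default used in the
stochastic recovery demonstration is sd = 0.005 mm, i.e. 0.1 px at the
0.05 mm/px default pixel scale — the order of subpixel centroiding error.

The generator is exactly affine, so passing tests show correctness of the
kinematics, invariances, and noise behaviour; they do **not** show that a
real specimen deforms homogeneously, that real ink spots centroid as well as
rendered Gaussian profiles (real spots are irregular; only centroiding
accuracy, not appearance, matters downstream), or anything about
time-dependent material behaviour (water loss in hydrogels slowly lowers ν
during a long experiment — out of scope here). Reported laboratory values
for PVA hydrogel (ν ≈ 0.44 ± 0.025 over 2.6–47% elongation) require
physical specimens and are emulated only qualitatively by the synthetic
sweep.

Spot images are rendered as Gaussian profiles (background + peak, optional
photon noise); detection thresholds at background + frac·(max − background),
labels 8-connected components, and returns intensity-weighted centroids with
a roundness quality score (minor/major inertia axis ratio) that flags merged
spots closer than ~2σ.

## Numerical choices

* Principal strains use the closed Mohr's-circle form (centre ± radius,
  angle = ½·atan2(2ε_xy, ε_xx − ε_yy)), verified against a general
  symmetric eigensolver to 1e−12.
* The Biot measure computes √(FᵀF) via eigendecomposition of FᵀF.
* The naive baseline averages per-marker axial strains and transverse
  ratios arithmetically over the four markers — the simplest unbiased
  aggregation, fixed so that the bias demonstration is reproducible.
* Sweeps evaluate every step against the original reference configuration
  (total strain, not incremental); per-step failures are reported in the
  output row, not raised.
* All randomness flows through explicit integer seeds (numpy Generator);
  identical seeds give bit-identical fixtures.

## Problem sizes

Deterministic validation cases run on a single 4-marker element and finish
in milliseconds. The property suite uses 100 random rigid transforms, 25
random quads for the affine oracle, a 4 × 4 × 5 (ε, ν, θ) recovery grid,
and 10⁴ natural-coordinate points for the shape-function checks. The
stochastic recovery study uses 500 replicates per scenario at sd 0.005 mm.
These sizes give comfortable statistical margins (the element-method bias
bound is ~25× below the 3·SE threshold at 500 replicates) while keeping the
whole suite under a few seconds.

## Known limitations

* One element only: no meshing, no higher-order elements, no stress or
  constitutive modelling (displacements are prescribed, so none is needed).
* No lens-distortion or perspective correction in calibration — the camera
  model is rotation + isotropic scale + offset.
* The naive baseline requires markers away from the loading axes (its
  denominators are marker coordinates); the element method has no such
  restriction.
* ν(t) drift, 3D thickness effects, and physically realistic ink-spot
  appearance are out of scope.
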