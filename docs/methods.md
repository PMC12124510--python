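# Methods

This note records the models implemented in `fiberalign`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic-data
generators do and do not emulate.

## Polarized Raman branch

**Preprocessing.** The chain is fixed: (1) baseline subtraction by iterative
modified polynomial fitting (modpoly) of order 11 — the polynomial is fitted,
the working curve replaced by the pointwise minimum of itself and the fit,
and the loop repeats until the baseline moves by less than 10⁻⁶ of the
intensity range or 100 iterations are reached (the iterate is then returned
with a warning; modpoly converges geometrically and the residual drift after
100 iterations is far below the band amplitudes); (2) Savitzky–Golay
smoothing with a 3rd-order polynomial and an 11-point frame; (3) standard
normal variate normalization with the sample (n−1) SD; (4) cropping to the
closed 1400–1800 cm⁻¹ window. The crop comes last so smoothing edge effects
fall outside the analysis window; replicate averaging (12 shots per point)
happens after SNV so each shot is normalized before pooling, which makes the
average robust to per-shot intensity drift. Both the averaging switch and
the SNV-vs-averaging order are exposed in `PreprocessConfig`.

**Master loading.** PCA is fitted once on a preprocessed reference library
of highly aligned muscle-type spectra; test spectra are centered by the
*reference* mean and projected onto the *reference* PC1. This fixed affine
map is the only construction that makes scores comparable across samples
and runs. The PCA sign ambiguity is pinned by requiring a non-negative
coefficient at the grid point nearest 1665 cm⁻¹ (amide-I C=O), which makes
loadings, scores and fitted phases reproducible.

**Sine fit.** The model PC1₀ + A·sin(π(φ−φc)/90°) is linear in
(PC1₀, A cos Φ, −A sin Φ) with Φ = πφc/90°, so the least-squares problem is
solved in closed form; A ≥ 0 and φc ∈ [0°, 180°) select the unique branch
(the (−A, φc+90°) branch is equivalent). No iteration, initialization or
multi-start is needed — the linear solution *is* the global optimum. The
phase is unidentifiable as A → 0, so fits with A < 2·RMSE are flagged
`aligned = False` and `alignment_angle` refuses them. By default one sine is
fitted per measurement point and the per-location amplitude is summarized as
mean ± SD with a Student-t 95 % CI (t₀.₉₇₅,₂₁ = 2.080 at the protocol’s
n = 22); a pooled mode fits all points of a location jointly.

## Discrete-fiber branch

Fiber angles are axial (period 180°); all statistics double the angles. The
mean fiber axis is the major axis of the second-order orientation tensor,
equivalently ½·atan2(⟨sin 2θ⟩, ⟨cos 2θ⟩). The alignment index
S = ⟨cos 2(θ − θ̄)⟩ equals the doubled-angle resultant length, so S ∈ [0, 1]
with 0 for isotropy; a zero resultant (e.g. {0°, 90°}) leaves the axis
undefined and is flagged. Fibers are counted, not length-weighted (a
length-weighted mode exists, off by default). The angular SD is the axial
circular SD (circular SD of doubled angles, halved), with the arithmetic SD
of signed deviations reported alongside; the axial convention is the
primary one because it behaves correctly near the wrap point.

## Contraction model

**Kinematic split.** Cell traction is modeled as a stress-free isotropic
shrinkage of the cell-laden material: F = F_e F_s with F_s = (1 − εs)·I.
εs is stored as a positive magnitude (εs = 0.6 means stress-free stretch
0.4); an unconstrained patch contracts exactly to that stretch with zero
stress and zero energy (verified to machine precision by the patch test).
The strain energy is compressible neo-Hookean in the elastic part,
ψ = E/(4(1+ν))(Ī₁ − 3) + E/(6(1−2ν))(J_el − 1)², with Ī₁ the isochoric
first invariant and J_el the elastic volume ratio; E = 700 Pa and ν = 0.4
are literature values for collagen gel. Total potential energy integrates
J_s·ψ over the reference domain (J_s = (1−εs)³ maps intermediate to
reference volume); J_s is piecewise constant so it does not alter the
equilibrium of an all-cell mesh.

**Plane stress.** Sample thickness (1 mm) is small against its length, so
plane stress is enforced pointwise: at each quadrature point the
out-of-plane elastic stretch solves dψ/dλ₃ = 0 by a damped scalar Newton
iteration (tolerance 10⁻¹² on the stress residual relative to the moduli).
By the envelope theorem the in-plane first Piola stress is then simply
∂ψ/∂F_e evaluated at that stretch, which keeps the residual analytic.

**Geometry and boundary conditions.** The dog-bone's cell-laden gauge strip
is 4 mm wide and spans 10 mm between the two PDMS anchor bars; the
anchor-interface ends are fully fixed and the long lateral edges free. (The
anchors are 10 mm apart by construction of the mold; the perpendicular
orientation — 10 mm wide strip with a 4 mm span — pins the long edges and
suppresses all central necking, contradicting every measured alignment
pattern.) An `include_wings` mode meshes the passive anchor-bar gel pinned
on its outer boundary instead, for sensitivity analysis.

**Discretization and solver.** 4-node bilinear quadrilaterals with full 2×2
Gauss quadrature — at ν = 0.4 under plane stress there is no locking risk.
The default element size is 100 µm (40 × 100 = 4000 elements), at which the
mid-strip alignment factor is mesh-converged to well under 2 % against the
200 µm mesh. Equilibrium is solved total-Lagrangian: the load ramps in
increments (halved up to 5 times on divergence or element inversion) with a
Newton iteration per increment to a relative residual of 10⁻⁸. The element
internal force is the exact gradient of the element energy (checked against
central finite differences at random states, relative error < 10⁻⁵); the
tangent is assembled by forward differences of the element force vector —
8 vectorized force evaluations per iteration — which costs a negligible
accuracy penalty at this tolerance and avoids hand-deriving the
plane-stress-condensed material tangent.

**Shrinkage fitting.** The best-fit εs minimizes |simulated − measured|
area shrinkage of the cell region (polygon area of the deformed boundary)
over a grid with step ≤ 0.05, ties toward smaller εs. The grid is swept by
continuation — each level warm-starts from the previous equilibrium — so
the sweep costs one ramped solve; predicted shrinkage is monotone in εs
over the sweep range, making the grid minimum unambiguous.

## Local kinematics and the cross-modality bridge

At each quadrature point F is polar-decomposed via the eigendecomposition
of FᵀF (U = √(FᵀF), R = F U⁻¹; cross-checked against an SVD construction at
10⁻¹⁰). A seeded circle of radius r = 0.05 mm deforms into an ellipse with
semi-axes r·λ_max, r·λ_min; α = λ_max/λ_min and β_model is the principal
direction of F Fᵀ (the spatial major axis, equal to R applied to U's major
eigenvector), reported on [0°, 180°) with the inter-anchor axis at 90°.
α and β are invariant to the seed radius and to uniform scaling of F;
isotropic points (λ_max = λ_min) carry an undefined-angle flag.

The equivalent alignment index embeds n = 150 fibers at uniform reference
angles i·180°/n, pushes each tangent through F, and recomputes S. For pure
stretch with ratio α this converges to S = (α−1)/(α+1); at n = 150 the
deviation is below 0.02, which is how the model's (α, S) pairs — e.g.
(7.8 → 0.77) and (3.5 → 0.56) — relate to the imaging-scale S values.

**Region sampling.** The CE/ME/MC element coordinates are a package
convention (exposed in `alignment_map(..., sampling_points=...)`): the two
edge locations sit in the element row adjoining the free lateral edge —
matching the imaged edge fields of view — with CE one element inset from
the anchor interface, ME at mid-length, and MC at the strip center. Region
values average α and β (axially) over the element's quadrature points; the
equivalent S uses the quadrature-mean F. The four corners are equivalent up
to mirror symmetry (β ↔ 180° − β); the CE default reports the corner whose
major axis lies in the (90°, 180°) half-plane, the convention of the
corner-edge images. ME and MC are computed separately and their agreement
is asserted in tests, not assumed.

## Synthetic data

The generators are pure functions of (parameters, seed). Spectra are sums
of Gaussian bands at 1445/1465/1605/1656/1675 cm⁻¹ on the 1400–1800 cm⁻¹
acquisition grid, a smooth polynomial fluorescence/PBS baseline, and i.i.d.
Gaussian noise; the amide-I band heights are modulated with polarization as
height·(1 + m·sin(π(φ−φc)/90°)), the same 180°-periodic law the sine fit
assumes, so (m, φc) are recoverable ground truth. The acquisition emulator
reproduces the acquisition protocol's counting structure: 11 points × 2 ROIs × 12
replicates = 264 spectra per location, the replicates cycling the six
polarization angles twice, with point-to-point modulation-depth jitter
(6 % relative) supplying the between-point variability that the CI
summarizes. The reference library spans 110 angles with strong amide-I
modulation so its first principal direction is the modulation axis. Fiber
angles are drawn from an axial wrapped normal, chosen over a von Mises
because its closed form E[cos 2θ] = exp(−2σ²) gives an analytic oracle for
S (σ = 25° → S ≈ 0.683).

What the generators do *not* emulate: Voigt band shapes, shot noise,
cosmic rays, water/glass backgrounds beyond a smooth polynomial,
non-sinusoidal polarization response, spatially correlated fiber
populations, or non-affine fiber-network kinematics. Passing tests
therefore demonstrate estimator correctness under the model's own
assumptions — recovery of phase, relative amplitude, S and mean axis — not
robustness to every instrument artifact of real acquisitions.

## Known limitations

* The continuum model assumes perfectly embedded, affinely convected
  fibers; discrete-network non-affinity is outside its scope.
* No time-dependent remodeling or cell-density evolution; the shrinkage
  strain is spatially uniform within the cell-laden region.
* The PRS amplitude A is in score units and depends on the reference
  library; only ratios (γ) are comparable across setups.
* Angular resolution of the PRS branch is limited by the 30° polarization
  increment; fitted phases inherit roughly ±15° uncertainty in practice.
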