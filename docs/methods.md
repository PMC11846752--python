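# Methods

This note documents the models implemented in `bonerom`, the numerical
choices behind them, and what the synthetic test problem does and does not
demonstrate.

## Mesh morphing

New implant poses are generated by harmonic extension: each coordinate of
the morphed mesh solves the discrete Laplace equation (linear simplex FEM,
scalar stiffness `K`), with Dirichlet data on two node sets — the fixed
outer boundary Ω₁ and the rigidly transformed implant-plus-interface set
Ω₂.  Partitioning `K` by (Ω₁, Ω₂, interior) and condensing out the known
rows gives

    x₃(μ) = −K₃₃⁻¹K₃₁ p_Ω₁ − K₃₃⁻¹K₃₂ H_Ω₂ᵀ T_dirᵀ(μ),

where `H_Ω₂` stacks the homogeneous reference coordinates of Ω₂.  Both
products are precomputed per coordinate direction and `K₃₃` is factorised
once (scipy `splu`; a direct sparse LU — reused for every pose, which is the
point of the construction), so a pose evaluation reduces to building the
(d+1)×(d+1) transform and two small mat-vecs per direction.

Conventions the implementation fixes where the formulation leaves freedom:

* **Transform composition** is `T = R_x R_y R_z D` with the rotation-matrix
  sign conventions exactly as in the classical homogeneous form used here;
  the translation is applied first and hence rotated.
* **Rotation centre**: rotations act about the centroid of the Ω₂ node set
  (translated to the origin and back).  Any fixed centre is admissible; the
  centroid keeps small rotations producing small displacements.
* **Angles are degrees** at every interface, converted internally.
* **Interface ring**: Ω₂ contains every node of every implant-labelled
  element plus one layer of adjacent bone nodes (the analogue of including
  the resection-plane nodes), which moves the immediate bone interface
  rigidly and keeps the transition smooth.
* **Quality and repair**: after morphing, any element whose signed volume
  falls below `tol = 0.01` of its reference volume is flagged.  Inverted
  elements get their last two node indices swapped — a pure orientation fix
  that never moves nodes.  An element that needed that fix and still sits
  below the volume tolerance (or any element left non-positive) aborts the
  morph with an error naming the offenders; merely squeezed elements are
  reported but tolerated.

Invariants checked by the tests: identity pose reproduces the reference to
round-off; Ω₁ is bit-identical across poses; Ω₂ pairwise distances are
preserved to 1e−10; the interior satisfies the discrete Laplace system to
1e−8; the condensed path agrees with a dense full-system solve to 1e−10;
interior coordinates obey the discrete maximum principle per direction.

## Bone remodelling model

Small-strain, quasi-static, isothermal.  Stiffness follows a power law in
density, `E = E₀ (ϱ/ϱ₀)²`, giving the constitutive law
`σ = (ϱ/ϱ₀)² C^LE : ε` and strain energy density

    Ψ(ϱ, ε) = (ϱ/ϱ₀)² [ λ/2 tr(ε)² + μ tr(ε²) ].

Mass balance with a first-order source drives the density toward the
homeostatic target `Ψ^ref`:

    ϱ̇ = c (Ψ − Ψ^ref),  clamped to [ϱ_min, ϱ_max].

Defaults (mixed mm–N–(g/cm³) units): E₀ = 6500 N/mm², ν = 0.3,
ϱ₀ = 1 g/cm³, Ψ^ref = 0.002 N/mm², c = 0.01, ϱ_min = 0.001,
ϱ_max = 2.0, α_GE = 0.01, β_GE = 1e−8; the implant phase is linear elastic
titanium (E = 105000 N/mm², ν = 0.3) with frozen density.  The enhancement
coefficients' nominal SI units are used verbatim as in-context
coefficients; no unit conversion is applied (bookkeeping by convention).
2D problems are treated as plane strain with the 3D Lamé pair, so a
confined uniaxial state has identical energy in 2D and 3D.

**Gradient enhancement.**  Stationarity of the penalty energy
`α_GE/2 (φ − ϱ)² + β_GE/2 |∇φ|²` with respect to the nodal field φ yields
the screened L2 projection `(M + (β_GE/α_GE) K_lap) φ = M·ϱ`, assembled
with the consistent mass matrix.  β_GE = 0 recovers the plain consistent
L2 projection exactly.  Two consequences worth knowing: (i) with the
tabulated β_GE/α_GE = 1e−6 the smoothing length is far below the element
size of the desk-scale meshes, so the enhancement damps nodal variance only
slightly (the tests verify the strict inequality on a checkerboard); and
(ii) a consistent-mass projection of a near-binary element field overshoots
— the nodal φ can leave [ϱ_min, ϱ_max] by O(field jump).  The element
densities themselves are always clamped; φ is the visualisation/snapshot
field and inherits the overshoot.  The enhanced-field value interpolated to
an element (vertex mean) is floored at ϱ_min before entering the energy.

**Time stepping.**  Staggered scheme per pseudo-time step: solve mechanical
equilibrium at frozen density (linear at fixed ϱ; the Newton wrapper
converges in one iteration and asserts it), project φ, then update
`ϱ ← clip(ϱ + Δt·c·(Ψ(ε_new, φ_new) − Ψ^ref))` using the new strain and the
new enhanced density, matching the implicit-Euler argument structure.
Convergence is declared when the relative L2 change of φ between steps
drops below `density_tol` (default 1e−5); `max_steps` (default 500) bounds
the horizon, with a warning and an honest `converged=False` otherwise.
Dirichlet conditions are imposed by elimination; tractions are integrated
with linear shape functions on boundary facets.

**Stability of the remodelling law.**  Because Ψ grows with ϱ at fixed
strain, the source has positive feedback under displacement control: the
uniform steady state ϱ* = ϱ₀√(Ψ^ref/ψ^LE(ε)) of a strain-held bar is a
repeller, and a displacement-driven specimen runs to a density bound.
Under load control the feedback is negative (stiffer bone → less strain →
less stimulus) and the same closed-form density is the stable attractor.
The package's bar benchmark is therefore load-controlled: a confined bar
(lateral displacement blocked, one end held, end traction 4.0 N/mm² with
the default parameters) converges from ϱ₀ to exactly

    ϱ* = 4/√35 ≈ 0.6761234 g/cm³,  ε_eq = 1e−3,

which the tests check to 1e−4 relative.  The bar uses Δt = 2000 (the
linearised contraction rate near ϱ* is c·2Ψ^ref/ϱ* ≈ 5.9e−5 per unit
process time, so the default Δt = 10 would need tens of thousands of steps;
the explicit stability bound for this fixture is Δt ≲ 3.4e4).

**Convergence on the plate problem.**  With a stiff inclusion under
compression the local remodelling law forms trabecular-like load-bearing
columns; element densities become near-binary, and interface elements keep
exchanging roles indefinitely (the per-step relative change of φ plateaus
at ~1e−3·(Δt/500) instead of decaying).  This sustained reorganisation is a
known feature of local strain-energy remodelling with only mesh-scale
regularisation.  The campaign therefore runs a fixed process-time horizon
(Δt = 500, 300 steps, i.e. T = 1.5e5) and stores the final φ; the map from
pose to φ(T) is deterministic and smooth enough for reduction, and the
non-converged status is reported rather than hidden.

## POD

Thin SVD of the raw snapshot matrix (no mean-centring).  The mode count is
the smallest `n` whose squared singular values capture strictly more than
the energy fraction κ (default 0.9999).  The truncation error is the
relative tail energy `ε(n) = sqrt(Σ_{i>n} ςᵢ² / Σ ςᵢ²)` — the printed form
of that formula in the source literature has inconsistent summation limits,
and the standard tail-energy reading (which equals the relative Frobenius
reconstruction error, verified against a direct oracle) is used.  SVD sign
ambiguity is fixed deterministically: each mode is scaled so its
largest-magnitude entry is positive.

## RBF interpolation

Pose parameters are min-max normalised to [0, 1] from the training bounds
before any distance is computed (the alternative z-score scheme would work
equally; min-max was chosen as the simplest invertible map), and all
distances are Euclidean in the normalised space.  Six kernels are
implemented (Gaussian, multiquadric, inverse multiquadric, Matérn C0/C2/C4);
the plain interpolation matrix is solved directly with no regularisation
jitter, and a 1-norm condition estimate above 1e12 raises a warning —
ill-conditioning at small shape parameters is surfaced, not silently
patched.  Augmentation appends the degree-1 tail {1, μ̂₁, …, μ̂_np} with the
usual moment side conditions in a symmetric block system; it is required
for the multiquadric (only conditionally positive definite — requesting it
plain warns) and gives exact affine reproduction for every family.  The
pipeline default is the augmented Matérn C0 with shape a = 1e−4; the
shape-parameter sweep (MAE on a holdout split over a kernel × shape ×
augmentation grid, ties toward smaller a) can override it.

## Surrogate and diagnostics

The offline stage runs the high-fidelity pipeline at every training pose
(equidistant tensor grid, endpoints included; three points per dimension by
default — six parameters give 729 poses), stores the final nodal φ as a
snapshot column, excludes failed poses with a log entry rather than
imputing them, and ties snapshot and parameter columns with a SHA-256
checksum.  Holdout validation re-runs the solver at seeded pseudorandom
poses and reports overall and per-zone mean absolute error
`e = (1/n)Σ|φᵢ − φ̃ᵢ|`.  Zone-wise diagnostics partition the bone elements
into a distal band plus equal-height medial/lateral bands along the implant
axis — a deliberately simple, machine-checkable stand-in for the clinical
periprosthetic zones.  Mass change per zone uses element-centre density
(vertex mean of φ) times element volume; global sensitivity is Spearman's
rank correlation (average ranks on ties; constant inputs yield NaN, never a
silent zero) between each pose parameter and each zone's percent mass
change.

Model containers are single HDF5 files holding the basis, interpolant,
reference mesh and provenance, with a version tag and SHA-256 payload
checksum; HDF5 timestamps are disabled so identical campaigns produce
byte-identical files.  The morph operator is rebuilt deterministically from
the stored mesh at load time instead of serialising the factorisation.

## Synthetic test problem

The reference geometry is a 20×20 mm plate (2048 triangles) with a
5×10 mm implant inclusion, roller-supported at the base and loaded by a
uniform 5 N/mm² compression on the top edge; initial density decays from a
cortical-shell-like 1.4 g/cm³ at the boundary to 0.8 g/cm³ in the core.
The load magnitude puts the far-field stimulus near Ψ^ref so both apposition
(along the load paths flanking the stiff inclusion) and stress-shielding
resorption (above/below it) occur; the most shielded zone loses a median
≈ 78 % of its mass across the training campaign.  A coarse 3D box-with-
inclusion fixture exercises the tetrahedral code path.

What this emulates: fixed-connectivity pose parameterisation, shielding-
driven density redistribution around a stiff inclusion, and the full
offline/online reduction loop.  What it does not: real femoral geometry and
cortical/trabecular architecture, CT-derived initial BMD, physiological
muscle-force systems, or press-fit interface mechanics.  Accuracy numbers
on this problem (holdout MAE ≈ 1 % of the field's dynamic range with a 3×3
grid over δx, δy ∈ [−1, 1] mm) demonstrate the machinery, not clinical
fidelity.

## Known limitations

* The enhanced nodal field φ can overshoot the physiological density bounds
  near sharp element-density jumps (consistent-mass projection; see above).
* The tabulated gradient-enhancement strength is negligible at desk-scale
  element sizes, so checkerboard suppression is only marginal here.
* Plate campaigns stop at a fixed process-time horizon rather than a strict
  fixed point (interface chatter of the bang-bang density pattern); the bar
  benchmark converges to machine-level tolerance.
* Problem sizes in the tests (2048 elements, 9–25 training poses, 10
  holdout poses) were chosen as the smallest configurations that exhibit
  all qualitative features; larger campaigns only change cost, not code
  paths.
* Implant size/shape is not a parameter; only rigid-body pose is.
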