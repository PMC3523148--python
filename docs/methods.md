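# Methods

## Model

The package solves the stationary conductivity equation
−∇·(σ∇u) = 0 on the square Ω = (−0.1, 0.1)² with piecewise-constant
conductivity: background σ₀ in the saline, σ_A in a thin anomaly
region A built from annular "cells".  Each cell is a ring of outer
radius 0.01 and thickness δ = 0.002; holes of diameter 0.005 are
removed from the ring so ions can pass.  Defaults σ₀ = 1, σ_A = 0.001
give a contrast ratio ε = σ_A/σ₀ = 10⁻³, the regime where the
membrane dominates the apparent conductivity.  The model is a 2-D
idealisation of a stable phantom: an insulating thin cylinder with
holes immersed in homogeneous saline.

A hole is the open disk of the stated diameter centred on the ring's
mid-circle (radius 0.009) at its stated angle; ring material inside
the disk is replaced by background saline.  The annulus is closed and
holes are open — a measure-zero convention fixed so point tests are
deterministic.  An alternative reading (an angular sector cut through
the ring) was implemented as a probe and changes solver behaviour
negligibly; the disk convention is the package's convention.  Multi-
cell layouts place 9 or 25 identical cells on a 3×3 or 5×5 grid with
centre-to-centre spacing 0.04, keeping every ring strictly inside Ω
and pairwise disjoint.

## Discretisation

Ω is triangulated by an N×N structured grid, each square split along
its lower-left→upper-right diagonal (2N² congruent right triangles,
h = 0.2/N).  This yields the classical 5-point stencil for the
P1 stiffness matrix and bit-deterministic assembly.  The mesh is
deliberately *not* boundary-fitted: triangles straddle the membrane,
and the discontinuity is carried entirely by quadrature.  This smooths
the microscopic structure at the scale of one element — intentional,
since the quantity of interest is the apparent macroscopic field, not
a sharp interface resolution.

Splitting σ = σ₀ − σ̃_A with σ̃_A = (σ₀ − σ_A)χ_A gives two matrices on
the free nodes (interior + Neumann-edge):

* K — gradients only, conductivity-free;
* K_σ̃A — the same integrand weighted by (σ₀ − σ_A)χ_A, supported on
  membrane-crossing triangles.  K_σ̃A is positive *semi*definite: it
  vanishes on triangles missing A.

P1 gradients are constant per triangle, so the only nontrivial
integral is the intersection area |A ∩ τ|.  It is estimated by
composite Gaussian quadrature: the triangle is subdivided into
4^L congruent subtriangles, each carrying the interior 3-point
degree-2 rule, and χ_A is averaged.  The default level makes the
subtriangle diameter ≤ δ/4, i.e. L = max(1, ⌈log₂(4·h·√2/δ)⌉); at
N = 16 this is L = 6 (12 288 points per crossing triangle) and the
summed intersection areas reproduce the polygon-clipped membrane area
to ~3·10⁻⁴ relative.  The clipping oracle (shapely, circle polygons
refined until the area changes < 10⁻⁶ relatively) exists only for
validation and never feeds the solver.

Boundary data: Dirichlet rows/columns are eliminated; their columns of
the full matrix σ₀K − K_σ̃A multiply the prescribed values and move to
the load, together with the line integral of the Neumann flux against
edge hat functions (per-segment 3-point Gauss, exact through quartic
data).

### Canonical injection

The canonical "horizontal injection" is a voltage drive: u = 1 on the
left edge, u = 0 on the right, zero flux on top/bottom (vertical =
the 90°-rotated analogue).  Electrodes spanning a full edge are
equipotential surfaces, which makes Dirichlet data the physically
natural electrode model, and under this drive the solver reproduces
the published multi-cell iteration counts that a Neumann unit-flux
drive does not.  The flux realization remains available
(`BoundaryCondition.*_flux_injection`, config key `bc_style: flux`).
By linearity the drive amplitude is immaterial to every relative
quantity reported.

## The iteration

Algorithm: factorise σ₀K once (sparse LU, minimum-degree ordering);
start from the homogeneous solution U⁽⁰⁾ = (σ₀K)⁻¹g; repeat
σ₀K U⁽ⁿ⁺¹⁾ = g + K_σ̃A U⁽ⁿ⁾ until the Euclidean relative change over
the free nodes drops below tol (default 10⁻⁶, the published stopping
rule); cap at 10 000 updates and flag non-convergence rather than
raising.  The homogeneous initial guess is deterministic and makes
the relative-change denominator nonzero from the first update; the
reported iteration count is the number of updates performed after it.

Errors obey E⁽ⁿ⁺¹⁾ = (σ₀K)⁻¹K_σ̃A E⁽ⁿ⁾.  With
γ = max_τ |A∩τ|/|τ| and ε = σ_A/σ₀, the spectral norm of the
iteration matrix is bounded by γ(1 − ε): since |A∩τ| ≤ γ|τ| per
triangle and gradients are elementwise constant, K_σ̃A ≼ γ(σ₀−σ_A)K in
the quadratic-form order, and applying (σ₀K)⁻¹ preserves the norm
ordering for SPD matrices.  Because the same quadrature estimates
feed both K_σ̃A and γ, the bound holds at the discrete level up to
roundoff — `contraction_norm` verifies it with a dense SVD (small
systems) or power iteration on MᵀM (relative tolerance 10⁻⁸).  For a
layer of thickness δ, γ ≈ δ/h up to curvature effects: measured
values for the single-cell model are 0.14 (N=16), 0.40 (N=32), 0.76
(N=64) and reach 1.0 once a triangle fits inside the curved strip
(the inscribed-circle diameter h(2−√2) exceeds δ for N ≳ 115 — the
bound then stops being informative, yet the measured norm stays below
1 and the iteration still converges, only slowly).  `suggest_mesh`
inverts the scaling: h ≥ δ/c keeps the contraction factor near c.

## Reference solution and error metrics

The "truth" is an in-house direct solve of the coupled system
σ₀K − K_σ̃A on a fine uniform mesh, default N_fine = 1536
(h ≈ δ/15), chosen as a common multiple of the standard sweep
{32, 64, 128, 256} so coarse nodes are fine nodes and no
interpolation enters the comparison.  SuperLU factorises the
2.4M-unknown system in under a minute.  A boundary-fitted unstructured
reference would differ in its own discretisation error; the
self-consistency test (N_fine = 480 vs 960 differing by less than the
method error they measure) quantifies that the reference is accurate
enough for the error levels reported.

Current density is J = σ|∇u| at grid points, with ∇u by central
differences inside and second-order one-sided differences on the
boundary (exact for quadratics) and σ evaluated pointwise through
χ_A.  The error metric is the discrete relative L² norm
√(Σ(u−U_h)²/Σu²) over grid points, reported for the whole domain and
for the lumen Ω_I (points strictly inside a cell's inner circle).
Empirical convergence order is the least-squares slope of log error
vs log h.

## Problem sizes and numerical choices

The standard error study runs N ∈ {32, 64, 128, 256} against the
N_fine = 1536 reference (~70 s total); the contraction-bound sweep
uses dense norms at N ≤ 32 (≈10³ unknowns); the anisotropy study
solves four N = 256 systems directly (~3 s).  Tolerances: stopping
10⁻⁶ (headline runs) down to 10⁻¹² when validating against the direct
solve; quadrature level auto as above; power iteration 10⁻⁸.
Degenerate inputs: σ_A = σ₀ makes K_σ̃A the zero matrix and the
iteration converges in one update with zero change; empty geometries
are legal everywhere and give γ = 0.

## What the tests do and do not show

All experiments are synthetic by design — the study *is* a simulation
study of an idealised phantom.  The geometry generator reproduces the
published configurations exactly (cell dimensions, hole sizes, grid
layouts, conductivities), so passing tests show the solver behaves as
analysed on those configurations: contraction below γ(1−ε),
agreement with the direct solve, first-order voltage convergence,
direction-selective hole sensitivity.  They do not show fidelity to
living tissue: real membranes are curved 3-D surfaces with
capacitive (frequency-dependent) behaviour, distributed nanoscale
channels rather than four 2.5 mm-scale holes, and cells are neither
circular nor periodically arranged.

Iteration counts deserve a caveat: they depend on the boundary data,
initial guess and stopping-norm convention, none of which the model
itself pins down.  Under this package's documented defaults
the single-cell counts at N = 16 and the multi-cell counts at N = 32
match the published tables exactly; the single-cell counts at
N = 32–256 land near but not on the published values (4/8/49/142
vs 6/10/38/164).  Near-unit contraction amplifies tiny spectral
differences into visible count differences, so exact reproduction
would require the original code's conventions.

## Known limitations

* 2-D only; no spheres, no deformable or moving membranes.
* Uniform structured meshes only — that is the point of the method —
  so fields with boundary layers finer than h are smoothed.
* The current density inherits the O(h) voltage accuracy near the
  membrane; a first-order-system reformulation would improve it and
  is out of scope.
* The iteration degrades as γ(1−ε) → 1 (N ≳ 100 for δ = 0.002);
  beyond that the direct solve is preferable.
* Magnetic flux density and conductivity-image reconstruction
  pipelines that would consume these fields are out of scope.
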