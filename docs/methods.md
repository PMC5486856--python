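# Methods

## The model

The package simulates the contraction of a circular deep burn during the
proliferative phase of healing.  A slab of dermis is treated as a
continuum under plane strain (`w = 0`, `∂/∂z = 0`), with four
constituents — fibroblasts `N` and myofibroblasts `M` (cells/cm³), a
generic TGF-β-like signaling molecule `c` (g/cm³) and collagen `ρ`
(g/cm³) — obeying conservation laws on the deforming tissue,

    ∂z_i/∂t + ∇·(z_i v) = −∇·J_i + R_i,        −∇·σ = f,

where inertial forces are neglected so the momentum balance is
quasi-static.

**Transport.** Cells undergo density-dependent Fickian diffusion
(coefficient `D_F·F`, `F = N + M`) and chemotaxis up the signal gradient
(`χ_F z ∇c`); the signal diffuses linearly (`D_c`); collagen is not
transported (secreted molecules attach to the matrix instantly).

**Kinetics.** Both cell populations follow an adjusted logistic growth
law with a fractional exponent `1 + q` (`q ≈ −0.42 < 0`), enhanced by the
signal through a Michaelis–Menten factor and limited by crowding
`(1 − κ_F F)`; fibroblasts differentiate into myofibroblasts at rate
`k_F c`; both populations die at first-order rates `δ_N`, `δ_M`.
Myofibroblasts divide only in the presence of the signal.  The signal is
secreted by both cell types (myofibroblasts weighted by `η`) with
saturation, and degraded by a generic MMP whose level is
`g = F ρ / (1 + a_c^III c)` — proportional to cells and collagen,
inhibited by the signal.  Collagen is secreted with signal enhancement
and degraded by the same MMP.

**Consistency-forced constants.** Three constants are not free.
Requiring the homogeneous unwounded state `(N̄, 0, 0, ρ̄)` to be a fixed
point forces

    c̄ = 0,   q = [log δ_N − log(r_F (1 − κ_F N̄))]/log N̄,   δ_ρ = k_ρ/ρ̄².

Any logarithm base gives the same `q` (a ratio of logs); with Table
defaults `q ≈ −0.41507`, printed as −0.42.

**Mechanics.** The dermis is a heterogeneous, isotropic, compressible
neo-Hookean solid whose Young's modulus `E·ρ` tracks the local collagen
concentration (`ν = 0.49`):

    σ = 2 C₁ (det B)^(−5/6) (B − ⅓ tr B · I) + 2 D₁ (√det B − 1) I,
    C₁ = Eρ/4(1+ν),  D₁ = Eρ/6(1−2ν),

with `B` the left Cauchy–Green tensor built from the *Eulerian*
displacement gradient, embedded in plane strain (`B_zz = 1`; the trace
and determinant are 3D).  Myofibroblast traction enters as an isotropic
active stress `ψ I` with `ψ = ξ M ρ/(R_ρ² + ρ²)` (the saturation constant
is named `R_rho_const` in code to keep it apart from the collagen
reaction term); its divergence is the body force.  The outer boundary
carries a spring-like Robin condition `n·σ = −s ρ u`; the constituents
obey Dirichlet conditions (`N̄`, 0, 0) there.

**Initial conditions.** A smooth radial indicator `w` (0 in the wound,
1 outside, sinusoidal ramp of half-width `c_II = 0.1 cm` around the wound
radius `c_I`) sets `N = [I_w + (1−I_w)w]N̄`, `M = 0`, `c = (1−w)c_w`,
`ρ = [I_w + (1−I_w)w]ρ̄`, `u = 0`.

All internal computation is non-dimensional: `x = L x*`,
`t = (L²/D_F N̄) t*` (1 dimensionless time unit = 1000 days at defaults),
`N, M` by `N̄`, `c` by `c_w`, `ρ` by `ρ̄`, `σ` by `ξN̄/ρ̄` (500 N/cm²).
The scaled parameter collection has the same shape as the dimensional
one, so every model function is form-invariant.  When `c_w = 0` is
requested (unwounded runs), the signal scale is undefined; the solvers
substitute `a_c^I` as the concentration scale, which is harmless because
`c ≡ 0` is then invariant.

## Numerics

Two engines share the same time-integration scheme and differ only in
the spatial discretisation.

**Time stepping (both engines).** Backward Euler with a segregated
fixed-point defect correction per step: constituents first, then the
mechanics.  The loop exits when the relative 1-norms of successive
iterate differences fall below 5×10⁻² and the relative 1-norms of the
implicit-system residuals (normalised by the 1-norm of the right-hand
side) are below 1; at most 5 sweeps, otherwise the step restarts at 85%
of its size.  One guard beyond these printed criteria: the loop never
exits on the first sweep, because the first constituent solve still uses
the pre-step geometry — the dilution from mesh motion enters only once
the mechanics update has been seen, and exiting early would drop it
entirely (an O(1) consistency error, verified by a wrong dt→0 limit).

Step sizes are adaptive with local-truncation-error control: the
accepted solution is compared with a second-order variable-step
predictor `z^n + dt (z^n − z^{n−1})/dt_old`; the step is accepted iff the
error estimate is below `abs_tol + rel_tol·|z|` componentwise (10⁻² and
5×10⁻², dimensionless).  Initial step ≤ 10⁻⁵, cap 10⁻³, growth ≤ 1.25 on
accept, shrink ≥ 0.25 on reject.  After acceptance the truncation-error
estimate is subtracted from the solution (local extrapolation), clipped
at zero; this lifts the scheme to effective second order and is what
makes the day-42 area insensitive (< 1%) to halving the dt cap — without
it the result at the cap carries a ~3% first-order error.

**Positivity.** Reaction terms are Patankar-split: productions are
evaluated at the previous sweep iterate, sinks are implicit and
proportional to the new unknown.  Transport is discretised monotonically
(upwinded chemotactic fluxes in 1D; discrete upwinding of the assembled
operator plus lumped mass in 2D), giving M-matrices throughout, so all
four fields stay non-negative at every accepted step by construction;
the solvers additionally hard-assert it.  Negative entries at the
denormal level (~10⁻⁴⁰), which sparse LU can produce from exact zeros,
are clipped.

**Radial engine.** For circular wounds the problem reduces to 1D on a
disk of radius 12 cm (the full domain is the 24×24 cm square; the wound
radius is ≤ 3.99 cm, so the boundary-shape difference is small and is
quantified by the 2D engine: 0.6% on the day-42 relative area for the
reference parameter set).  Finite volumes on a graded Lagrangian grid
(nodes convect with the material, removing the advective flux exactly;
cell-volume changes carry the dilution).  The grid is finest
(`h = 0.03 cm` by default) across the wound-edge annulus
`[c_I − 2c_II, c_I + 2c_II]`, growing geometrically (ratio ≤ 1.3, cap
0.4 cm) away from it — halving `h` changes the day-42 area by < 0.01%.
The neo-Hookean balance becomes a two-point boundary value problem in
the radial displacement, solved by damped Newton with the analytic
weak-form residual and a 3-colored finite-difference tridiagonal
Jacobian.

**2D engine.** Base triangulations of the square (or a disk, for
cross-validation) come from a force-equilibrium generator in the
distmesh style: hexagonal packing fitted to the domain (with wall nodes
at every row on straight boundaries), bar-force relaxation, then a
deterministic pattern-search polish of the worst nodes; all triangles
exceed quality 0.86 (`2√3·area·2/(sum of squared edges)`) at the three
study resolutions.  A recovered-gradient error estimator (area-weighted
nodal averaging of element gradients, compared elementwise against the
low-order constant gradient) drives static red/green adaptation around
the wound edge before the run: elements with error fraction > 0.2 are
red-refined (1→4) with a 2:1 balance rule and green conformity closure,
at most 4 levels, never coarser than the base, at most 10 sweeps or
until the total estimated error changes < 5%.  The wound edge never
leaves the pre-refined annulus at these geometries, so no dynamic
remeshing is performed.  P1 elements for every unknown; second-order
Newton–Cotes interior and 2-point Gauss boundary quadrature; mechanics
in total-Lagrangian form with element-level finite-difference Jacobians
assembled sparse and solved by damped Newton + sparse LU.

## The statistical experiments

**Factorial + regression.** The four study factors take equally spaced
levels spanning their reported ranges, endpoints included: `c_I` ∈
{3.57, 3.99} cm, `I_w` ∈ {0.10, 0.15, 0.20}, `k_ρ` ∈ {1.25, 1.75, 2.25,
2.75}×10⁻⁸ g/(cells·day), `δ_M` ∈ {1…6}×10⁻² /day — 144 deterministic
runs of the radial engine to day 42.  The response is the relative wound
area: the shoelace area of the polygon through 40 tracked boundary
material points divided by its day-0 value (the 40-gon underestimates a
circle's area by the fixed factor 0.99589, which cancels in the ratio).
The response is Rankit-normalised (rank `r` of `n` → `Φ⁻¹((r−0.5)/n)`,
ties averaged), the factors are z-scored (n−1 denominator), and an OLS
with intercept and no interactions is fitted.  Squared semipartial
correlations are computed as the drop in R² when a predictor is removed;
the identity `sr²_i = t_i²(1−R²)/(n−p−1)` is asserted against that route
in the tests.  p values are unadjusted.

**Probabilistic analysis.** 100 draws of `k_ρ ~ N(2×10⁻⁸, 3.75×10⁻⁹)`
and `δ_M ~ N(3.5×10⁻², 1.25×10⁻²)` (one 100-observation sample per
distribution), with `I_w = 0.15`, `c_I = 3.78 cm`; non-positive draws
are rejected and redrawn (≈0.26% probability per `δ_M` draw) because
negative rates are unphysical; the input samples are checked with the
Anderson–Darling test (advisory warning only).  Each draw is simulated
to day 42; the relative area, and the Lagrangian 9-point probe averages
of `M` and `ρ` (wound center, four points at `c_I/2`, four at `c_I`,
interpolated on the initial configuration so the probes follow the
tissue), are recorded.  Outputs: mean, sd and skewness of the area
distribution; the Anderson–Darling statistic with the small-sample
correction `A²* = A²(1 + 0.75/n + 2.25/n²)` and the standard
piecewise-exponential p-value approximation for the estimated-parameters
case; and the pairwise Pearson matrix (two-sided t-transform p values)
among `δ_M`, `k_ρ`, `M_avg`, `ρ_avg` and the relative area.

## Problem sizes and determinism

Default problem sizes: radial grid ≈ 60–90 nodes (h_min 0.03 cm), one
42-day run ≈ 60 accepted steps; 2D meshes ≈ 400 base / ≈ 4000 adapted
elements at 1.85 cm target edge.  The experiments use the radial engine;
the solvers are fully deterministic, and all randomness (Monte-Carlo
draws) flows from a single integer seed through `numpy`'s `default_rng`.

## What the simulations do and do not show

The simulator reproduces the study's conditions exactly as specified —
the same kinetics, geometry, parameter ranges and analysis pipeline —
so agreement of the regression table and Monte-Carlo summary is a check
of the model and its numerics, not of dermal biology.  Real burns are
not circular, dermal tissue is anisotropic and viscoelastic, the model
cannot form permanent (morphoelastic) deformation — the displacement
returns to zero as the constituents re-equilibrate — and the mechanical
stiffness felt by differentiating fibroblasts is not modeled.
Quantities measured at material probes depend on the interpolation mesh
near the steep wound edge at the level of a few percent.

## Known behaviours and limitations

* Retraction: after the contraction minimum (≈ day 45 at default
  parameters) the area recovers monotonically toward 1.  At low
  myofibroblast apoptosis (`δ_M = 2×10⁻²`) the recovery shows a genuine
  ~0.5% secondary dip near day 95, when the signal collapses and the
  myofibroblast population crashes; it persists at 4× finer time steps
  and is a model property, not an artifact.
* The crowding factor `1 − κ_F F` is clamped at zero (with a warning)
  for super-physiological densities; the clamp is never active in the
  study's parameter ranges.
* The fractional power `M^(1+q)` is well defined at `M = 0` since
  `1 + q > 0`; because productions are Picard-lagged, no Jacobian of the
  fractional power is ever needed and no regularisation floor enters.
* The unstructured 2D mesh is not rotationally symmetric, so circular
  wounds keep a residual azimuthal asymmetry of ~2% (RMS) of the radial
  field variation at the study resolution.
* The radial engine is the default for the statistical experiments;
  every result records which engine produced it.
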