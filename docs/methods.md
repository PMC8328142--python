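# Methods

This note documents the models, numerical choices and limitations behind
`amrdmd`, in the spirit of the methods documentation of established
scientific-computing packages.

## Dynamic mode decomposition

Given snapshots `u_0 … u_m` sampled every `Δt_o`, the shifted pair
`Y_1 = [u_0 … u_{m−1}]`, `Y_2 = [u_1 … u_m]` defines the best-fit linear
propagator `A = Y_2 Y_1⁺`.  We never form `A`: the rank-r truncated SVD
`Y_1 ≈ U_r Σ_r V_rᵀ` (Eckart–Young optimal) gives the reduced operator
`Ã = U_rᵀ Y_2 V_r Σ_r⁻¹`, whose eigendecomposition `Ã W = W Λ` produces
exact-DMD modes `Ψ = Y_2 V_r Σ_r⁻¹ W`.  Amplitudes solve the least-squares
problem `Ψ b = u_0`, and continuous eigenvalues are `ω = ln λ / Δt_o`
(principal branch).  Reconstruction/extrapolation is `u(t) = Ψ exp(ω (t−t_0)) b`
with `t_0` the time of the first training snapshot.

Choices where the classical formulation leaves freedom:

- **Mode ordering.** Modes are sorted by non-increasing `|b_j|`, ties broken by
  `|λ_j|` and then original index, so output is deterministic.
- **Branch of the logarithm.** `λ` on the negative real axis maps to
  `Im ω = π/Δt_o`; such Nyquist-frequency modes are logged.  `λ = 0`
  (nilpotent directions) have no continuous eigenvalue and are dropped with a
  warning.
- **Singular-value floor.** Directions with `σ_i < 10⁻¹² σ_0` are treated as
  numerically rank-deficient and removed before inverting `Σ_r`, preventing
  pseudoinverse blow-up; the effective rank is reported on the model.
- **Randomized SVD.** The randomized path (scikit-learn's range finder) uses
  10 oversampling columns and 2 power iterations under a caller-provided seed;
  on matrices whose numerical rank is at most r it reproduces deterministic
  singular values to ~1e-8.  The deterministic thin SVD is the default and is
  what all reported numbers use.
- **Rank selection.** Either a fixed rank r or the hard energy threshold: the
  smallest r with residual energy `κ(r) = 1 − Σ_{i≤r}σ_i²/Σσ_i² ≤ τ`
  (default `τ = 1e-6`, retaining >99.9999 % of the variance).  The 1D epidemic
  preset fixes `r = 15`; the threshold rule is exposed separately and is not
  claimed to reproduce that choice.
- **Real output.** `evaluate` returns the real part and logs the maximum
  imaginary residual; for real training data the conjugate-pair symmetry keeps
  it at rounding level, and a large residual indicates a broken pairing.

## L2 projection between non-matching meshes

A P1 field on a donor mesh is transferred to a target mesh by the orthogonal
projection `(u − u_proj, v) = 0` for all target basis functions, i.e.
`M u_proj = P u` with the consistent target mass matrix `M` and cross mass
matrix `P_ij = ∫ φ_i^target φ_j^donor`.

`P` is assembled **exactly on the local supermesh**: in 1D each target element
is split at the donor nodes it contains and integrated with 2-point Gauss per
sub-interval; in 2D each target triangle is intersected with the overlapping
donor triangles (shapely polygon clipping), the convex intersections are
fan-triangulated, and the 3-point mid-edge rule (exact for quadratics)
integrates the product of linears.  Consequences, verified by the test suite:

- integral conservation `∫u_proj = ∫u` to machine precision (the constant is
  always in the target space here);
- the projection is an L2 contraction and idempotent;
- identity on the same mesh and exactness for nested coarse-to-fine transfer.

A cheaper alternative — fixed-order quadrature on target elements with point
location into the donor mesh — was rejected because the integrand has gradient
kinks at donor element boundaries, which caps the accuracy at O(h²) and, more
importantly, destroys exact conservation.  The supermesh assembly costs more
per projection but the projection is a per-output post-processing step and is
a negligible fraction of the simulation cost.

`M` is the consistent (not lumped) mass matrix, solved by direct sparse
factorization; at the problem sizes targeted here (10³–10⁴ dof) this is
exact and fast, and the factorization is cached per donor/target mesh pair.

## Adaptive meshes

Adaptivity is organised as a refinement forest over the initial elements:
binary in 1D, red (1:4) in 2D.  The conforming 2D mesh is emitted from the
leaves with *transient green closure*: hanging mid-edge nodes are closed by
bisecting the coarser neighbour into 2–3 triangles that are recomputed at
every emission and never refined themselves, keeping the genealogy a pure red
forest.  A 1-irregularity rule (edge neighbours differ by at most one level)
is enforced by recursive neighbour refinement, and coarsening (which requires
all siblings flagged — safety over aggressiveness) is vetoed when it would
violate the rule.  Mesh genealogy is an implementation detail: all results are
compared on the reference mesh, where the projection contract above is what
matters.

Element flagging is statistical: the flux-jump indicator (per element, the sum
of absolute gradient jumps across its faces, scaled by element size; in 2D the
normal-gradient jump times edge length, scaled by the diameter) is computed
per compartment, each compartment's indicator is normalized by its maximum so
that large-amplitude fields do not monopolise refinement, and the top
`refine_fraction` / bottom `coarsen_fraction` of elements are flagged (ties by
element id, refinement suppressed at `max_level`).  The fractions for the 1D
epidemic preset are 0.3/0.1; they are not critical because the snapshot stream
is evaluated on the reference mesh, where moderate flagging differences wash
out — this was confirmed by the scenario's error levels being insensitive to
the exact fractions.

## The SEIRD model

Densities s, e, i, r, d evolve under nonlinear transmission
(`β_i s i`, `β_e s e`, optionally damped by the Allee factor `1 − A_e/n_pop`),
incubation `α e`, recoveries `γ_e e`, `γ_i i`, mortality `δ i`, and
population-weighted diffusion `∇·(n_pop ν ∇u)` with `n_pop = s+e+i+r`.
The cumulative compartment is advanced as `dc/dt = α e` — the influx into the
symptomatic compartment — the natural reading of "cumulative infections";
the defining equation is a documented package choice.  Parameters may be piecewise-constant
schedules in time (restriction-style interventions); the shipped 1D preset
uses `α = 0.09375`, `β_i = β_e = 0.375`, `δ = 0.0046875`, `γ_i = 0.03125`,
`γ_e = 0.125`, `A_e = 0`, `ν_s = ν_r = 3.75e−5`, `ν_e = 7.5e−4`,
`ν_i = 7.5e−11` (units: rates per day, diffusion km² persons⁻¹ day⁻¹),
Δt = 0.25 days.

Discretization choices:

- **Group finite elements for reactions.** Nonlinear products are interpolated
  nodally and multiplied by the consistent mass matrix.  This gives closed-form
  reaction Jacobians and makes the spatially uniform limit *exactly* the
  well-mixed ODE system, which is what allows the stiff-ODE oracle tests to be
  sharp.
- **BDF2 with a single backward-Euler start-up step.**  Second-order,
  A-stable; self-convergence slope measured at ≈ 2.0.
- **Newton iteration** on the monolithic 5-compartment system, analytic
  reaction Jacobian, with the population-weighted stiffness operator
  reassembled at every iterate but not differentiated (quasi-Newton lagging);
  the Allee factor is likewise lagged.  Transiently negative `n_pop` iterates
  are clamped to zero inside the diffusion coefficient.  Default tolerances
  are absolute 1e-12 / relative 1e-10, max 25 iterations; the tight absolute
  tolerance is what lets the discrete conservation identity (reaction terms
  telescope; with all-Neumann boundaries `d/dt ∫(s+e+i+r+d) = 0`) hold to
  ~1e-12 per step and ~1e-10 over a 176-step run.
- **Dirichlet conditions** are imposed by row replacement with symmetric
  column elimination (zero-population boundaries only, so the elimination has
  no right-hand-side contribution).
- The scheme does **not** guarantee non-negative fields; per-step minimum
  values are recorded rather than asserted.

## The 1D forecasting scenario

Domain [0, 1]; initial susceptible population: a Gaussian bump centred at
x = 0.35 on a small background, three quartic-bump clusters at x = 0.42, 0.52,
0.62 (weight 1/8) and one at x = 0.735 (weight 1/4); initial exposed: a
quartic bump at x = 0.75 with amplitude 1/20; i = r = d = c = 0.  Homogeneous
Neumann at x = 0 and zero-population Dirichlet at x = 1.  The mesh starts as
125 uniform elements, is uniformly refined twice (giving h = 0.002, the
reference-mesh resolution), and then adapts every 4 steps with depth cap 2.
Every step's solution is projected onto the uniform 500-element reference
mesh.  DMD is trained per compartment on days 3–30 (the first 3 days are
skipped because several compartments start at zero, which pollutes the fitted
dynamics) at rank 15, and evaluated through day 44 — a 14-day forecast.

Error reporting follows two windows, both always computed and labeled:
`eta_F` over the post-shift comparison window (days 3–44) and
`eta_F_from_day0` over all 177 columns (days 0–44, with the model
back-extrapolated across the shift).  The full-window variant is the one to
use when comparing overall errors across implementations of this scenario
(whole-run error budgets are conventionally quoted over all outputs); the
post-shift variant is roughly an order of magnitude smaller and is the better
measure of forecast quality proper.  Forecast errors are always measured against the
*projected* simulation snapshots, never against the adaptive-mesh fields
directly.  Wall-clock speedups are deliberately not part of any metric
(hardware-dependent); timing is logged informationally only.

## Synthetic data

`planted_spectrum_series` builds `u_k = Re(Ψ Λᵏ b)` from a requested discrete
spectrum (which must be closed under conjugation for real output), modes drawn
from random orthonormal real directions, and random amplitudes — a pure
function of (parameters, seed).  It emulates exactly the class of signals DMD
represents exactly: a finite sum of exponentially growing/decaying
oscillations.  What it does *not* emulate: measurement noise, continuous
spectra, translating/advecting structures, or any nonlinearity — so passing
the exactness tests demonstrates correctness of the algebra, not robustness on
real data.  The epidemic simulation itself provides the nonlinear,
multi-scale test signal.  `|λ|^m` is capped at 1e12 to avoid overflow.
The square-indicator fixture values nodes on the boundary of
[-0.3, 0.3]² as 1 (closed square).

## Problem sizes and budgets

Default test and acceptance runs use the full 1D scenario (501 reference dof,
177 snapshots, 176 implicit steps — seconds on one core), 2D projection
examples on meshes up to 80×80 cells, and small well-mixed meshes for the ODE
oracle comparisons (the uniform limit is mesh-independent, so a 10-element
mesh suffices).  The uniform initial values of the well-mixed check are the
domain averages of the scenario's initial fields (s = 0.3025, e = 0.0051),
i.e. the well-mixed limit of the same scenario.

## Known limitations

- P1 elements only; no curved geometry; no fully unstructured mesh
  generation.  Structured triangulations and their red-refinement descendants
  are the supported 2D family.
- The L2 projection is not a constrained/conservative transfer in the
  monotonicity sense: discontinuous donors overshoot (Gibbs-like, a few
  percent on the indicator example).  Integral conservation holds exactly;
  positivity does not.
- DMD is linear: strongly nonlinear transients and moving fronts are captured
  only as superpositions of fixed spatial modes; forecast skill degrades with
  horizon, which the per-snapshot error series makes visible.
- Koopman-style nonlinear observables, streaming/compressed decompositions and
  noise-robust rank selection are out of scope.
- True hanging-node constraints are not implemented; conformity is restored by
  closure triangles instead.
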