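# amrdmd

Dynamic mode decomposition (DMD) for simulations that run on **adaptively
refined and coarsened finite-element meshes**, with an end-to-end
spatio-temporal SEIRD epidemic forecasting workflow.

## The problem

DMD stacks the discrete solution at successive output times into a snapshot
matrix `Y = [u_0 … u_m]` and fits the best linear operator `A` with
`Y_2 ≈ A Y_1` (the one-step-shifted splitting of `Y`).  Working in the rank-r
SVD subspace of `Y_1`, the reduced operator

    Ã = U_rᵀ Y_2 V_r Σ_r⁻¹

yields eigenpairs `(λ_j, w_j)`, exact-DMD modes `Ψ = Y_2 V_r Σ_r⁻¹ W`,
continuous eigenvalues `ω_j = ln λ_j / Δt_o`, and amplitudes `b = Ψ⁺ u_0`, so
that the signal is reconstructed — and extrapolated in time — as

    u(t) ≈ Ψ exp(Ω t) b.

This requires every snapshot to have the same dimensionality.  Adaptive mesh
refinement/coarsening (AMR/C) breaks that assumption: the mesh, node numbering
and number of degrees of freedom change during the run.  `amrdmd` restores a
constant-dimension snapshot stream by **L2-projecting every output onto a
fixed reference mesh**, solving `M u_proj = P u` with the reference-mesh mass
matrix `M` and the cross mass matrix `P_ij = ∫ φ_i^target φ_j^donor`.  `P` is
assembled on the local supermesh (merged breakpoints in 1D, triangle–triangle
intersections in 2D), so the projection conserves integrals to machine
precision.

The package is aimed at practitioners of reduced-order modelling and
epidemiological/CFD simulation who want snapshot-based analysis and short-time
forecasting on top of adaptive finite-element codes.

## What is included

- `amrdmd.dmd` — exact DMD with deterministic or randomized truncated SVD and
  the hard-threshold energy criterion `κ(r) = 1 − Σ_{i≤r}σ_i²/Σσ_i² ≤ τ` for
  rank selection.
- `amrdmd.mesh` / `amrdmd.refine` — conforming P1 interval and triangle
  meshes with refinement genealogy (binary / red-refinement forests with green
  closure), mass and stiffness assembly, exact P1 integration, and the
  conservative L2 projection between non-matching meshes.
- `amrdmd.seird` — the spatio-temporal SEIRD reaction–diffusion model
  (susceptible/exposed/infected/recovered/deceased densities plus cumulative
  infections), with population-weighted diffusion, optional Allee factor,
  Galerkin P1 semi-discretization and implicit BDF2 stepping with Newton
  iteration.
- `amrdmd.amrc` — flux-jump error indicator, statistical refine/coarsen
  flagging, solution transfer, and the reference-mesh snapshot stream.
- `amrdmd.metrics` — overall relative error `η_F = ‖Y − Y_DMD‖_F / ‖Y‖_F`,
  per-snapshot relative errors `η(t)`, and rank studies.
- `amrdmd.fixtures` — planted-spectrum synthetic snapshot generators with
  exact ground truth.
- `amrdmd.pipeline` / the `amrdmd` CLI — the full simulate → project → fit →
  forecast → evaluate workflow from one config file.

## Worked example

Fit a model to a synthetic linear system with a planted spectrum:

```python
import numpy as np
from amrdmd import planted_spectrum_series, fit_dmd, evaluate, overall_relative_error

eigs = [0.95, 0.8 * np.exp(1j * np.pi / 8), 0.8 * np.exp(-1j * np.pi / 8)]
series, truth = planted_spectrum_series(100, 60, eigs, seed=7)
model = fit_dmd(series, r=3)
print("recovered:", np.sort_complex(model.lam))
print("eta_F =", overall_relative_error(series.values, evaluate(model, series.times)))
```

prints

```
recovered: [0.73910363-0.30614675j 0.73910363+0.30614675j 0.95      +0.j]
eta_F = 7.700918859044722e-15
```

— the three planted discrete eigenvalues (`0.8 e^{±iπ/8}` is the decaying
oscillation pair) recovered to machine precision, with a reconstruction error
of the same order.

The 1D epidemic forecasting scenario — 44 simulated days at Δt = 0.25 on an
adaptive mesh (125 root elements, two refinement levels, adaptation every 4
steps), projection of every step onto the uniform reference mesh with
h = 0.002, DMD training on days 3–30 at rank 15, 14-day forecast — runs from
the shipped preset:

```sh
amrdmd run --output artifacts/
```

The summary it prints contains per-compartment overall relative errors of the
DMD reconstruction-plus-forecast against the projected snapshots over the full
44-day window, e.g.

```
"eta_F_from_day0": { "s": 9.25e-04, "e": 3.19e-02, "i": 2.31e-02,
                     "r": 6.60e-03, "d": 2.04e-02, "c": 4.38e-03 }
```

meaning the susceptible field is predicted to a tenth of a percent while the
exposed field — the fastest, most transient compartment — is the hardest to
forecast, at roughly 3 %.  Normalized total population stays within 1e-7 % of
1.0 through the reconstruction window.

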