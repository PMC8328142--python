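"""Spatio-temporal SEIRD reaction-diffusion model, Galerkin P1 + BDF2.

Compartments are densities of susceptible (s), exposed (e), infected (i),
recovered (r) and deceased (d) individuals; c accumulates the influx into i.
The living population n_pop = s + e + i + r weights the diffusion coefficients
and enters the optional Allee factor (1 − A_e/n_pop), which damps transmission
at low density.  The semi-discrete system per compartment is

    M du/dt − M f(u) + K(n_pop ν) u = 0,

with f the nodal reaction rates (group-FEM treatment: nonlinear products are
interpolated nodally, so the spatially uniform limit reduces exactly to the
well-mixed ODE system).  Time integration is BDF2 with a single backward-Euler
start-up step; the nonlinear system is solved by Newton iteration with an
analytic reaction Jacobian and the population-weighted diffusion operator
lagged at the previous iterate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import FEField, Mesh1D, assemble_mass, assemble_stiffness, integrate

__all__ = [
    "SEIRDParams",
    "SEIRDState",
    "BCSpec",
    "Schedule",
    "seird_1d_params",
    "initial_conditions_1d",
    "reaction_rates",
    "semidiscrete_residual",
    "SEIRDSolver",
    "total_population",
]

COMPARTMENTS = ("s", "e", "i", "r", "d")
DIFFUSIVE = {"s": "nu_s", "e": "nu_e", "i": "nu_i", "r": "nu_r"}


class Schedule:
    """Piecewise-constant parameter schedule: value(t) = v_k for t >= t_k."""

    def __init__(self, breakpoints, values):
        self.t = np.asarray(breakpoints, dtype=float)
        self.v = np.asarray(values, dtype=float)
        if len(self.t) != len(self.v):
            raise ValueError("breakpoints and values must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(self.v < 0):
            raise ValueError("rates must be non-negative")

    def __call__(self, t: float) -> float:
        k = np.searchsorted(self.t, t, side="right") - 1
        if k < 0:
            raise ValueError(f"schedule undefined at t={t} (starts at {self.t[0]})")
        return float(self.v[k])


def _rate(p, t: float) -> float:
    return p(t) if callable(p) else float(p)


@dataclass
class SEIRDParams:
    """Epidemiological and diffusion parameters.

    Rates are per day; transmission per day per person; diffusion in
    km² persons⁻¹ day⁻¹.  Any entry may be a callable of time (e.g. a
    :class:`Schedule`) to model time-varying restrictions.
    """

    alpha: object  # incubation rate
    beta_i: object  # symptomatic transmission
    beta_e: object  # asymptomatic transmission
    delta: object  # mortality rate
    gamma_i: object  # symptomatic recovery
    gamma_e: object  # asymptomatic recovery
    A_e: object = 0.0  # Allee parameter (persons)
    nu_s: object = 0.0
    nu_e: object = 0.0
    nu_i: object = 0.0
    nu_r: object = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta_i", "beta_e", "delta", "gamma_i", "gamma_e",
                     "A_e", "nu_s", "nu_e", "nu_i", "nu_r"):
            v = getattr(self, name)
            if not callable(v) and float(v) < 0:
                raise ValueError(f"parameter {name} must be non-negative")

    def at(self, t: float) -> dict:
        return {
            name: _rate(getattr(self, name), t)
            for name in ("alpha", "beta_i", "beta_e", "delta", "gamma_i",
                         "gamma_e", "A_e", "nu_s", "nu_e", "nu_i", "nu_r")
        }


def seird_1d_params() -> SEIRDParams:
    """Shipped default parameter preset for the 1D scenario."""
    return SEIRDParams(
        alpha=0.09375,
        beta_i=0.375,
        beta_e=0.375,
        delta=0.0046875,
        gamma_i=0.03125,
        gamma_e=0.125,
        A_e=0.0,
        nu_s=3.75e-5,
        nu_e=0.75e-3,
        nu_i=0.75e-10,
        nu_r=3.75e-5,
    )


@dataclass
class SEIRDState:
    """Nodal compartment fields on one mesh at time ``t`` (days)."""

    t: float
    mesh: object
    s: np.ndarray
    e: np.ndarray
    i: np.ndarray
    r: np.ndarray
    d: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        n = self.mesh.n_nodes
        for name in ("s", "e", "i", "r", "d", "c"):
            v = np.asarray(getattr(self, name), dtype=float)
            if len(v) != n:
                raise ValueError(f"compartment {name} has {len(v)} values for {n} nodes")
            setattr(self, name, v)

    def fields(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in ("s", "e", "i", "r", "d", "c")}

    def n_pop(self) -> np.ndarray:
        """Total living population density (deceased excluded)."""
        return self.s + self.e + self.i + self.r

    def with_fields(self, t: float, mesh, fields: dict[str, np.ndarray]) -> "SEIRDState":
        return SEIRDState(t, mesh, fields["s"], fields["e"], fields["i"],
                          fields["r"], fields["d"], fields["c"])


@dataclass
class BCSpec:
    """Boundary conditions per boundary tag, shared by all compartments.

    ``kind_by_tag`` maps a tag ("left"/"right" in 1D, or "boundary" for the
    whole boundary in 2D) to "neumann" (natural, do nothing) or "dirichlet0"
    (zero population).
    """

    kind_by_tag: dict = field(default_factory=dict)

    def dirichlet_nodes(self, mesh) -> np.ndarray:
        out: set[int] = set()
        if isinstance(mesh, Mesh1D):
            valid = {"left", "right"}
            for tag, kind in self.kind_by_tag.items():
                if tag not in valid:
                    raise ValueError(f"unknown 1D boundary tag {tag!r}")
                if kind == "dirichlet0":
                    out.add(0 if tag == "left" else mesh.n_nodes - 1)
                elif kind != "neumann":
                    raise ValueError(f"unknown boundary condition kind {kind!r}")
        else:
            for tag, kind in self.kind_by_tag.items():
                if tag != "boundary":
                    raise ValueError(f"unknown 2D boundary tag {tag!r}")
                if kind == "dirichlet0":
                    out.update(_boundary_nodes_2d(mesh))
                elif kind != "neumann":
                    raise ValueError(f"unknown boundary condition kind {kind!r}")
        return np.array(sorted(out), dtype=int)


def _boundary_nodes_2d(mesh) -> list[int]:
    from collections import Counter

    edges = Counter()
    for tri in mesh.triangles:
        for a in range(3):
            edges[tuple(sorted((tri[a], tri[(a + 1) % 3])))] += 1
    nodes = set()
    for (a, b), cnt in edges.items():
        if cnt == 1:
            nodes.update((a, b))
    return sorted(nodes)


def seird_1d_bcs() -> BCSpec:
    """Homogeneous Neumann at x=0, zero-population Dirichlet at x=1."""
    return BCSpec({"left": "neumann", "right": "dirichlet0"})


# --------------------------------------------------------------------------- #
# initial conditions
# --------------------------------------------------------------------------- #


def initial_conditions_1d(mesh: Mesh1D) -> SEIRDState:
    """Initial fields on [0, 1]: a large susceptible population centred at
    x = 0.35 plus smaller clusters, and a small exposed group centred at
    x = 0.75; all other compartments start at zero."""
    lo, hi = mesh.domain
    if abs(lo) > 1e-12 or abs(hi - 1.0) > 1e-12:
        raise ValueError(f"1D initial conditions are defined on [0, 1], got [{lo}, {hi}]")
    x = mesh.node_coords
    s0 = (
        np.exp(-((x + 1.0) ** 4))
        + np.exp(-((x - 0.35) ** 2) / 1e-2)
        + (np.exp(-((x - 0.62) ** 4) / 1e-5)
           + np.exp(-((x - 0.52) ** 4) / 1e-5)
           + np.exp(-((x - 0.42) ** 4) / 1e-5)) / 8.0
        + np.exp(-((x - 0.735) ** 4) / 1e-5) / 4.0
    )
    e0 = np.exp(-((x - 0.75) ** 4) / 1e-5) / 20.0
    z = np.zeros_like(x)
    return SEIRDState(0.0, mesh, s0, e0, z.copy(), z.copy(), z.copy(), z.copy())


# --------------------------------------------------------------------------- #
# semi-discrete operators
# --------------------------------------------------------------------------- #


def _allee_factor(A_e: float, n_pop: np.ndarray) -> np.ndarray:
    if A_e == 0.0:
        return np.ones_like(n_pop)
    if np.any(n_pop <= 0):
        raise ValueError("n_pop <= 0 at a node while the Allee factor requires division")
    return 1.0 - A_e / n_pop


def reaction_rates(p: dict, s, e, i, r, d) -> dict[str, np.ndarray]:
    """Nodal reaction rates f such that du/dt = f(u) in the well-mixed limit."""
    n_pop = s + e + i + r
    A = _allee_factor(p["A_e"], n_pop)
    infection = A * (p["beta_i"] * s * i + p["beta_e"] * s * e)
    return {
        "s": -infection,
        "e": infection - (p["alpha"] + p["gamma_e"]) * e,
        "i": p["alpha"] * e - (p["gamma_i"] + p["delta"]) * i,
        "r": p["gamma_e"] * e + p["gamma_i"] * i,
        "d": p["delta"] * i,
    }


def _reaction_jacobian(p: dict, s, e, i, r) -> dict[tuple[str, str], np.ndarray]:
    """Nodal partial derivatives ∂f_comp/∂u_other (Allee factor lagged)."""
    n_pop = s + e + i + r
    A = _allee_factor(p["A_e"], n_pop)
    bi, be = p["beta_i"], p["beta_e"]
    J = {
        ("s", "s"): -A * (bi * i + be * e),
        ("s", "e"): -A * be * s,
        ("s", "i"): -A * bi * s,
        ("e", "s"): A * (bi * i + be * e),
        ("e", "e"): A * be * s - (p["alpha"] + p["gamma_e"]),
        ("e", "i"): A * bi * s,
        ("i", "e"): np.full_like(s, p["alpha"]),
        ("i", "i"): np.full_like(s, -(p["gamma_i"] + p["delta"])),
        ("r", "e"): np.full_like(s, p["gamma_e"]),
        ("r", "i"): np.full_like(s, p["gamma_i"]),
        ("d", "i"): np.full_like(s, p["delta"]),
    }
    return J


def semidiscrete_residual(state: SEIRDState, params: SEIRDParams, bcs: BCSpec | None = None,
                          dudt: dict[str, np.ndarray] | None = None) -> dict[str, np.ndarray]:
    """Galerkin residual R_comp = M dudt − M f(u) + K(n_pop ν) u per compartment.

    With ``dudt`` omitted (zero), the returned vectors are minus the projected
    right-hand side: for a spatially uniform state under pure Neumann
    conditions they equal −(mass row sums)·(well-mixed ODE rates).  Dirichlet
    rows are replaced by the constraint residual u − 0.
    """
    p = params.at(state.t)
    mesh = state.mesh
    M = assemble_mass(mesh)
    f = reaction_rates(p, state.s, state.e, state.i, state.r, state.d)
    n_pop = state.n_pop()
    res = {}
    for comp in COMPARTMENTS:
        u = getattr(state, comp)
        R = -(M @ f[comp])
        if comp in DIFFUSIVE:
            K = assemble_stiffness(mesh, n_pop * p[DIFFUSIVE[comp]])
            R = R + K @ u
        if dudt is not None:
            R = R + M @ np.asarray(dudt[comp], dtype=float)
        res[comp] = R
    if bcs is not None:
        dn = bcs.dirichlet_nodes(mesh)
        for comp in COMPARTMENTS:
            res[comp][dn] = getattr(state, comp)[dn]
    return res


# --------------------------------------------------------------------------- #
# BDF2 stepping
# --------------------------------------------------------------------------- #


class NewtonError(RuntimeError):
    pass


class SEIRDSolver:
    """Implicit BDF2 stepper on a fixed mesh (rebuild after each adaptation).

    Newton iteration with analytic reaction Jacobian; the population-weighted
    stiffness operators are reassembled at every iterate but not differentiated
    (quasi-Newton lagging).  Default tolerances are tight enough that the
    discrete conservation identity holds to ~1e-12 per step.
    """

    def __init__(self, mesh, params: SEIRDParams, bcs: BCSpec,
                 newton_tol_abs: float = 1e-12, newton_tol_rel: float = 1e-10,
                 max_newton_iter: int = 25):
        self.mesh = mesh
        self.params = params
        self.bcs = bcs
        self.tol_abs = newton_tol_abs
        self.tol_rel = newton_tol_rel
        self.max_iter = max_newton_iter
        self.M = assemble_mass(mesh)
        self.dirichlet = bcs.dirichlet_nodes(mesh)
        self.min_values: dict[str, float] = {}

    # ordering of the monolithic unknown vector
    def _pack(self, fields: dict[str, np.ndarray]) -> np.ndarray:
        return np.concatenate([fields[c] for c in COMPARTMENTS])

    def _unpack(self, U: np.ndarray) -> dict[str, np.ndarray]:
        n = self.mesh.n_nodes
        return {c: U[k * n:(k + 1) * n] for k, c in enumerate(COMPARTMENTS)}

    def _residual_and_jacobian(self, U, c0, hist, t_new):
        p = self.params.at(t_new)
        n = self.mesh.n_nodes
        u = self._unpack(U)
        f = reaction_rates(p, u["s"], u["e"], u["i"], u["r"], u["d"])
        Jf = _reaction_jacobian(p, u["s"], u["e"], u["i"], u["r"])
        # transient Newton iterates may undershoot zero; the diffusion
        # coefficient is clamped to keep the operator positive semi-definite
        n_pop = np.maximum(u["s"] + u["e"] + u["i"] + u["r"], 0.0)
        M = self.M
        K = {c: assemble_stiffness(self.mesh, n_pop * p[DIFFUSIVE[c]])
             for c in DIFFUSIVE}
        res_blocks = []
        for c in COMPARTMENTS:
            R = c0 * (M @ u[c]) - M @ hist[c] - M @ f[c]
            if c in K:
                R = R + K[c] @ u[c]
            res_blocks.append(R)
        blocks = [[None] * 5 for _ in range(5)]
        for a, ca in enumerate(COMPARTMENTS):
            for b_, cb in enumerate(COMPARTMENTS):
                B = None
                if (ca, cb) in Jf:
                    B = -M.multiply(Jf[(ca, cb)][None, :])
                if a == b_:
                    diag_part = c0 * M
                    if ca in K:
                        diag_part = diag_part + K[ca]
                    B = diag_part if B is None else B + diag_part
                blocks[a][b_] = B
        J = sp.bmat(blocks, format="csr")
        res = np.concatenate(res_blocks)
        # Dirichlet constraints: row replacement + symmetric column elimination
        if len(self.dirichlet):
            mask = np.ones(5 * n)
            rows = np.concatenate([self.dirichlet + k * n for k in range(5)])
            mask[rows] = 0.0
            Dm = sp.diags(mask)
            J = Dm @ J @ Dm + sp.diags(1.0 - mask)
            res[rows] = U[rows]  # target value 0
        return res, J

    def step(self, state_n: SEIRDState, state_nm1: SEIRDState | None, dt: float) -> SEIRDState:
        """Advance one step: BDF2 when two history states exist, else backward Euler."""
        t_new = state_n.t + dt
        fields_n = {c: getattr(state_n, c) for c in COMPARTMENTS}
        if state_nm1 is None:
            c0 = 1.0 / dt
            hist = {c: fields_n[c] / dt for c in COMPARTMENTS}
        else:
            c0 = 1.5 / dt
            hist = {c: (2.0 * fields_n[c] - 0.5 * getattr(state_nm1, c)) / dt
                    for c in COMPARTMENTS}
        U = self._pack(fields_n).copy()
        res, J = self._residual_and_jacobian(U, c0, hist, t_new)
        norm0 = np.linalg.norm(res, np.inf)
        tol = max(self.tol_abs, self.tol_rel * norm0)
        converged = norm0 <= tol
        for it in range(self.max_iter):
            if converged:
                break
            dU = spla.spsolve(J.tocsc(), res)
            U = U - dU
            res, J = self._residual_and_jacobian(U, c0, hist, t_new)
            if np.linalg.norm(res, np.inf) <= tol:
                converged = True
        if not converged:
            raise NewtonError(
                f"Newton did not converge at t={t_new:g} within {self.max_iter} "
                f"iterations (residual {np.linalg.norm(res, np.inf):.3e}, tol {tol:.3e})"
            )
        u = self._unpack(U)
        # cumulative symptomatic infections: dc/dt = alpha * e, same BDF formula
        alpha = self.params.at(t_new)["alpha"]
        if state_nm1 is None:
            c_new = state_n.c + dt * alpha * u["e"]
        else:
            c_new = (4.0 * state_n.c - state_nm1.c + 2.0 * dt * alpha * u["e"]) / 3.0
        new = SEIRDState(t_new, self.mesh, u["s"].copy(), u["e"].copy(), u["i"].copy(),
                         u["r"].copy(), u["d"].copy(), c_new)
        self.min_values = {c: float(getattr(new, c).min()) for c in COMPARTMENTS}
        return new


def total_population(state: SEIRDState, normalize_by: float | None = None) -> float:
    """∫(s+e+i+r+d) dΩ, optionally normalized by a reference value."""
    total = integrate(FEField(state.mesh, state.s + state.e + state.i + state.r + state.d))
    if normalize_by is not None:
        total /= normalize_by
    return float(total)
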