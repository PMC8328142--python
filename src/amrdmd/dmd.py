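"""Exact dynamic mode decomposition with truncated (optionally randomized) SVD.

Given snapshots u_0 ... u_m sampled every ``dt_o``, the method finds the best-fit
linear map A with Y2 ≈ A Y1 (Y1/Y2 the unshifted/shifted snapshot matrices),
works in the rank-r SVD subspace of Y1, and extracts eigenpairs of the reduced
operator Ã = U_rᵀ Y2 V_r Σ_r⁻¹.  The exact-DMD modes Ψ = Y2 V_r Σ_r⁻¹ W together
with continuous eigenvalues ω = ln(λ)/dt_o and amplitudes b (least-squares fit of
Ψ b = u_0) reconstruct and extrapolate the signal as u(t) ≈ Ψ exp(ω (t−t0)) b.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la
from sklearn.utils.extmath import randomized_svd

logger = logging.getLogger(__name__)

__all__ = [
    "SnapshotSeries",
    "SVDFactors",
    "RankSelection",
    "DMDModel",
    "split_snapshots",
    "truncated_svd",
    "hard_threshold_rank",
    "fit_dmd",
    "evaluate",
    "evaluate_complex",
]

#: relative singular-value floor below which directions are treated as numerically
#: rank-deficient (guards Σ_r⁻¹ against blow-up)
SV_FLOOR = 1e-12

#: randomized-SVD parameters: oversampling columns and subspace (power) iterations
RSVD_OVERSAMPLES = 10
RSVD_POWER_ITER = 2


@dataclass
class SnapshotSeries:
    """Fixed-dimension field history: column k is the field at ``t0 + k*dt_o``."""

    values: np.ndarray
    dt_o: float
    t0: float = 0.0
    field_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D (n x m+1) array")
        if self.values.shape[1] < 2:
            raise ValueError("a snapshot series needs at least 2 columns")
        if not self.dt_o > 0:
            raise ValueError("dt_o must be positive")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_snapshots(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt_o * np.arange(self.n_snapshots)

    def window(self, t_start: float, t_end: float) -> "SnapshotSeries":
        """Sub-series of the columns with t_start <= t <= t_end (half-sample tolerance)."""
        t = self.times
        keep = (t >= t_start - 0.5 * self.dt_o * 1e-6) & (t <= t_end + 0.5 * self.dt_o * 1e-6)
        idx = np.nonzero(keep)[0]
        if len(idx) < 2:
            raise ValueError("window selects fewer than 2 snapshots")
        if np.any(np.diff(idx) != 1):
            raise ValueError("window must select contiguous columns")
        return SnapshotSeries(
            self.values[:, idx], self.dt_o, float(t[idx[0]]), self.field_name
        )


@dataclass
class SVDFactors:
    """Rank-r truncated SVD: Y1 ≈ U_r diag(S_r) V_rᵀ."""

    U_r: np.ndarray
    S_r: np.ndarray
    V_r: np.ndarray


@dataclass
class RankSelection:
    """Hard-threshold rank choice: smallest r with residual energy κ(r) <= τ."""

    r: int
    kappa: float
    tau: float


@dataclass
class DMDModel:
    """Fitted DMD: modes, discrete/continuous eigenvalues, amplitudes."""

    Psi: np.ndarray
    lam: np.ndarray
    omega: np.ndarray
    b: np.ndarray
    dt_o: float
    r: int
    t0: float = 0.0
    field_name: str = ""
    rank_selection: RankSelection | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (len(self.lam) == len(self.omega) == len(self.b) == self.Psi.shape[1]):
            raise ValueError("inconsistent mode count across Psi, lam, omega, b")


def split_snapshots(Y: SnapshotSeries) -> tuple[np.ndarray, np.ndarray]:
    """Split into the time-shifted pair: Y1 = columns 0..m-1, Y2 = columns 1..m."""
    if Y.values.shape[1] < 2:
        raise ValueError("need at least 2 snapshot columns to form the shifted pair")
    return Y.values[:, :-1], Y.values[:, 1:]


def truncated_svd(
    Y1: np.ndarray,
    r: int,
    method: str = "deterministic",
    seed: int | None = None,
) -> SVDFactors:
    """Rank-r truncated SVD of the first snapshot matrix.

    ``deterministic`` computes the full thin SVD and truncates (the Eckart-Young
    optimal rank-r approximation); ``randomized`` uses a seeded randomized range
    finder with oversampling ``RSVD_OVERSAMPLES`` and ``RSVD_POWER_ITER`` power
    iterations, near-optimal for matrices with fast singular-value decay.
    """
    Y1 = np.asarray(Y1, dtype=float)
    n, m = Y1.shape
    if not 1 <= r <= min(n, m):
        raise ValueError(f"rank r={r} out of range [1, {min(n, m)}]")
    if method == "deterministic":
        U, s, Vt = la.svd(Y1, full_matrices=False)
        return SVDFactors(U[:, :r], s[:r], Vt[:r].T)
    if method == "randomized":
        U, s, Vt = randomized_svd(
            Y1,
            n_components=r,
            n_oversamples=RSVD_OVERSAMPLES,
            n_iter=RSVD_POWER_ITER,
            random_state=np.random.RandomState(seed),
        )
        return SVDFactors(U, s, Vt.T)
    raise ValueError(f"unknown SVD method {method!r}")


def hard_threshold_rank(singular_values: np.ndarray, tau: float = 1e-6) -> RankSelection:
    """Smallest rank r whose residual energy κ(r) = 1 − Σ_{i<=r}σ_i²/Σσ_i² is <= τ.

    Retains more than 100(1−τ)% of the variance in the data.
    """
    s = np.asarray(singular_values, dtype=float)
    if np.any(s < 0):
        raise ValueError("singular values must be non-negative")
    if np.any(np.diff(s) > 1e-12 * max(s.max(initial=0.0), 1.0)):
        raise ValueError("singular values must be non-increasing")
    total = np.sum(s**2)
    if total == 0:
        raise ValueError("all-zero singular values: residual energy undefined")
    kappa_r = 1.0 - np.cumsum(s**2) / total
    kappa_r = np.maximum(kappa_r, 0.0)  # guard rounding below zero
    r = int(np.argmax(kappa_r <= tau)) + 1
    return RankSelection(r=r, kappa=float(kappa_r[r - 1]), tau=float(tau))


def fit_dmd(
    Y: SnapshotSeries,
    r: int | None = None,
    svd_method: str = "deterministic",
    seed: int | None = None,
    tau: float = 1e-6,
) -> DMDModel:
    """Fit an exact-DMD model to a snapshot series.

    When ``r`` is None the truncation rank is chosen by the hard-threshold
    energy criterion with tolerance ``tau``.  Singular values below
    ``SV_FLOOR`` relative to the largest are treated as zero and the rank is
    reduced accordingly; eigenvalues exactly zero (nilpotent directions) are
    dropped from the continuous spectrum.  Modes are ordered by non-increasing
    amplitude magnitude |b_j| (ties: |λ_j|, then original index).
    """
    Y1, Y2 = split_snapshots(Y)
    n, m = Y1.shape
    sel = None
    if r is None:
        probe = truncated_svd(Y1, min(n, m), "deterministic")
        sel = hard_threshold_rank(probe.S_r, tau)
        r = sel.r
    if not 1 <= r <= min(n, m):
        raise ValueError(f"rank r={r} out of range [1, {min(n, m)}]")

    f = truncated_svd(Y1, r, svd_method, seed)
    keep = f.S_r >= SV_FLOOR * f.S_r[0]
    if not np.all(keep):
        r_eff = int(np.count_nonzero(keep))
        warnings.warn(
            f"dropping {r - r_eff} singular value(s) below the relative floor "
            f"{SV_FLOOR:g}; truncation rank reduced to {r_eff}",
            stacklevel=2,
        )
        f = SVDFactors(f.U_r[:, keep], f.S_r[keep], f.V_r[:, keep])
        r = r_eff

    Atilde = f.U_r.T @ Y2 @ f.V_r / f.S_r  # U_rᵀ Y2 V_r Σ_r⁻¹
    lam, W = la.eig(Atilde)
    Psi = (Y2 @ f.V_r / f.S_r) @ W  # exact-DMD modes

    nonzero = np.abs(lam) > 0.0
    if not np.all(nonzero):
        warnings.warn(
            f"dropping {np.count_nonzero(~nonzero)} mode(s) with λ = 0 "
            "(nilpotent direction has no continuous eigenvalue)",
            stacklevel=2,
        )
        lam, W, Psi = lam[nonzero], W[:, nonzero], Psi[:, nonzero]
    omega = np.log(lam) / Y.dt_o  # principal branch; λ<0 maps to Im ω = π/dt_o

    u0 = Y.values[:, 0]
    b, *_ = la.lstsq(Psi, u0.astype(complex))

    order = sorted(
        range(len(b)), key=lambda j: (-np.abs(b[j]), -np.abs(lam[j]), j)
    )
    order = np.asarray(order, dtype=int)
    model = DMDModel(
        Psi=Psi[:, order],
        lam=lam[order],
        omega=omega[order],
        b=b[order],
        dt_o=Y.dt_o,
        r=len(order),
        t0=Y.t0,
        field_name=Y.field_name,
        rank_selection=sel,
    )
    nyq = np.abs(np.imag(model.omega) * Y.dt_o - np.pi) < 1e-12
    if np.any(nyq):
        logger.info(
            "%d mode(s) sit at the Nyquist frequency (negative real eigenvalue)",
            int(np.count_nonzero(nyq)),
        )
    return model


def evaluate_complex(model: DMDModel, t) -> np.ndarray:
    """Complex reconstruction Ψ exp(ω (t − t0)) b at one or several times."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    tau = t - model.t0
    time_dyn = np.exp(np.outer(model.omega, tau)) * model.b[:, None]
    return model.Psi @ time_dyn


def evaluate(model: DMDModel, t) -> np.ndarray:
    """Real part of the reconstruction; the imaginary residual is logged.

    For real training data the modes come in conjugate pairs and the imaginary
    part is numerically zero; a large residual signals a broken pairing.
    """
    rec = evaluate_complex(model, t)
    scale = np.abs(rec).max(initial=0.0)
    imag_max = np.abs(rec.imag).max(initial=0.0)
    if scale > 0:
        logger.debug("max imaginary residual %.3e (relative %.3e)", imag_max, imag_max / scale)
    return np.ascontiguousarray(rec.real)


def reconstruct_series(model: DMDModel, times: np.ndarray) -> SnapshotSeries:
    """Evaluate the model on a uniform time grid and wrap as a series."""
    times = np.asarray(times, dtype=float)
    dts = np.diff(times)
    if len(times) < 2 or not np.allclose(dts, dts[0]):
        raise ValueError("reconstruct_series needs a uniform time grid")
    vals = evaluate(model, times)
    return SnapshotSeries(vals, float(dts[0]), float(times[0]), model.field_name)
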