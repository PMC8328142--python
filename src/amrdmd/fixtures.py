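"""Synthetic snapshot generators with known ground truth.

These make every decomposition and projection stage testable without running a
PDE simulation: a planted-spectrum linear system whose exact modes, eigenvalues
and amplitudes are returned alongside the data, and the square indicator field
used in the projection worked example.  Generators are pure functions of their
parameters and seed.
"""

from __future__ import annotations

import numpy as np

from .dmd import DMDModel, SnapshotSeries
from .mesh import FEField, TriMesh2D

__all__ = ["planted_spectrum_series", "indicator_square_field"]

_OVERFLOW_CAP = 1e12  # |lambda|**m may not exceed this


def planted_spectrum_series(
    n: int,
    m: int,
    eigenvalues,
    seed: int,
    dt_o: float = 1.0,
    t0: float = 0.0,
) -> tuple[SnapshotSeries, DMDModel]:
    """Real snapshot series u_k = Re(Ψ Λᵏ b) with a planted discrete spectrum.

    ``eigenvalues`` must be closed under complex conjugation so the snapshots
    are real; modes are built from random orthonormal real directions and the
    exact generating model is returned as ground truth.  Deterministic for a
    fixed seed.
    """
    eigs = [complex(z) for z in eigenvalues]
    q = len(eigs)
    if n < q:
        raise ValueError(f"need n >= number of eigenvalues ({n} < {q})")
    if m < 1:
        raise ValueError("m must be >= 1")
    growth = max(abs(z) for z in eigs) ** (m + 1)
    if not np.isfinite(growth) or growth > _OVERFLOW_CAP:
        raise ValueError(
            f"|lambda|^m = {growth:.3g} exceeds the overflow cap {_OVERFLOW_CAP:g}"
        )
    # pair up conjugates
    remaining = list(range(q))
    kind: list[tuple] = []  # ("real", j) or ("pair", j, k)
    while remaining:
        j = remaining.pop(0)
        if abs(eigs[j].imag) < 1e-14:
            kind.append(("real", j))
            continue
        match = None
        for k in remaining:
            if abs(eigs[k] - eigs[j].conjugate()) < 1e-12:
                match = k
                break
        if match is None:
            raise ValueError(
                f"eigenvalue {eigs[j]} has no complex conjugate partner; "
                "real snapshots require a conjugation-closed spectrum"
            )
        remaining.remove(match)
        kind.append(("pair", j, match))

    rng = np.random.default_rng(seed)
    basis, _ = np.linalg.qr(rng.standard_normal((n, q)))
    lam = np.empty(q, dtype=complex)
    Psi = np.empty((n, q), dtype=complex)
    b = np.empty(q, dtype=complex)
    col = 0
    out_idx = 0
    for item in kind:
        if item[0] == "real":
            lam[out_idx] = eigs[item[1]].real
            Psi[:, out_idx] = basis[:, col]
            b[out_idx] = rng.uniform(0.5, 1.5)
            col += 1
            out_idx += 1
        else:
            z = eigs[item[1]]
            if z.imag < 0:
                z = z.conjugate()
            mode = (basis[:, col] + 1j * basis[:, col + 1]) / np.sqrt(2.0)
            amp = rng.uniform(0.5, 1.5) * np.exp(1j * rng.uniform(0, 2 * np.pi)) / 2.0
            lam[out_idx], lam[out_idx + 1] = z, z.conjugate()
            Psi[:, out_idx], Psi[:, out_idx + 1] = mode, mode.conjugate()
            b[out_idx], b[out_idx + 1] = amp, amp.conjugate()
            col += 2
            out_idx += 2

    powers = lam[:, None] ** np.arange(m + 1)[None, :]
    values = np.real(Psi @ (powers * b[:, None]))
    series = SnapshotSeries(values, dt_o, t0)
    truth = DMDModel(
        Psi=Psi,
        lam=lam,
        omega=np.log(lam) / dt_o,
        b=b,
        dt_o=dt_o,
        r=q,
        t0=t0,
    )
    return series, truth


def indicator_square_field(mesh: TriMesh2D, half_width: float = 0.3) -> FEField:
    """Nodal indicator of the closed square [-w, w]² on a mesh over [-1, 1]²."""
    x, y = mesh.node_coords[:, 0], mesh.node_coords[:, 1]
    tol = 1e-12
    inside = (np.abs(x) <= half_width + tol) & (np.abs(y) <= half_width + tol)
    return FEField(mesh, inside.astype(float))
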