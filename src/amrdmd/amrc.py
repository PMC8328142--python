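"""Adaptive refine/coarsen driver and projection of snapshots to a reference mesh.

The adaptive loop flags elements from a flux-jump error indicator, refines the
top fraction and coarsens the bottom fraction (unanimous-sibling rule), and
transfers all fields to the adapted mesh by L2-projection.  Independently of
the adaptation, every output instant each field is L2-projected onto a fixed
reference mesh, producing a snapshot stream of constant dimensionality that
decomposition methods can consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dmd import SnapshotSeries
from .mesh import FEField, L2Projector

__all__ = [
    "AMRConfig",
    "flux_jump_indicator",
    "combined_indicator",
    "flag_elements",
    "adapt_and_transfer",
    "SnapshotStream",
]


@dataclass
class AMRConfig:
    """Knobs of the adaptive loop.

    ``refine_fraction``/``coarsen_fraction`` are statistical flagging quantiles
    (top/bottom shares of the indicator distribution); ``max_level`` caps the
    refinement depth and acts as the stopping criterion.
    """

    adapt_every: int = 4
    max_level: int = 2
    refine_fraction: float = 0.3
    coarsen_fraction: float = 0.1
    indicator: str = "flux_jump"
    output_every: int = 1

    def __post_init__(self) -> None:
        if self.adapt_every < 1:
            raise ValueError("adapt_every must be >= 1")
        if self.max_level < 0:
            raise ValueError("max_level must be >= 0")
        for name in ("refine_fraction", "coarsen_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.output_every < 1:
            raise ValueError("output_every must be >= 1")


def flux_jump_indicator(field: FEField) -> np.ndarray:
    """Per-element error indicator from gradient jumps across element faces.

    1D: for element e, h_e * (|[u']| at its left node + |[u']| at its right
    node), zero jumps on the boundary.  2D: element diameter times the sum over
    its edges of |[∂u/∂n]| * edge length (interior edges only).
    """
    mesh = field.mesh
    u = field.nodal_values
    if mesh.dim == 1:
        x = mesh.node_coords
        h = mesh.element_sizes()
        grads = (u[mesh.elements[:, 1]] - u[mesh.elements[:, 0]]) / h
        jumps = np.zeros(mesh.n_nodes)
        jumps[1:-1] = np.abs(np.diff(grads))
        return h * (jumps[mesh.elements[:, 0]] + jumps[mesh.elements[:, 1]])
    # 2D: constant gradient per triangle
    tri = mesh.triangles
    p = mesh.node_coords[tri]
    areas = mesh.signed_areas()
    b = np.empty((len(tri), 3))
    c = np.empty((len(tri), 3))
    for a in range(3):
        j, k = (a + 1) % 3, (a + 2) % 3
        b[:, a] = p[:, j, 1] - p[:, k, 1]
        c[:, a] = p[:, k, 0] - p[:, j, 0]
    ue = u[tri]
    gx = np.sum(ue * b, axis=1) / (2 * areas)
    gy = np.sum(ue * c, axis=1) / (2 * areas)
    edge_owner: dict[tuple, list[int]] = {}
    for e, t in enumerate(tri):
        for a in range(3):
            key = tuple(sorted((t[a], t[(a + 1) % 3])))
            edge_owner.setdefault(key, []).append(e)
    ind = np.zeros(mesh.n_elements)
    coords = mesh.node_coords
    for (na, nb), owners in edge_owner.items():
        if len(owners) != 2:
            continue
        e0, e1 = owners
        tvec = coords[nb] - coords[na]
        elen = np.hypot(*tvec)
        nvec = np.array([tvec[1], -tvec[0]]) / elen
        jump = abs((gx[e0] - gx[e1]) * nvec[0] + (gy[e0] - gy[e1]) * nvec[1])
        ind[e0] += jump * elen
        ind[e1] += jump * elen
    return mesh.element_sizes() * ind


def combined_indicator(fields: list[FEField]) -> np.ndarray:
    """Sum of per-field flux-jump indicators, each normalized by its maximum so
    that no single large-amplitude compartment dominates the flagging."""
    total = np.zeros(fields[0].mesh.n_elements)
    for f in fields:
        ind = flux_jump_indicator(f)
        mx = ind.max(initial=0.0)
        if mx > 0:
            total += ind / mx
    return total


def flag_elements(values: np.ndarray, config: AMRConfig,
                  levels: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Statistical flagging: top ``refine_fraction`` of elements by indicator
    are flagged for refinement (suppressed at ``max_level``), bottom
    ``coarsen_fraction`` for coarsening.  Ties are broken by element id."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    ids = np.arange(n)
    order_desc = np.lexsort((ids, -values))
    order_asc = np.lexsort((ids, values))
    n_ref = int(config.refine_fraction * n)
    n_crs = int(config.coarsen_fraction * n)
    refine = np.zeros(n, dtype=bool)
    coarsen = np.zeros(n, dtype=bool)
    refine[order_desc[:n_ref]] = True
    coarsen[order_asc[:n_crs]] = True
    coarsen &= ~refine
    if levels is not None:
        refine &= np.asarray(levels) < config.max_level
    return refine, coarsen


def adapt_and_transfer(forest, flags: tuple[np.ndarray, np.ndarray],
                       fields: dict[str, np.ndarray], current_mesh,
                       max_level: int | None = None):
    """Apply refine/coarsen flags to the forest and transfer all nodal fields
    onto the adapted mesh by L2-projection.

    Returns ``(mesh, fields)`` — the same objects when nothing changed, so an
    empty flag set is bitwise idempotent.
    """
    refine_flags, coarsen_flags = flags
    changed = forest.apply_flags(refine_flags, coarsen_flags, max_level=max_level)
    if not changed:
        return current_mesh, fields
    new_mesh = forest.to_mesh()
    proj = L2Projector(current_mesh, new_mesh)
    new_fields = {name: proj.project_values(v) for name, v in fields.items()}
    return new_mesh, new_fields


class SnapshotStream:
    """Accumulates reference-mesh snapshot columns with uniform time spacing.

    The whole point of projecting onto a fixed reference mesh is a snapshot
    matrix of constant dimensionality; this container asserts it on every
    append.
    """

    def __init__(self, reference_mesh, field_name: str = ""):
        self.reference_mesh = reference_mesh
        self.field_name = field_name
        self._cols: list[np.ndarray] = []
        self._times: list[float] = []

    def append(self, values: np.ndarray, t: float) -> None:
        values = np.asarray(values, dtype=float)
        if len(values) != self.reference_mesh.n_nodes:
            raise ValueError(
                f"snapshot has {len(values)} dof, reference mesh has "
                f"{self.reference_mesh.n_nodes}"
            )
        if self._times and t <= self._times[-1]:
            raise ValueError("snapshot times must be strictly increasing")
        self._cols.append(values)
        self._times.append(float(t))

    def __len__(self) -> int:
        return len(self._cols)

    def to_series(self) -> SnapshotSeries:
        if len(self._cols) < 2:
            raise ValueError("need at least 2 snapshots to form a series")
        times = np.asarray(self._times)
        dts = np.diff(times)
        if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
            raise ValueError("snapshot stream is not uniformly spaced")
        return SnapshotSeries(
            np.column_stack(self._cols), float(dts[0]), float(times[0]), self.field_name
        )


def snapshot_to_reference(fields: dict[str, FEField] | dict[str, np.ndarray],
                          donor_mesh, streams: dict[str, SnapshotStream],
                          t: float, projector: L2Projector | None = None) -> L2Projector:
    """Project each field onto the streams' shared reference mesh and append.

    A projector built for the current donor mesh may be passed in and is
    returned for reuse while the donor mesh is unchanged.
    """
    ref = next(iter(streams.values())).reference_mesh
    if projector is None or projector.donor_mesh is not donor_mesh:
        projector = L2Projector(donor_mesh, ref)
    for name, f in fields.items():
        vals = f.nodal_values if isinstance(f, FEField) else np.asarray(f, dtype=float)
        streams[name].append(projector.project_values(vals), t)
    return projector
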