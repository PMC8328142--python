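"""File formats: snapshot containers (HDF5/CSV), DMD models, Gmsh MSH, VTK.

Snapshot container layout: one HDF5 dataset ``values`` of shape n x (m+1) with
attributes ``dt_o``, ``t0`` and ``field_name``.  DMD models store each complex
array as paired ``<name>_re`` / ``<name>_im`` datasets.  Meshes travel as Gmsh
MSH v2.2 ASCII (element type 1 = 2-node line, 2 = 3-node triangle, 1-based
node ids); fields for visualization as legacy ASCII VTK with POINT_DATA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dmd import DMDModel, SnapshotSeries
from .mesh import Mesh1D, TriMesh2D

__all__ = [
    "save_series",
    "load_series",
    "series_to_csv",
    "series_from_csv",
    "save_model",
    "load_model",
    "write_msh",
    "read_msh",
    "write_vtk",
]


# --------------------------------------------------------------------------- #
# snapshot container
# --------------------------------------------------------------------------- #


def save_series(series: SnapshotSeries, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        ds = f.create_dataset("values", data=series.values)
        ds.attrs["dt_o"] = series.dt_o
        ds.attrs["t0"] = series.t0
        ds.attrs["field_name"] = series.field_name


def load_series(path) -> SnapshotSeries:
    import h5py

    with h5py.File(path, "r") as f:
        ds = f["values"]
        return SnapshotSeries(
            ds[...],
            float(ds.attrs["dt_o"]),
            float(ds.attrs["t0"]),
            str(ds.attrs.get("field_name", "")),
        )


def series_to_csv(series: SnapshotSeries, path) -> None:
    """Small-case CSV export: one row per dof, one column per output time."""
    cols = {f"t={t:.10g}": series.values[:, k] for k, t in enumerate(series.times)}
    pd.DataFrame(cols).to_csv(path, index_label="dof")


def series_from_csv(path, field_name: str = "") -> SnapshotSeries:
    df = pd.read_csv(path, index_col="dof")
    times = np.array([float(c.split("=", 1)[1]) for c in df.columns])
    dts = np.diff(times)
    if len(times) < 2 or not np.allclose(dts, dts[0]):
        raise ValueError("CSV columns are not a uniform time grid")
    return SnapshotSeries(df.to_numpy(), float(dts[0]), float(times[0]), field_name)


# --------------------------------------------------------------------------- #
# DMD model container
# --------------------------------------------------------------------------- #


def save_model(model: DMDModel, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for name in ("Psi", "lam", "omega", "b"):
            arr = np.asarray(getattr(model, name))
            f.create_dataset(f"{name}_re", data=arr.real)
            f.create_dataset(f"{name}_im", data=arr.imag)
        f.attrs["dt_o"] = model.dt_o
        f.attrs["t0"] = model.t0
        f.attrs["r"] = model.r
        f.attrs["field_name"] = model.field_name


def load_model(path) -> DMDModel:
    import h5py

    with h5py.File(path, "r") as f:
        arrs = {
            name: f[f"{name}_re"][...] + 1j * f[f"{name}_im"][...]
            for name in ("Psi", "lam", "omega", "b")
        }
        return DMDModel(
            **arrs,
            dt_o=float(f.attrs["dt_o"]),
            r=int(f.attrs["r"]),
            t0=float(f.attrs["t0"]),
            field_name=str(f.attrs.get("field_name", "")),
        )


# --------------------------------------------------------------------------- #
# Gmsh MSH v2.2 ASCII
# --------------------------------------------------------------------------- #


def write_msh(mesh, path) -> None:
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(mesh.n_nodes)]
    if mesh.dim == 1:
        for i, x in enumerate(mesh.node_coords, start=1):
            lines.append(f"{i} {x:.16g} 0 0")
        conn = mesh.elements
        etype = 1
    else:
        for i, (x, y) in enumerate(mesh.node_coords, start=1):
            lines.append(f"{i} {x:.16g} {y:.16g} 0")
        conn = mesh.triangles
        etype = 2
    lines += ["$EndNodes", "$Elements", str(len(conn))]
    for e, nodes in enumerate(conn, start=1):
        node_str = " ".join(str(v + 1) for v in nodes)
        lines.append(f"{e} {etype} 2 0 0 {node_str}")
    lines.append("$EndElements")
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


def read_msh(path):
    with open(path) as f:
        tokens = f.read().split("\n")
    it = iter(tokens)

    def seek(tag):
        for line in it:
            if line.strip() == tag:
                return
        raise ValueError(f"section {tag} not found")

    seek("$MeshFormat")
    version = next(it).split()[0]
    if not version.startswith("2.2"):
        raise ValueError(f"unsupported MSH version {version} (need 2.2 ASCII)")
    seek("$Nodes")
    n_nodes = int(next(it))
    coords = np.empty((n_nodes, 3))
    for k in range(n_nodes):
        parts = next(it).split()
        coords[k] = [float(v) for v in parts[1:4]]
    seek("$Elements")
    n_el = int(next(it))
    lines_conn, tris_conn = [], []
    for _ in range(n_el):
        parts = next(it).split()
        etype = int(parts[1])
        ntags = int(parts[2])
        nodes = [int(v) - 1 for v in parts[3 + ntags:]]
        if etype == 1:
            lines_conn.append(nodes)
        elif etype == 2:
            tris_conn.append(nodes)
        # other element types (points, quads, ...) are skipped
    if tris_conn:
        tris = np.array(tris_conn, dtype=int)
        # restore counterclockwise orientation if the file stored it flipped
        pts = coords[:, :2]
        p = pts[tris]
        area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
            p[:, 2, 0] - p[:, 0, 0]
        ) * (p[:, 1, 1] - p[:, 0, 1])
        flip = area2 < 0
        tris[flip] = tris[flip][:, ::-1]
        return TriMesh2D(pts, tris)
    if lines_conn:
        order = np.argsort(coords[:, 0])
        rank = np.empty(n_nodes, dtype=int)
        rank[order] = np.arange(n_nodes)
        conn = rank[np.array(lines_conn, dtype=int)]
        conn.sort(axis=1)
        conn = conn[np.argsort(conn[:, 0])]
        return Mesh1D(coords[order, 0], conn)
    raise ValueError("no line or triangle elements in MSH file")


# --------------------------------------------------------------------------- #
# legacy VTK
# --------------------------------------------------------------------------- #


def write_vtk(mesh, fields: dict[str, np.ndarray], path, title: str = "amrdmd output") -> None:
    """Legacy ASCII VTK unstructured grid with one scalar per field."""
    lines = ["# vtk DataFile Version 3.0", title, "ASCII", "DATASET UNSTRUCTURED_GRID"]
    n = mesh.n_nodes
    lines.append(f"POINTS {n} double")
    if mesh.dim == 1:
        for x in mesh.node_coords:
            lines.append(f"{x:.16g} 0 0")
        conn = mesh.elements
        cell_type = 3  # VTK_LINE
    else:
        for x, y in mesh.node_coords:
            lines.append(f"{x:.16g} {y:.16g} 0")
        conn = mesh.triangles
        cell_type = 5  # VTK_TRIANGLE
    nper = conn.shape[1]
    lines.append(f"CELLS {len(conn)} {len(conn) * (nper + 1)}")
    for nodes in conn:
        lines.append(f"{nper} " + " ".join(str(v) for v in nodes))
    lines.append(f"CELL_TYPES {len(conn)}")
    lines.extend([str(cell_type)] * len(conn))
    lines.append(f"POINT_DATA {n}")
    for name, values in fields.items():
        values = np.asarray(values, dtype=float)
        if len(values) != n:
            raise ValueError(f"field {name!r} has {len(values)} values for {n} nodes")
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.16g}" for v in values)
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")
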