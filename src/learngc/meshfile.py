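"""Mesh I/O: PLY (via trimesh) and legacy ASCII VTK polydata.

Per-node scalar arrays (ground-truth labels, predicted probabilities) are
stored as VTK POINT_DATA fields; the PLY path writes a plain mesh plus a
sidecar CSV with the scalars, which keeps both files human-readable.
"""

from __future__ import annotations

import numpy as np
import trimesh

from .surface import SurfaceMesh

__all__ = ["write_vtk", "read_vtk", "write_ply", "read_ply"]


def write_vtk(path: str, mesh: SurfaceMesh, point_data: dict | None = None) -> None:
    v, f = mesh.vertices, mesh.faces
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nlearngc surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} float\n")
        for p in v:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
        for tri in f:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        if point_data:
            fh.write(f"POINT_DATA {len(v)}\n")
            for name, values in point_data.items():
                values = np.asarray(values, dtype=float)
                if len(values) != len(v):
                    raise ValueError(f"point data {name!r} has wrong length")
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{x:.6f}" for x in values) + "\n")


def read_vtk(path: str) -> tuple[SurfaceMesh, dict]:
    with open(path) as fh:
        tokens = fh.read().split()
    def grab(kw):
        return tokens.index(kw)
    i = grab("POINTS")
    n = int(tokens[i + 1])
    pts = np.array(tokens[i + 3:i + 3 + 3 * n], dtype=float).reshape(n, 3)
    i = grab("POLYGONS")
    nf = int(tokens[i + 1])
    raw = np.array(tokens[i + 3:i + 3 + 4 * nf], dtype=int).reshape(nf, 4)
    if not np.all(raw[:, 0] == 3):
        raise ValueError("only triangle polydata is supported")
    point_data: dict[str, np.ndarray] = {}
    j = 0
    while "SCALARS" in tokens[j:]:
        j = tokens.index("SCALARS", j) + 1
        name = tokens[j]
        start = tokens.index("default", j) + 1
        point_data[name] = np.array(tokens[start:start + n], dtype=float)
        j = start + n
    return SurfaceMesh(pts, raw[:, 1:]), point_data


def write_ply(path: str, mesh: SurfaceMesh, point_data: dict | None = None) -> None:
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    tm.export(path, file_type="ply", encoding="ascii")
    if point_data:
        import pandas as pd
        pd.DataFrame({k: np.asarray(v) for k, v in point_data.items()}).to_csv(
            path + ".csv", index_label="node")


def read_ply(path: str) -> SurfaceMesh:
    tm = trimesh.load(path, file_type="ply", process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
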