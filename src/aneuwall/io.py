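"""Mesh and table IO: STL/OBJ/PLY in, STL/CSV/JSON out."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .analysis import CoefficientRecord
from .cohort import CohortTable
from .mesh import MeshError, TriangleMesh

__all__ = ["read_mesh", "read_stl", "write_stl", "read_table", "write_table",
           "write_report", "write_thickness_csv", "read_thickness_csv"]


def read_mesh(path) -> TriangleMesh:
    """Read STL (binary or ASCII, auto-detected), OBJ or PLY."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mesh file not found: {path}")
    loaded = trimesh.load_mesh(str(path), process=False)
    if isinstance(loaded, trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if not geoms:
            raise MeshError(f"no geometry in {path}")
        loaded = trimesh.util.concatenate(geoms)
    # drop exact duplicate vertices STL stores per-facet
    loaded.merge_vertices()
    return TriangleMesh(np.asarray(loaded.vertices, dtype=float),
                        np.asarray(loaded.faces, dtype=np.int64))


read_stl = read_mesh


def write_stl(mesh: TriangleMesh, path, ascii_format: bool = False) -> None:
    """Write binary STL by default, ASCII on request."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if ascii_format:
        path.write_text(tm.export(file_type="stl_ascii"))
    else:
        path.write_bytes(tm.export(file_type="stl"))


def read_table(path) -> CohortTable:
    """Read a cohort table CSV (columns id, group, location, I_S, volume_mm3, I_BA, I_delta)."""
    df = pd.read_csv(path)
    records = [CoefficientRecord(
        id=int(row.id), location=str(row.location), I_S=float(row.I_S),
        volume=float(row.volume_mm3), I_BA=float(row.I_BA),
        I_delta=float(row.I_delta), group=str(row.group),
    ) for row in df.itertuples()]
    return CohortTable(records=records)


def write_table(table: CohortTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_frame().to_csv(path, index=False)


def write_report(report: dict, path) -> None:
    """Deterministic JSON report (sorted keys, fixed float formatting)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def write_thickness_csv(mesh: TriangleMesh, stretch: np.ndarray,
                        thickness: np.ndarray, path) -> None:
    df = pd.DataFrame({
        "vertex": np.arange(len(mesh.vertices)),
        "x": mesh.vertices[:, 0], "y": mesh.vertices[:, 1],
        "z": mesh.vertices[:, 2],
        "stretch": stretch, "thickness": thickness,
    })
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_thickness_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
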