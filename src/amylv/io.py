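"""File formats: legacy-VTK meshes, PLY surfaces, CSV tables, fit JSON.

Meshes travel as ASCII legacy VTK unstructured grids (hexahedral cells,
with optional per-cell fiber/sheet vectors); surfaces as PLY via trimesh;
regional strain tables and curves as plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import LVMesh, triangulate_quads
from .geometry import RegionalStrainField
from .mechanics import PressureVolumeCurve, StressStretchCurve

__all__ = [
    "write_vtk",
    "read_vtk_points_cells",
    "write_surface_ply",
    "strain_table",
    "write_strain_csv",
    "write_curve_csv",
    "read_curve_csv",
]


def write_vtk(path, mesh: LVMesh, comment: str = "amylv LV wall mesh") -> None:
    """Write the mesh as an ASCII legacy VTK unstructured grid."""
    path = Path(path)
    n = mesh.n_nodes
    e = mesh.n_elements
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{comment}\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} double\n")
        np.savetxt(fh, mesh.points, fmt="%.9g")
        fh.write(f"CELLS {e} {e * 9}\n")
        cells = np.column_stack([np.full(e, 8, dtype=np.int64), mesh.hexes])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {e}\n")
        np.savetxt(fh, np.full(e, 12, dtype=np.int64), fmt="%d")
        if mesh.fiber is not None:
            fh.write(f"CELL_DATA {e}\n")
            fh.write("VECTORS fiber double\n")
            np.savetxt(fh, mesh.fiber, fmt="%.9g")
            if mesh.sheet is not None:
                fh.write("VECTORS sheet double\n")
                np.savetxt(fh, mesh.sheet, fmt="%.9g")


def read_vtk_points_cells(path):
    """Read points and hexahedral cells back from a legacy ASCII VTK file."""
    lines = Path(path).read_text().splitlines()
    i = 0
    points = cells = None
    while i < len(lines):
        tok = lines[i].split()
        if tok and tok[0] == "POINTS":
            n = int(tok[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(v) for v in lines[i].split())
                i += 1
            points = np.array(vals).reshape(n, 3)
            continue
        if tok and tok[0] == "CELLS":
            e = int(tok[1])
            rows = []
            i += 1
            for _ in range(e):
                row = [int(v) for v in lines[i].split()]
                if row[0] != 8:
                    raise ValueError("only hexahedral cells supported")
                rows.append(row[1:])
                i += 1
            cells = np.array(rows, dtype=np.int64)
            continue
        i += 1
    if points is None or cells is None:
        raise ValueError("not a recognisable legacy VTK unstructured grid")
    return points, cells


def write_surface_ply(path, mesh: LVMesh, surface: str = "endo") -> None:
    """Export one surface (triangulated) as PLY."""
    import trimesh

    faces = mesh.endo_faces if surface == "endo" else mesh.epi_faces
    tris = triangulate_quads(faces)
    uniq, inv = np.unique(tris, return_inverse=True)
    tm = trimesh.Trimesh(
        vertices=mesh.points[uniq], faces=inv.reshape(tris.shape), process=False
    )
    tm.export(str(path))


# ---------------------------------------------------------------------------


def strain_table(field: RegionalStrainField) -> pd.DataFrame:
    """Long-format regional strain table (frame, layer, region, E_cc, E_ll)."""
    rows = []
    for j in range(field.n_frames):
        for k in range(field.n_layer):
            for r in range(field.n_reg):
                rows.append(
                    (j + 1, k + 1, r + 1, field.E_cc[k, r, j], field.E_ll[k, r, j])
                )
    return pd.DataFrame(rows, columns=["frame", "layer", "region", "E_cc", "E_ll"])


def write_strain_csv(path, field: RegionalStrainField) -> None:
    strain_table(field).to_csv(path, index=False, float_format="%.9g")


def write_curve_csv(path, curve) -> None:
    """Two-column CSV for p-V or stress-stretch curves."""
    if isinstance(curve, PressureVolumeCurve):
        df = pd.DataFrame(
            {"pressure_mmHg": curve.pressures, "volume_mL": curve.volumes}
        )
    elif isinstance(curve, StressStretchCurve):
        df = pd.DataFrame(
            {"stretch": curve.stretches, "cauchy_stress_kPa": curve.stresses}
        )
    else:
        raise TypeError("unsupported curve type")
    df.to_csv(path, index=False, float_format="%.9g")


def read_curve_csv(path):
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[:2] == ["pressure_mmHg", "volume_mL"]:
        return PressureVolumeCurve(df[cols[0]].to_numpy(), df[cols[1]].to_numpy())
    if cols[:2] == ["stretch", "cauchy_stress_kPa"]:
        return StressStretchCurve(df[cols[0]].to_numpy(), df[cols[1]].to_numpy())
    raise ValueError("unrecognised curve CSV header")


def write_fit_json(path, result) -> None:
    Path(path).write_text(result.to_json())


def read_fit_json(path) -> dict:
    return json.loads(Path(path).read_text())
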