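"""Minimal legacy-ASCII VTK export for meshes and solution fields.

Writes unstructured tetrahedral grids with point and cell data in the
legacy VTK 2.0 text format, which every common viewer (ParaView, VisIt,
pyvista) reads. Only the subset needed by this package is implemented.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .meshing import Mesh

__all__ = ["write_vtk"]


def _write_array(fh, name: str, values: np.ndarray):
    values = np.asarray(values)
    if values.ndim == 1:
        fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, values, fmt="%.9g")
    elif values.ndim == 2 and values.shape[1] == 3:
        fh.write(f"VECTORS {name} double\n")
        np.savetxt(fh, values, fmt="%.9g")
    else:
        raise ValueError(f"unsupported data shape {values.shape} for {name}")


def write_vtk(path, mesh: Mesh,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> Path:
    """Write the mesh (plus optional nodal/cell fields) as a .vtk file.

    ``point_data`` arrays must have length ``mesh.n_vertices`` (or be dicts
    of per-subspace values already scattered to the full vertex set);
    ``cell_data`` arrays length ``mesh.n_cells``. Domain tags are always
    included as cell data.
    """
    path = Path(path)
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})
    cell_data.setdefault("domain", mesh.domain_tags.astype(float))

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 2.0\n")
        fh.write("spherotrap tagged tetrahedral mesh\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        np.savetxt(fh, mesh.vertices, fmt="%.9g")
        nt = mesh.n_cells
        fh.write(f"CELLS {nt} {5 * nt}\n")
        conn = np.column_stack([np.full(nt, 4), mesh.cells])
        np.savetxt(fh, conn, fmt="%d")
        fh.write(f"CELL_TYPES {nt}\n")
        np.savetxt(fh, np.full(nt, 10), fmt="%d")   # VTK_TETRA
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, values in point_data.items():
                _write_array(fh, name, values)
        fh.write(f"CELL_DATA {nt}\n")
        for name, values in cell_data.items():
            _write_array(fh, name, values)
    return path
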