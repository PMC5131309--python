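"""Minimal legacy-ASCII VTK output for structured (uniform Cartesian) fields.

Writes STRUCTURED_POINTS datasets with CELL_DATA so grids and per-cell fields
can be inspected in ParaView. Kept dependency-free on purpose.
"""

from __future__ import annotations

import os

import numpy as np

from .geometry import Grid2D

__all__ = ["write_vtk_cells"]


def write_vtk_cells(path: str | os.PathLike, grid: Grid2D, fields: dict[str, np.ndarray]) -> str:
    """Write per-cell scalar ``fields`` (each shape (ny, nx)) to legacy VTK."""
    path = os.fspath(path)
    lines = [
        "# vtk DataFile Version 3.0",
        "thrombosim structured cell data",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {grid.nx + 1} {grid.ny + 1} 1",
        f"ORIGIN {grid.origin[0]:.9e} {grid.origin[1]:.9e} 0.0",
        f"SPACING {grid.dx:.9e} {grid.dy:.9e} 1.0",
        f"CELL_DATA {grid.nx * grid.ny}",
    ]
    for name, arr in fields.items():
        a = np.asarray(arr)
        if a.shape != (grid.ny, grid.nx):
            raise ValueError(f"field {name!r} has shape {a.shape}, expected {(grid.ny, grid.nx)}")
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(" ".join(f"{v:.9e}" for v in row) for row in a)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
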