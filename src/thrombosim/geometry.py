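"""Structured 2D grids with boundary tagging for the surrogate flow domains.

All grids are uniform Cartesian (``dx == dy``), built from a cell count across
the principal channel height. Cells carry exactly one tag (FLUID, SOLID, INLET,
OUTLET); walls are represented stair-step fashion by SOLID cells or by the
domain boundary. Reactive (platelet-adhesive) wall faces are tracked per
fluid-cell face. Out-of-plane depth is 1 m, so face "areas" are lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "FLUID",
    "SOLID",
    "INLET",
    "OUTLET",
    "XM",
    "XP",
    "YM",
    "YP",
    "FACE_NORMALS",
    "GeometryError",
    "Grid2D",
    "WallFace",
    "build_channel",
    "build_backward_facing_step",
    "build_crevice_channel",
    "wall_faces",
    "validate_grid",
]

FLUID = 0
SOLID = 1
INLET = 2
OUTLET = 3

# Face direction codes; normals point out of the fluid cell.
XM, XP, YM, YP = 0, 1, 2, 3
FACE_NORMALS = {XM: (-1, 0), XP: (1, 0), YM: (0, -1), YP: (0, 1)}
_FACE_SHIFT = {XM: (0, -1), XP: (0, 1), YM: (-1, 0), YP: (1, 0)}


class GeometryError(ValueError):
    """Raised for invalid grid dimensions or inconsistent tagging."""


@dataclass(frozen=True)
class WallFace:
    """One fluid-cell face lying on a wall (SOLID neighbor or domain edge)."""

    j: int
    i: int
    direction: int  # XM/XP/YM/YP
    area: float  # m^2 per unit depth (== dx or dy)
    reactive: bool

    @property
    def normal(self) -> tuple[int, int]:
        return FACE_NORMALS[self.direction]


@dataclass
class Grid2D:
    """Uniform Cartesian grid with per-cell tags and reactive wall faces.

    ``cell_type`` has shape ``(ny, nx)`` indexed ``[j, i]`` with x increasing
    streamwise (i) and y increasing upward (j). ``reactive_wall`` has shape
    ``(4, ny, nx)``: entry ``[d, j, i]`` flags face ``d`` of cell ``(j, i)``
    as a platelet-adhesive wall face.
    """

    nx: int
    ny: int
    dx: float
    dy: float
    cell_type: np.ndarray
    reactive_wall: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cell_type = np.ascontiguousarray(self.cell_type, dtype=np.int8)
        self.reactive_wall = np.ascontiguousarray(self.reactive_wall, dtype=bool)
        validate_grid(self)

    # -- convenience masks -------------------------------------------------
    @property
    def fluid_mask(self) -> np.ndarray:
        return self.cell_type == FLUID

    @property
    def solid_mask(self) -> np.ndarray:
        return self.cell_type == SOLID

    @property
    def inlet_mask(self) -> np.ndarray:
        return self.cell_type == INLET

    @property
    def outlet_mask(self) -> np.ndarray:
        return self.cell_type == OUTLET

    @property
    def cell_volume(self) -> float:
        """Cell volume in m^3 (unit out-of-plane depth)."""
        return self.dx * self.dy

    def x_centers(self) -> np.ndarray:
        return self.origin[0] + (np.arange(self.nx) + 0.5) * self.dx

    def y_centers(self) -> np.ndarray:
        return self.origin[1] + (np.arange(self.ny) + 0.5) * self.dy

    def padded_types(self) -> np.ndarray:
        """Cell types padded by one ring of SOLID (the domain exterior)."""
        return np.pad(self.cell_type, 1, mode="constant", constant_values=SOLID)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Grid2D):
            return NotImplemented
        return (
            self.nx == other.nx
            and self.ny == other.ny
            and self.dx == other.dx
            and self.dy == other.dy
            and self.origin == other.origin
            and np.array_equal(self.cell_type, other.cell_type)
            and np.array_equal(self.reactive_wall, other.reactive_wall)
        )


def _wall_face_mask(grid: Grid2D) -> np.ndarray:
    """Boolean (4, ny, nx): faces of FLUID cells adjacent to SOLID/exterior."""
    pad = grid.padded_types()
    fluid = grid.fluid_mask
    core = pad[1:-1, 1:-1]
    assert core.shape == fluid.shape
    out = np.zeros((4,) + fluid.shape, dtype=bool)
    out[XM] = fluid & (pad[1:-1, :-2] == SOLID)
    out[XP] = fluid & (pad[1:-1, 2:] == SOLID)
    out[YM] = fluid & (pad[:-2, 1:-1] == SOLID)
    out[YP] = fluid & (pad[2:, 1:-1] == SOLID)
    return out


def validate_grid(grid: Grid2D) -> None:
    """Check the structural invariants; raise GeometryError on violation."""
    if grid.nx < 4 or grid.ny < 4:
        raise GeometryError(f"grid must be at least 4x4, got {grid.nx}x{grid.ny}")
    if grid.dx <= 0 or grid.dy <= 0:
        raise GeometryError("cell spacing must be positive")
    if grid.cell_type.shape != (grid.ny, grid.nx):
        raise GeometryError("cell_type shape mismatch")
    if grid.reactive_wall.shape != (4, grid.ny, grid.nx):
        raise GeometryError("reactive_wall shape mismatch")
    if not np.isin(grid.cell_type, [FLUID, SOLID, INLET, OUTLET]).all():
        raise GeometryError("unknown cell tag")

    walls = _wall_face_mask(grid)
    if np.any(grid.reactive_wall & ~walls):
        raise GeometryError("reactive_wall flags a face that is not a wall face")

    n_inlet = int(grid.inlet_mask.sum())
    n_outlet = int(grid.outlet_mask.sum())
    if (n_inlet == 0) != (n_outlet == 0):
        raise GeometryError("open domains need both INLET and OUTLET cells")
    if n_inlet:
        open_mask = grid.cell_type != SOLID
        labels, _ = ndimage.label(open_mask)
        fluid_labels = set(np.unique(labels[grid.fluid_mask]))
        inlet_labels = set(np.unique(labels[grid.inlet_mask]))
        outlet_labels = set(np.unique(labels[grid.outlet_mask]))
        if not fluid_labels <= (inlet_labels & outlet_labels):
            raise GeometryError(
                "every FLUID region must be connected to an INLET and an OUTLET"
            )


def wall_faces(grid: Grid2D) -> list[WallFace]:
    """Enumerate every FLUID face adjacent to a SOLID cell or the domain edge.

    Faces toward INLET/OUTLET cells are open boundaries, not walls. The
    enumeration order is deterministic (row-major over cells, then XM/XP/YM/YP).
    """
    walls = _wall_face_mask(grid)
    faces: list[WallFace] = []
    areas = {XM: grid.dy, XP: grid.dy, YM: grid.dx, YP: grid.dx}
    for j in range(grid.ny):
        for i in range(grid.nx):
            for d in (XM, XP, YM, YP):
                if walls[d, j, i]:
                    faces.append(
                        WallFace(
                            j=j,
                            i=i,
                            direction=d,
                            area=areas[d],
                            reactive=bool(grid.reactive_wall[d, j, i]),
                        )
                    )
    return faces


def _resolve_counts(length: float, h_ref: float, n_across: int) -> tuple[float, int]:
    if length <= 0 or h_ref <= 0:
        raise GeometryError("dimensions must be positive")
    if n_across < 4:
        raise GeometryError("n_across must be >= 4")
    d = h_ref / n_across
    n_len = int(round(length / d))
    if n_len < 2:
        raise GeometryError("length too short for the requested resolution")
    return d, n_len


def build_channel(
    length: float,
    height: float,
    n_across: int,
    *,
    reactive_walls: bool = True,
) -> Grid2D:
    """Straight channel: left column INLET, right column OUTLET.

    ``n_across`` cells span ``height``; ``dx == dy``. The inlet/outlet columns
    are appended outside ``length`` so the fluid section has the requested
    extent. Top and bottom walls are reactive by default.
    """
    d, n_len = _resolve_counts(length, height, n_across)
    nx = n_len + 2
    ny = n_across
    ct = np.full((ny, nx), FLUID, dtype=np.int8)
    ct[:, 0] = INLET
    ct[:, -1] = OUTLET
    grid = Grid2D(nx, ny, d, d, ct, np.zeros((4, ny, nx), dtype=bool))
    if reactive_walls:
        walls = _wall_face_mask(grid)
        grid.reactive_wall[YM] = walls[YM]
        grid.reactive_wall[YP] = walls[YP]
    grid.meta.update(preset="channel", length=length, height=height)
    return grid


def build_backward_facing_step(
    inlet_h: float,
    outlet_h: float,
    step_x: float,
    length: float,
    n_across: int,
) -> Grid2D:
    """Channel with a sudden expansion at ``step_x``.

    The inlet section of height ``inlet_h`` sits on top of a SOLID block that
    ends at ``step_x``; downstream the full ``outlet_h`` is open, creating a
    recirculation zone behind the step. ``n_across`` cells span ``outlet_h``.
    The step face and all downstream walls are reactive.
    """
    if not (0 < inlet_h < outlet_h):
        raise GeometryError("require outlet_h > inlet_h > 0")
    if not (0 < step_x < length):
        raise GeometryError("require 0 < step_x < length")
    d, n_len = _resolve_counts(length, outlet_h, n_across)
    n_step = int(round(step_x / d))
    n_block = int(round((outlet_h - inlet_h) / d))  # solid rows below inlet
    if n_step < 2 or n_block < 1 or n_block >= n_across:
        raise GeometryError("step geometry unresolvable at this resolution")
    nx = n_len + 1  # outlet column appended beyond `length`
    ny = n_across
    ct = np.full((ny, nx), FLUID, dtype=np.int8)
    ct[:n_block, :n_step] = SOLID  # block spans [0, step_x) incl. sub-inlet rows
    ct[n_block:, 0] = INLET
    ct[:, -1] = OUTLET
    grid = Grid2D(nx, ny, d, d, ct, np.zeros((4, ny, nx), dtype=bool))
    walls = _wall_face_mask(grid)
    # reactive: the step face and every wall at/downstream of the expansion
    downstream = np.zeros((4, ny, nx), dtype=bool)
    downstream[:, :, n_step:] = True
    grid.reactive_wall[:] = walls & downstream
    grid.meta.update(
        preset="backward_facing_step",
        inlet_h=inlet_h,
        outlet_h=outlet_h,
        step_x=step_x,
        length=length,
        n_step=n_step,
        n_block=n_block,
    )
    return grid


def build_crevice_channel(
    channel_h: float,
    crevice_w: float,
    crevice_d: float,
    length: float,
    n_across: int,
) -> Grid2D:
    """Straight channel with a rectangular cavity sunk into the lower wall.

    The cavity (width ``crevice_w``, depth ``crevice_d``) is centered along the
    channel and mimics a stagnant bearing-crevice region. Only the cavity walls
    are reactive. ``n_across`` cells span ``channel_h``.
    """
    if crevice_w <= 0 or crevice_d <= 0:
        raise GeometryError("crevice dimensions must be positive")
    d, n_len = _resolve_counts(length, channel_h, n_across)
    n_cw = int(round(crevice_w / d))
    n_cd = int(round(crevice_d / d))
    if n_cw < 1 or n_cd < 1:
        raise GeometryError("crevice unresolvable at this resolution")
    if n_cw > n_len - 2:
        raise GeometryError("crevice wider than the channel")
    nx = n_len + 2
    ny = n_across + n_cd
    ct = np.full((ny, nx), SOLID, dtype=np.int8)
    ct[n_cd:, 1:-1] = FLUID
    i0 = 1 + (n_len - n_cw) // 2
    ct[:n_cd, i0 : i0 + n_cw] = FLUID
    ct[n_cd:, 0] = INLET
    ct[n_cd:, -1] = OUTLET
    grid = Grid2D(nx, ny, d, d, ct, np.zeros((4, ny, nx), dtype=bool))
    walls = _wall_face_mask(grid)
    cavity = np.zeros((4, ny, nx), dtype=bool)
    cavity[:, :n_cd, :] = True  # wall faces of cells inside the cavity
    grid.reactive_wall[:] = walls & cavity
    grid.meta.update(
        preset="crevice_channel",
        channel_h=channel_h,
        crevice_w=crevice_w,
        crevice_d=crevice_d,
        length=length,
        n_cw=n_cw,
        n_cd=n_cd,
        i0=i0,
    )
    return grid
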