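"""Species transport, surface deposition, shear cleaning, and thrombus update.

The seven free-stream species are advected (first-order upwind, flux form) and
diffused with their effective diffusivities; the three deposited species have
no transport and evolve by local rate equations. Platelets move between the
free and deposited pools only through number-conserving transfer channels
(deposition, cleaning), so a discrete platelet ledger closes to roundoff.

Deposition model: on a reactive wall face the flux crosses over from
platelet-surface kinetics (k_rpd_b, k_apd_b, saturating with monolayer
capacity M_inf) to platelet-platelet kinetics (k_ra, k_aa) as the surface
fills; once a cell packs to phi_crit its fluid neighbors become
deposition-active with platelet-platelet kinetics (thrombus propagation).
Shear cleaning removes RP_d/AP_d above a characteristic stress (tau_sc_b on
the biomaterial surface, tau_sc on platelet layers) and returns them to the
free stream in their pre-deposition state; stabilized platelets (AP_s) are
immune to cleaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import FLUID, INLET, OUTLET, Grid2D
from .hemodynamics import FlowState
from . import kinetics as kin

__all__ = [
    "StabilityError",
    "TransportParams",
    "SpeciesState",
    "ThrombusState",
    "effective_diffusivity",
    "make_species_state",
    "transport_step",
    "wall_geometry",
    "deposition_fluxes",
    "cleaning_rates",
    "stabilization_rate",
    "apply_surface_processes",
    "update_thrombus",
]

class StabilityError(ValueError):
    """Raised when a requested transport step exceeds the stability limit."""

    def __init__(self, message: str, suggested_dt: float):
        super().__init__(message)
        self.suggested_dt = suggested_dt


# default effective diffusivities, m^2/s, ordered as kinetics.SPECIES.
# Red-cell-augmented values (Zydney-Colton scale); molecular diffusivities
# alone starve the wall of platelets at these cell sizes.
_D_DEFAULT = (1.25e-9, 1.25e-9, 2.5e-9, 2.5e-9, 1.0e-9, 1.0e-9, 1.0e-9)


@dataclass(frozen=True)
class TransportParams:
    """Transport, deposition, cleaning and packing parameters.

    Deposition rate constants are deliberately reaction-limited (chi * k_aa
    below the diffusive delivery velocity D/dy) so that agonist chemistry and
    anticoagulation — not delivery alone — control the deposition rate.
    """

    D_l: tuple = _D_DEFAULT  # effective diffusivity per free species, m^2/s
    Sc: float = 0.9  # turbulent Schmidt number
    nu_t: float = 0.0  # eddy viscosity (laminar runs: 0), m^2/s
    k_rpd_b: float = 2.0e-9  # RP -> surface deposition rate, m/s
    k_apd_b: float = 1.0e-7  # AP -> surface deposition rate, m/s
    k_ra: float = 5.0e-10  # RP -> thrombus deposition rate, m/s
    k_aa: float = 6.0e-7  # AP -> thrombus deposition rate, m/s
    tau_sc: float = 1.5  # platelet-platelet cleavage stress, Pa (15 dyne/cm^2)
    tau_sc_b: float = 0.15  # platelet-surface cleavage stress, Pa
    k_clean: float = 10.0  # cleaning rate scale, 1/s
    k_stab: float = 0.02  # AP_d -> AP_s stabilization rate, 1/s
    M_inf: float = 1.0e10  # wall monolayer capacity, PLT/m^2
    V_p: float = 1.1e-17  # single-platelet volume, m^3
    phi_max: float = 0.8  # packing limit
    phi_crit: float = 0.72  # propagation threshold (0.9 * phi_max)

    def __post_init__(self) -> None:
        if len(self.D_l) != 7 or any(d <= 0 for d in self.D_l):
            raise ValueError("need 7 positive laminar diffusivities")
        pos = (
            self.Sc,
            self.k_rpd_b,
            self.k_apd_b,
            self.k_ra,
            self.k_aa,
            self.tau_sc,
            self.tau_sc_b,
            self.k_clean,
            self.k_stab,
            self.M_inf,
            self.V_p,
            self.phi_max,
            self.phi_crit,
        )
        if any(v <= 0 for v in pos):
            raise ValueError("transport parameters must be positive")
        if not self.phi_crit <= self.phi_max <= 1.0:
            raise ValueError("require phi_crit <= phi_max <= 1")

    def effective_D(self) -> np.ndarray:
        return np.array([effective_diffusivity(d, self.nu_t, self.Sc) for d in self.D_l])


def effective_diffusivity(D_l: float, nu_t: float, Sc: float) -> float:
    """D = D_laminar + nu_t / Sc (turbulent contribution, inactive when nu_t=0)."""
    if Sc <= 0:
        raise ValueError("Schmidt number must be positive")
    if D_l <= 0 or nu_t < 0:
        raise ValueError("require D_l > 0 and nu_t >= 0")
    return D_l + nu_t / Sc


@dataclass
class SpeciesState:
    """Free-stream fields (7, ny, nx) and deposited fields (3, ny, nx)."""

    free: np.ndarray
    dep: np.ndarray

    def copy(self) -> "SpeciesState":
        return SpeciesState(self.free.copy(), self.dep.copy())

    def deposited_total(self) -> np.ndarray:
        """Deposited platelet number density per cell, PLT/m^3."""
        return self.dep.sum(axis=0)


@dataclass
class ThrombusState:
    """Deposited-platelet packing state derived from the species fields."""

    phi: np.ndarray  # volume fraction per cell, clipped at phi_max
    active_mask: np.ndarray  # cells currently accepting deposition
    capacity_used: np.ndarray  # monolayer fraction consumed, per wall cell
    core_mask: np.ndarray  # cells at/above phi_crit
    grow_area: np.ndarray | None = None  # face area shared with core cells


def make_species_state(grid: Grid2D, inlet: np.ndarray) -> SpeciesState:
    """Initial state: the domain filled with inlet blood, no deposits."""
    inlet = np.asarray(inlet, dtype=float)
    free = np.zeros((7, grid.ny, grid.nx))
    carry = grid.fluid_mask | grid.inlet_mask | grid.outlet_mask
    free[:, carry] = inlet[:, None]
    dep = np.zeros((3, grid.ny, grid.nx))
    return SpeciesState(free, dep)


# ---------------------------------------------------------------------------
# cached per-grid wall geometry


def wall_geometry(grid: Grid2D) -> dict:
    """Per-cell wall areas (m^2 per depth): total and reactive-only."""
    cached = grid.meta.get("_wall_geom")
    if cached is not None:
        return cached
    from .geometry import _wall_face_mask

    walls = _wall_face_mask(grid)
    areas = np.array([grid.dy, grid.dy, grid.dx, grid.dx])
    total = np.tensordot(areas, walls, axes=(0, 0))
    reactive = np.tensordot(areas, walls & grid.reactive_wall, axes=(0, 0))
    geom = {"wall_area": total, "reactive_area": reactive}
    grid.meta["_wall_geom"] = geom
    return geom


def _neighbor_face_area(grid: Grid2D, mask: np.ndarray) -> np.ndarray:
    """For each cell, total face area shared with ``mask`` 4-neighbors."""
    out = np.zeros(mask.shape)
    out[:, 1:] += grid.dy * mask[:, :-1]
    out[:, :-1] += grid.dy * mask[:, 1:]
    out[1:, :] += grid.dx * mask[:-1, :]
    out[:-1, :] += grid.dx * mask[1:, :]
    return out


def update_thrombus(
    species: SpeciesState, params: TransportParams, grid: Grid2D
) -> ThrombusState:
    """Recompute phi, the deposition-active mask, and wall capacity usage."""
    geom = wall_geometry(grid)
    n_dep = species.deposited_total()
    phi = np.minimum(n_dep * params.V_p, params.phi_max)
    core = phi >= params.phi_crit
    wall_cells = geom["reactive_area"] > 0
    neighbor_area = _neighbor_face_area(grid, core)
    active = grid.fluid_mask & (wall_cells | core | (neighbor_area > 0))
    cap = np.zeros_like(phi)
    cap[wall_cells] = np.minimum(
        1.0,
        n_dep[wall_cells]
        * grid.cell_volume
        / (params.M_inf * geom["reactive_area"][wall_cells]),
    )
    return ThrombusState(
        phi=phi,
        active_mask=active,
        capacity_used=cap,
        core_mask=core,
        grow_area=neighbor_area,
    )


# ---------------------------------------------------------------------------
# transport


def transport_step(
    grid: Grid2D,
    flow: FlowState,
    species: SpeciesState,
    sources: tuple[np.ndarray, np.ndarray] | None,
    params: TransportParams,
    dt: float,
    inlet: np.ndarray | None = None,
    record: dict | None = None,
) -> SpeciesState:
    """Advance the ten fields by ``dt``: advect+diffuse+react free species,
    apply rate sources to the deposited species.

    ``sources`` is ``(s_free, s_dep)`` (per-cell rates) or None. ``inlet``
    gives the 7 inlet concentrations (Dirichlet); if None, the values stored
    in the INLET cells are used. When ``record`` is a dict, the advective
    boundary fluxes are accumulated into it (keys ``inflow``/``outflow``,
    arrays of shape (7,), units: amount per unit depth) for ledger checks.
    """
    dx, dy = grid.dx, grid.dy
    limit = stable_transport_dt(grid, flow, params, cfl=1.0)
    if dt > limit * (1.0 + 1e-9):
        raise StabilityError(
            f"transport step dt={dt:.3e} s violates the explicit stability "
            f"limit; use dt <= {0.8 * limit:.3e} s",
            suggested_dt=0.8 * limit,
        )
    ws = _workspace(grid)

    C = ws["C"]
    np.copyto(C, species.free)
    if inlet is not None:
        C[:, ws["in_j"], ws["in_i"]] = np.asarray(inlet, dtype=float)[:, None]
    # zero-gradient mirror into the outlet column for the upwind donor
    C[:, ws["out_j"], ws["out_i"]] = C[:, ws["out_j"], ws["out_i"] - 1]

    u, v = flow.u, flow.v
    up = np.maximum(u, 0.0)
    un = np.minimum(u, 0.0)
    vp = np.maximum(v, 0.0)
    vn = np.minimum(v, 0.0)

    Cpx = ws["Cpx"]
    Cpx[:, :, 1:-1] = C
    Cpx[:, :, 0] = C[:, :, 0]
    Cpx[:, :, -1] = C[:, :, -1]
    Cpy = ws["Cpy"]
    Cpy[:, 1:-1, :] = C
    Cpy[:, 0, :] = C[:, 0, :]
    Cpy[:, -1, :] = C[:, -1, :]

    Fx = ws["Fx"]
    np.multiply(Cpx[:, :, :-1], up[None], out=Fx)
    Fx += un[None] * Cpx[:, :, 1:]
    Fy = ws["Fy"]
    np.multiply(Cpy[:, :-1, :], vp[None], out=Fy)
    Fy += vn[None] * Cpy[:, 1:, :]

    if record is not None:
        record["inflow"] = record.get("inflow", 0.0) + dt * dy * Fx[:, ws["finf"]].sum(
            axis=1
        )
        record["outflow"] = record.get("outflow", 0.0) + dt * dy * Fx[
            :, ws["fout"]
        ].sum(axis=1)

    # diffusion only across FLUID-FLUID faces (zero-flux walls and open ends)
    D = params.effective_D()[:, None, None]
    Fx[:, :, 1:-1] -= (D * ws["ff_x"][None] / dx) * (C[:, :, 1:] - C[:, :, :-1])
    Fy[:, 1:-1, :] -= (D * ws["ff_y"][None] / dy) * (C[:, 1:, :] - C[:, :-1, :])

    # flux divergence is identically zero on SOLID cells (all face velocities
    # vanish, diffusion is masked) and on INLET/OUTLET cells (uniform donor
    # values), so the update can be applied unmasked; INLET cells are then
    # re-pinned to the Dirichlet values.
    new_free = C - dt * (
        (Fx[:, :, 1:] - Fx[:, :, :-1]) / dx + (Fy[:, 1:, :] - Fy[:, :-1, :]) / dy
    )
    new_dep = species.dep.copy()
    if sources is not None:
        s_free, s_dep = sources
        new_free += dt * s_free
        new_dep += dt * s_dep
    if inlet is not None:
        new_free[:, ws["in_j"], ws["in_i"]] = np.asarray(inlet, dtype=float)[:, None]
    return SpeciesState(new_free, new_dep)


def _workspace(grid: Grid2D) -> dict:
    """Cached masks, index arrays and scratch buffers for transport_step."""
    ws = grid.meta.get("_transport_ws")
    if ws is not None:
        return ws
    fluid = grid.fluid_mask
    ny, nx = grid.ny, grid.nx
    pad = grid.padded_types()
    L = pad[1:-1, :-1]
    R = pad[1:-1, 1:]
    in_j, in_i = np.nonzero(grid.inlet_mask)
    out_j, out_i = np.nonzero(grid.outlet_mask)
    ws = {
        "fluid": fluid,
        "in_j": in_j,
        "in_i": in_i,
        "out_j": out_j,
        "out_i": out_i,
        "ff_x": fluid[:, :-1] & fluid[:, 1:],
        "ff_y": fluid[:-1, :] & fluid[1:, :],
        "finf": (L == INLET) & (R == FLUID),
        "fout": (L == FLUID) & (R == OUTLET),
        "C": np.zeros((7, ny, nx)),
        "Cpx": np.zeros((7, ny, nx + 2)),
        "Cpy": np.zeros((7, ny + 2, nx)),
        "Fx": np.zeros((7, ny, nx + 1)),
        "Fy": np.zeros((7, ny + 1, nx)),
    }
    grid.meta["_transport_ws"] = ws
    return ws


def stable_transport_dt(
    grid: Grid2D, flow: FlowState, params: TransportParams, cfl: float = 0.8
) -> float:
    """Combined advective (upwind) + diffusive explicit stability bound."""
    umax = max(np.abs(flow.u).max(), 1e-12)
    vmax = max(np.abs(flow.v).max(), 1e-12)
    dmax = params.effective_D().max()
    dt_adv = 1.0 / (umax / grid.dx + vmax / grid.dy)
    dt_diff = 0.5 / (dmax * (1.0 / grid.dx**2 + 1.0 / grid.dy**2))
    return cfl * min(dt_adv, dt_diff)


# ---------------------------------------------------------------------------
# surface processes (deposition, cleaning, stabilization)


def deposition_fluxes(
    grid: Grid2D,
    species: SpeciesState,
    thrombus: ThrombusState,
    params: TransportParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Volumetric deposition rates (PLT/m^3/s) for RP->RP_d and AP->AP_d.

    Wall term: flux (k_*_b (1-cap) + k_thrombus cap) * C over the reactive
    wall area of the cell. Propagation term: platelet-platelet flux k_ra/k_aa
    over face area shared with packed (phi >= phi_crit) neighbor cells.
    Cells packed to phi_max accept no further deposit.
    """
    geom = wall_geometry(grid)
    V = grid.cell_volume
    cap = thrombus.capacity_used
    a_wall = geom["reactive_area"]
    a_grow = (
        thrombus.grow_area
        if thrombus.grow_area is not None
        else _neighbor_face_area(grid, thrombus.core_mask)
    )
    open_cells = (thrombus.phi < params.phi_max) & grid.fluid_mask

    k_rp = (params.k_rpd_b * (1.0 - cap) + params.k_ra * cap) * a_wall
    k_ap = (params.k_apd_b * (1.0 - cap) + params.k_aa * cap) * a_wall
    k_rp = k_rp + params.k_ra * a_grow
    k_ap = k_ap + params.k_aa * a_grow
    scale = np.where(open_cells, 1.0 / V, 0.0)
    r_rp = k_rp * species.free[kin.I_RP] * scale
    r_ap = k_ap * species.free[kin.I_AP] * scale
    return r_rp, r_ap


def cleaning_rates(
    deposited_rp: np.ndarray,
    deposited_ap: np.ndarray,
    tau_local: np.ndarray,
    on_surface: np.ndarray,
    params: TransportParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Shear-cleaning removal rates (PLT/m^3/s) for RP_d and AP_d.

    Linear excess-stress law with threshold tau_sc_b on the biomaterial
    surface and tau_sc on platelet-on-platelet layers; AP_s is never removed.
    """
    tau_star = np.where(on_surface, params.tau_sc_b, params.tau_sc)
    excess = np.maximum(0.0, tau_local / tau_star - 1.0)
    k = params.k_clean * excess
    return k * deposited_rp, k * deposited_ap


def stabilization_rate(ap_d: np.ndarray, params: TransportParams) -> np.ndarray:
    """Constant-rate conversion AP_d -> AP_s (PLT/m^3/s)."""
    return params.k_stab * np.asarray(ap_d)


def apply_surface_processes(
    grid: Grid2D,
    species: SpeciesState,
    thrombus: ThrombusState,
    tau_cell: np.ndarray,
    params: TransportParams,
    dt: float,
) -> dict:
    """Apply deposition, cleaning and stabilization transfers for one step.

    All channels are donor-limited (a transfer never overdraws its source
    within the step), which preserves both non-negativity and the platelet
    ledger exactly. Modifies ``species`` in place; returns diagnostics with
    the transferred amounts (PLT per unit depth).
    """
    V = grid.cell_volume
    free = species.free
    dep = species.dep

    # deposition (free -> deposited)
    r_rp, r_ap = deposition_fluxes(grid, species, thrombus, params)
    # propagation into a cell may only proceed up to the packing limit
    room = np.maximum(0.0, params.phi_max / params.V_p - species.deposited_total())
    tot = r_rp + r_ap
    lim = np.where(tot * dt > room, room / np.where(tot > 0, tot * dt, 1.0), 1.0)
    d_rp = np.minimum(r_rp * lim * dt, free[kin.I_RP])
    d_ap = np.minimum(r_ap * lim * dt, free[kin.I_AP])
    free[kin.I_RP] -= d_rp
    free[kin.I_AP] -= d_ap
    dep[0] += d_rp
    dep[1] += d_ap

    # cleaning (deposited -> free), not on stabilized platelets
    geom = wall_geometry(grid)
    on_surface = geom["wall_area"] > 0
    c_rp_rate, c_ap_rate = cleaning_rates(dep[0], dep[1], tau_cell, on_surface, params)
    c_rp = np.minimum(c_rp_rate * dt, dep[0])
    c_ap = np.minimum(c_ap_rate * dt, dep[1])
    dep[0] -= c_rp
    dep[1] -= c_ap
    free[kin.I_RP] += c_rp
    free[kin.I_AP] += c_ap

    # stabilization (AP_d -> AP_s)
    s_ap = np.minimum(stabilization_rate(dep[1], params) * dt, dep[1])
    dep[1] -= s_ap
    dep[2] += s_ap

    return {
        "deposited": float((d_rp + d_ap).sum() * V),
        "cleaned": float((c_rp + c_ap).sum() * V),
        "stabilized": float(s_ap.sum() * V),
    }
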