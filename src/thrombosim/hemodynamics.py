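"""Incompressible flow with a porous-thrombus momentum sink.

Fractional-step (projection) solver on a staggered (MAC) arrangement:
first-order upwind advection and explicit viscous diffusion, with the drag
term ``-C2 * f(phi) * v`` integrated implicitly (pointwise) because its
coefficient can reach ~1.6e10 kg/(m^3 s) at packing density. The thrombus
phase is static (``v_T = 0``): only stator-like walls are modeled.

Boundary conditions: uniform inlet velocity, outlet pressure 0 Pa, no-slip
walls (mirror ghosts at stair-step solid boundaries). Runs are laminar; an
additive eddy-viscosity slot (``mu_turb``) is retained but defaults to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import FLUID, INLET, OUTLET, SOLID, YM, YP, Grid2D, wall_faces

__all__ = [
    "FlowParams",
    "FlowState",
    "FlowSolver",
    "SolverError",
    "hindrance",
    "drag_coefficient",
    "flow_step",
    "solve_steady_flow",
    "wall_shear_stress",
    "cell_shear_stress",
    "divergence",
]


class SolverError(RuntimeError):
    """Raised when the pressure solve or time stepping fails."""


@dataclass(frozen=True)
class FlowParams:
    """Physical and numerical parameters of the fluid phase."""

    mu_f: float = 3.5e-3  # dynamic viscosity, Pa s
    rho_f0: float = 1060.0  # pure-fluid density, kg/m^3
    C2: float = 2.0e9  # thrombus resistance coefficient, kg/(m^3 s)
    mu_turb: float = 0.0  # additive eddy viscosity (laminar runs: 0)
    u_inlet: float = 0.0  # uniform inlet speed, m/s (+x)
    cfl: float = 0.4
    div_tol: float = 1e-8  # max |div u| accepted after projection, 1/s
    max_iters: int = 200_000
    steady_tol: float = 1e-3  # relative acceleration threshold for steady state

    def __post_init__(self) -> None:
        if min(self.mu_f, self.rho_f0) <= 0 or self.C2 < 0 or self.mu_turb < 0:
            raise ValueError("physical flow parameters must be positive")

    @property
    def mu_eff(self) -> float:
        return self.mu_f + self.mu_turb

    @property
    def nu(self) -> float:
        return self.mu_eff / self.rho_f0


@dataclass
class FlowState:
    """Face-normal velocities and cell pressures of the fluid phase.

    ``u`` has shape (ny, nx+1) on x-faces, ``v`` shape (ny+1, nx) on y-faces,
    ``p`` shape (ny, nx) at cell centers (Pa).
    """

    u: np.ndarray
    v: np.ndarray
    p: np.ndarray

    def copy(self) -> "FlowState":
        return FlowState(self.u.copy(), self.v.copy(), self.p.copy())

    def validate(self) -> None:
        for name in ("u", "v", "p"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise SolverError(f"non-finite values in FlowState.{name}")


def hindrance(phi):
    """Drag hindrance factor f(phi) = phi * (1 + 6.5 phi) on [0, 1]."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi > 1):
        raise ValueError("volume fraction must lie in [0, 1]")
    out = phi * (1.0 + 6.5 * phi)
    return float(out) if out.ndim == 0 else out


def drag_coefficient(phi, params: FlowParams):
    """Isotropic momentum-sink coefficient C2 * f(phi), kg/(m^3 s)."""
    return params.C2 * hindrance(phi)


def _edge_mean(a: np.ndarray, axis: int) -> np.ndarray:
    """Face-interpolate a cell field along ``axis`` with edge extension."""
    pad = [(0, 0), (0, 0)]
    pad[axis] = (1, 1)
    ap = np.pad(a, pad, mode="edge")
    if axis == 1:
        return 0.5 * (ap[:, :-1] + ap[:, 1:])
    return 0.5 * (ap[:-1, :] + ap[1:, :])


class FlowSolver:
    """Projection solver bound to one grid + parameter set.

    The pressure-Poisson operator depends only on the grid (density is held
    at ``rho_f0``), so its LU factorization is computed once per instance.
    """

    def __init__(self, grid: Grid2D, params: FlowParams):
        self.grid = grid
        self.params = params
        ny, nx = grid.ny, grid.nx
        pad = grid.padded_types()

        # ---- u-face classification: face i lies between cells (j,i-1),(j,i)
        L = pad[1:-1, :-1]
        R = pad[1:-1, 1:]
        self.u_unknown = (L == FLUID) & ((R == FLUID) | (R == OUTLET))
        self.u_inletf = (L == INLET) | (R == INLET)
        self.u_ghost_out = L == OUTLET  # zero-gradient copies past the outlet
        # mirror masks for tangential (y) neighbors: both cells above/below solid
        self.u_mirror_up = (pad[2:, :-1] == SOLID) & (pad[2:, 1:] == SOLID)
        self.u_mirror_dn = (pad[:-2, :-1] == SOLID) & (pad[:-2, 1:] == SOLID)

        # ---- v-face classification: face j lies between cells (j-1,i),(j,i)
        B = pad[:-1, 1:-1]
        T = pad[1:, 1:-1]
        self.v_unknown = (B == FLUID) & (T == FLUID)
        self.v_ghost_out = ((B == OUTLET) | (T == OUTLET)) & ~self.v_unknown
        self.v_mirror_lf = (pad[:-1, :-2] == SOLID) & (pad[1:, :-2] == SOLID)
        self.v_mirror_rt = (pad[:-1, 2:] == SOLID) & (pad[1:, 2:] == SOLID)

        # inlet/outlet faces for flux bookkeeping (normal +x flow assumed)
        self.u_inflow_faces = (L == INLET) & (R == FLUID)
        self.u_outflow_faces = (L == FLUID) & (R == OUTLET)

        self.fluid = grid.fluid_mask
        ny_, nx_ = grid.ny, grid.nx
        idx = -np.ones((ny_, nx_), dtype=np.int64)
        idx[self.fluid] = np.arange(int(self.fluid.sum()))
        self.cell_index = idx
        self._pinned = not np.any(self.u_outflow_faces)
        self._lu = None
        self._lu_key: tuple | None = None  # (dt, phi snapshot)
        self._beta_u = None
        self._beta_v = None

    # ------------------------------------------------------------------
    def _face_sink(self, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Darcy sink coefficient C2 f(phi)/rho interpolated to u/v faces."""
        p = self.params
        k_u = drag_coefficient(_edge_mean(phi, axis=1), p) / p.rho_f0
        k_v = drag_coefficient(_edge_mean(phi, axis=0), p) / p.rho_f0
        return k_u, k_v

    def _ensure_poisson(self, phi: np.ndarray, dt: float) -> None:
        """(Re)build the variable-coefficient projection operator.

        The projection solves div(beta grad p) = div(u*) with
        beta = dt / (rho (1 + dt k)) on faces, so the implicit Darcy sink acts
        consistently on the pressure correction and the steady momentum
        balance (viscous + Darcy + pressure) is recovered exactly.
        """
        key = self._lu_key
        if (
            key is not None
            and abs(key[0] - dt) <= 1e-12 * dt
            and np.array_equal(key[1], phi)
        ):
            return
        g, p = self.grid, self.params
        ny, nx = g.ny, g.nx
        k_u, k_v = self._face_sink(phi)
        beta_u = dt / (p.rho_f0 * (1.0 + dt * k_u))
        beta_v = dt / (p.rho_f0 * (1.0 + dt * k_v))
        idx = self.cell_index
        n = int(self.fluid.sum())
        pad = g.padded_types()
        rows, cols, vals = [], [], []
        diag = np.zeros(n)
        wx, wy = 1.0 / g.dx**2, 1.0 / g.dy**2
        # (dj, di, axis weight, face-beta getter)
        shifts = [
            (-1, 0, wy, beta_v[:-1, :]),  # south face of cell (j,i): v[j,i]
            (1, 0, wy, beta_v[1:, :]),  # north face: v[j+1,i]
            (0, -1, wx, beta_u[:, :-1]),  # west face: u[j,i]
            (0, 1, wx, beta_u[:, 1:]),  # east face: u[j,i+1]
        ]
        for dj, di, w, bface in shifts:
            nb = pad[1 + dj : 1 + dj + ny, 1 + di : 1 + di + nx]
            open_f = self.fluid & (nb == FLUID)
            dir_f = self.fluid & (nb == OUTLET)  # Dirichlet p = 0 ghost
            both = open_f | dir_f
            diag[idx[both]] += w * bface[both]
            jj, ii = np.nonzero(open_f)
            rows.append(idx[jj, ii])
            cols.append(idx[jj + dj, ii + di])
            vals.append(-w * bface[jj, ii])
        rows = np.concatenate(rows + [np.arange(n)])
        cols = np.concatenate(cols + [np.arange(n)])
        vals = np.concatenate(vals + [diag])
        A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
        if self._pinned:  # pure-Neumann closed box: pin one pressure
            A = A.tolil()
            A[0, 0] += wx * beta_u.max()
            A = A.tocsc()
        self._lu = splu(A)
        self._lu_key = (dt, phi.copy())
        self._beta_u, self._beta_v = beta_u, beta_v

    # ------------------------------------------------------------------
    def initial_state(self) -> FlowState:
        g = self.grid
        u = np.zeros((g.ny, g.nx + 1))
        v = np.zeros((g.ny + 1, g.nx))
        self._apply_bcs(u, v)
        return FlowState(u, v, np.zeros((g.ny, g.nx)))

    def _apply_bcs(self, u: np.ndarray, v: np.ndarray) -> None:
        u[~(self.u_unknown | self.u_ghost_out)] = 0.0
        u[self.u_inletf] = self.params.u_inlet
        v[~(self.v_unknown | self.v_ghost_out)] = 0.0
        # zero-gradient ghosts past the outlet column
        jj, ii = np.nonzero(self.u_ghost_out)
        u[jj, ii] = u[jj, ii - 1]
        jj, ii = np.nonzero(self.v_ghost_out)
        v[jj, ii] = v[jj, ii - 1]

    def stable_dt(self, flow: FlowState) -> float:
        g, p = self.grid, self.params
        umax = max(np.abs(flow.u).max(), abs(p.u_inlet), 1e-12)
        vmax = max(np.abs(flow.v).max(), 1e-12)
        dt_adv = min(g.dx / umax, g.dy / vmax)
        dt_visc = 0.5 / (p.nu * (1.0 / g.dx**2 + 1.0 / g.dy**2))
        return p.cfl * min(dt_adv, dt_visc)

    # ------------------------------------------------------------------
    def _predict(self, u: np.ndarray, v: np.ndarray, phi: np.ndarray, dt: float):
        g, p = self.grid, self.params
        dx, dy, nu = g.dx, g.dy, p.nu

        # shifted neighbor values with mirror ghosts at solid walls
        u_w = np.empty_like(u)
        u_w[:, 1:] = u[:, :-1]
        u_w[:, 0] = u[:, 0]
        u_e = np.empty_like(u)
        u_e[:, :-1] = u[:, 1:]
        u_e[:, -1] = u[:, -1]
        u_up = np.empty_like(u)
        u_up[:-1, :] = u[1:, :]
        u_up[-1, :] = 0.0
        u_up = np.where(self.u_mirror_up, -u, u_up)
        u_dn = np.empty_like(u)
        u_dn[1:, :] = u[:-1, :]
        u_dn[0, :] = 0.0
        u_dn = np.where(self.u_mirror_dn, -u, u_dn)

        vp = np.pad(v, ((0, 0), (1, 1)), mode="edge")
        vbar = 0.25 * (vp[:-1, :-1] + vp[:-1, 1:] + vp[1:, :-1] + vp[1:, 1:])

        adv_u = u * np.where(u > 0, (u - u_w) / dx, (u_e - u) / dx) + vbar * np.where(
            vbar > 0, (u - u_dn) / dy, (u_up - u) / dy
        )
        lap_u = (u_e - 2 * u + u_w) / dx**2 + (u_up - 2 * u + u_dn) / dy**2

        v_dn = np.empty_like(v)
        v_dn[1:, :] = v[:-1, :]
        v_dn[0, :] = v[0, :]
        v_up = np.empty_like(v)
        v_up[:-1, :] = v[1:, :]
        v_up[-1, :] = v[-1, :]
        v_lf = np.empty_like(v)
        v_lf[:, 1:] = v[:, :-1]
        v_lf[:, 0] = 0.0
        v_lf = np.where(self.v_mirror_lf, -v, v_lf)
        v_rt = np.empty_like(v)
        v_rt[:, :-1] = v[:, 1:]
        v_rt[:, -1] = 0.0
        v_rt = np.where(self.v_mirror_rt, -v, v_rt)

        up = np.pad(u, ((1, 1), (0, 0)), mode="edge")
        ubar = 0.25 * (up[:-1, :-1] + up[:-1, 1:] + up[1:, :-1] + up[1:, 1:])

        adv_v = ubar * np.where(
            ubar > 0, (v - v_lf) / dx, (v_rt - v) / dx
        ) + v * np.where(v > 0, (v - v_dn) / dy, (v_up - v) / dy)
        lap_v = (v_rt - 2 * v + v_lf) / dx**2 + (v_up - 2 * v + v_dn) / dy**2

        k_u, k_v = self._face_sink(phi)

        u_star = u.copy()
        v_star = v.copy()
        upd = self.u_unknown
        u_star[upd] = (u[upd] + dt * (-adv_u[upd] + nu * lap_u[upd])) / (
            1.0 + dt * k_u[upd]
        )
        upd = self.v_unknown
        v_star[upd] = (v[upd] + dt * (-adv_v[upd] + nu * lap_v[upd])) / (
            1.0 + dt * k_v[upd]
        )
        return u_star, v_star

    def _project(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        g = self.grid
        div = (u[:, 1:] - u[:, :-1]) / g.dx + (v[1:, :] - v[:-1, :]) / g.dy
        rhs = np.zeros(self._lu.shape[0])
        rhs[self.cell_index[self.fluid]] = -div[self.fluid]
        pr = self._lu.solve(rhs)
        pres = np.zeros((g.ny, g.nx))
        pres[self.fluid] = pr
        # correct unknown faces; ghost pressures are 0 at the outlet (Dirichlet)
        gpx = np.zeros_like(u)
        gpx[:, 1:-1] = (pres[:, 1:] - pres[:, :-1]) / g.dx
        gpy = np.zeros_like(v)
        gpy[1:-1, :] = (pres[1:, :] - pres[:-1, :]) / g.dy
        u[self.u_unknown] -= self._beta_u[self.u_unknown] * gpx[self.u_unknown]
        v[self.v_unknown] -= self._beta_v[self.v_unknown] * gpy[self.v_unknown]
        return pres

    def step(self, flow: FlowState, phi: np.ndarray, dt: float) -> FlowState:
        """Advance one projection step of size ``dt`` (caller ensures stability)."""
        self._ensure_poisson(phi, dt)
        u = flow.u.copy()
        v = flow.v.copy()
        self._apply_bcs(u, v)
        u, v = self._predict(u, v, phi, dt)
        pres = self._project(u, v)
        self._apply_bcs(u, v)
        new = FlowState(u, v, pres)
        new.validate()
        return new

    def advance(self, flow: FlowState, phi: np.ndarray, dt: float) -> FlowState:
        """Advance by ``dt``, internally sub-stepping to satisfy stability."""
        remaining = float(dt)
        state = flow
        h = min(self.stable_dt(state), remaining)
        while remaining > 1e-15 * dt:
            cand = self.stable_dt(state)
            # keep h fixed while admissible to avoid refactorizing the
            # projection operator every sub-step
            if cand < h or cand > 2.0 * h:
                h = cand
            h = min(h, remaining)
            state = self.step(state, phi, h)
            remaining -= h
        return state

    def solve_steady(
        self,
        phi: np.ndarray,
        flow: FlowState | None = None,
        max_steps: int | None = None,
    ) -> FlowState:
        """Pseudo-time march to steady state.

        Convergence: the maximum face acceleration |du|/dt falls below
        ``steady_tol * U_ref * nu / H^2`` (the slowest viscous decay scale),
        or the state stops changing to near machine precision.
        """
        g, p = self.grid, self.params
        state = flow.copy() if flow is not None else self.initial_state()
        H = g.ny * g.dy
        max_steps = max_steps if max_steps is not None else p.max_iters
        dt = self.stable_dt(state)
        for _ in range(max_steps):
            cand = self.stable_dt(state)
            if cand < dt or cand > 2.0 * dt:
                dt = cand
            new = self.step(state, phi, dt)
            du = max(
                np.abs(new.u - state.u).max(initial=0.0),
                np.abs(new.v - state.v).max(initial=0.0),
            )
            u_ref = max(abs(p.u_inlet), np.abs(new.u).max(initial=0.0), 1e-30)
            state = new
            if du / dt <= p.steady_tol * u_ref * p.nu / H**2 or du <= 1e-14 * u_ref:
                return state
        raise SolverError(
            f"steady flow solve did not converge within {max_steps} steps "
            f"(last residual {du / dt:.3e})"
        )

    # ------------------------------------------------------------------
    def boundary_fluxes(self, flow: FlowState) -> tuple[float, float]:
        """(inlet, outlet) volumetric fluxes in m^3/s per unit depth."""
        dy = self.grid.dy
        q_in = float(flow.u[self.u_inflow_faces].sum() * dy)
        q_out = float(flow.u[self.u_outflow_faces].sum() * dy)
        return q_in, q_out


def divergence(grid: Grid2D, flow: FlowState) -> np.ndarray:
    """Discrete divergence (1/s) on cells; meaningful on FLUID cells."""
    return (flow.u[:, 1:] - flow.u[:, :-1]) / grid.dx + (
        flow.v[1:, :] - flow.v[:-1, :]
    ) / grid.dy


# ---------------------------------------------------------------------------
# module-level API with a per-grid solver cache


def _get_solver(grid: Grid2D, params: FlowParams) -> FlowSolver:
    cached = grid.meta.get("_flow_solver")
    if cached is not None and cached[0] == params:
        return cached[1]
    solver = FlowSolver(grid, params)
    grid.meta["_flow_solver"] = (params, solver)
    return solver


def flow_step(
    grid: Grid2D,
    flow: FlowState,
    phi_field: np.ndarray,
    params: FlowParams,
    dt: float,
) -> FlowState:
    """Advance the flow by ``dt`` (sub-stepped internally for stability)."""
    return _get_solver(grid, params).advance(flow, phi_field, dt)


def solve_steady_flow(
    grid: Grid2D,
    phi_field: np.ndarray,
    params: FlowParams,
    flow: FlowState | None = None,
) -> FlowState:
    """March to steady state from ``flow`` (or rest)."""
    return _get_solver(grid, params).solve_steady(phi_field, flow)


def wall_shear_stress(grid: Grid2D, flow: FlowState, mu_f: float) -> np.ndarray:
    """Wall shear stress magnitude (Pa) per face, aligned with wall_faces(grid).

    One-sided difference: tangential cell-center velocity over the half-cell
    distance to the wall. 1 dyne/cm^2 = 0.1 Pa.
    """
    faces = wall_faces(grid)
    tau = np.empty(len(faces))
    u, v = flow.u, flow.v
    for n, f in enumerate(faces):
        if f.direction in (YM, YP):
            ut = 0.5 * (u[f.j, f.i] + u[f.j, f.i + 1])
            tau[n] = mu_f * abs(ut) / (0.5 * grid.dy)
        else:
            vt = 0.5 * (v[f.j, f.i] + v[f.j + 1, f.i])
            tau[n] = mu_f * abs(vt) / (0.5 * grid.dx)
    return tau


def cell_shear_stress(grid: Grid2D, flow: FlowState, mu_f: float) -> np.ndarray:
    """Cell-centered shear stress magnitude mu * sqrt(2 D:D) (Pa).

    Used for shear cleaning inside the domain; wall-adjacent cells should be
    combined with the one-sided wall value by the caller.
    """
    uc = 0.5 * (flow.u[:, 1:] + flow.u[:, :-1])
    vc = 0.5 * (flow.v[1:, :] + flow.v[:-1, :])
    uc = np.where(grid.fluid_mask, uc, 0.0)
    vc = np.where(grid.fluid_mask, vc, 0.0)
    dudy, dudx = np.gradient(uc, grid.dy, grid.dx)
    dvdy, dvdx = np.gradient(vc, grid.dy, grid.dx)
    mag = np.sqrt(2.0 * (dudx**2 + dvdy**2) + (dudy + dvdx) ** 2)
    return np.where(grid.fluid_mask, mu_f * mag, 0.0)
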