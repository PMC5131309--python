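"""Scenario configuration and the coupled time-stepping driver.

Operator-splitting order per step (fixed):
flow (quasi-steady, refreshed when the thrombus has grown) -> species
transport + reaction -> surface deposition fluxes -> cleaning/stabilization ->
thrombus update. The deposition timescale is far slower than the flow
timescale, so the flow is only re-solved when the packing field has changed
materially (frozen-flow coupling).

Reaction-rate time scaling: the four deposition rate constants (k_ra, k_aa,
k_rpd_b, k_apd_b) are multiplied by chi (default 30) and all reported times
are scaled by the same factor, exploiting the high Damköhler numbers of the
species network.

Everything is single-threaded and deterministic: identical configurations
produce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import io
import json
import zipfile
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import kinetics as kin
from .geometry import (
    Grid2D,
    build_backward_facing_step,
    build_channel,
    build_crevice_channel,
)
from .hemodynamics import (
    FlowParams,
    FlowSolver,
    FlowState,
    cell_shear_stress,
    wall_shear_stress,
)
from .transport_deposition import (
    SpeciesState,
    ThrombusState,
    TransportParams,
    apply_surface_processes,
    make_species_state,
    stable_transport_dt,
    transport_step,
    update_thrombus,
    wall_geometry,
)
from .vtkio import write_vtk_cells

__all__ = [
    "ScenarioConfig",
    "ResultBundle",
    "Simulation",
    "CheckpointError",
    "scale_reaction_rates",
    "make_scenario",
    "run_simulation",
    "save_checkpoint",
    "load_checkpoint",
    "table1_inlet",
]

CHECKPOINT_SCHEMA = 1

_GEOMETRY_BUILDERS = {
    "channel": build_channel,
    "backward_facing_step": build_backward_facing_step,
    "crevice_channel": build_crevice_channel,
}


def table1_inlet(rp: float = 3.0e14) -> np.ndarray:
    """Default inlet concentrations: RP, AP=0.01*RP, agonists 0, PT, T=0, AT."""
    return np.array([rp, 0.01 * rp, 0.0, 0.0, 1.1e-6, 0.0, 2.844e-6])


_DEFAULT_INLET = tuple(float(x) for x in table1_inlet())


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one simulation run."""

    geometry: dict = field(
        default_factory=lambda: {
            "preset": "crevice_channel",
            "channel_h": 1.0e-3,
            "crevice_w": 1.0e-3,
            "crevice_d": 2.5e-4,
            "length": 4.0e-3,
            "n_across": 16,
        }
    )
    u_inlet: float = 0.015  # inlet mean velocity, m/s
    inlet: tuple = _DEFAULT_INLET  # 7 inlet concentrations
    heparin: float = 0.1  # circulating heparin, nmol/m^3
    chi: float = 30.0  # reaction-rate / time scaling factor
    duration: float = 150.0  # simulated seconds (reported time = chi * this)
    flow_overrides: dict = field(default_factory=dict)
    kinetics_overrides: dict = field(default_factory=dict)
    # desk-scale packing calibration: at this resolution a cell at phi = 0.4
    # is already hydrodynamically occluded (drag length ~1 um), and each
    # deposited platelet occupies an effective aggregate volume (trapped
    # plasma) rather than its bare 1.1e-17 m^3
    transport_overrides: dict = field(
        default_factory=lambda: {"phi_crit": 0.4, "V_p": 1.1e-16}
    )
    dt_max: float | None = None
    cfl: float = 0.4
    transport_cfl: float = 0.8  # upwind CFL for the species step
    output_every: float = 1.0  # simulated seconds between recorded rows
    flow_check_every: int = 50  # steps between phi-drift checks
    flow_phi_retol: float = 0.005  # max |dphi| before the flow is re-solved
    outdir: str | None = None
    write_vtk: bool = False
    label: str = "run"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.chi < 1:
            raise ValueError("chi must be >= 1")
        if any(c < 0 for c in self.inlet) or len(self.inlet) != 7:
            raise ValueError("inlet needs 7 non-negative concentrations")
        if self.heparin < 0:
            raise ValueError("heparin must be non-negative")

    # -- assembly ----------------------------------------------------------
    def build_grid(self) -> Grid2D:
        geo = dict(self.geometry)
        preset = geo.pop("preset")
        try:
            builder = _GEOMETRY_BUILDERS[preset]
        except KeyError:
            raise ValueError(f"unknown geometry preset {preset!r}") from None
        return builder(**geo)

    def flow_params(self) -> FlowParams:
        return FlowParams(u_inlet=self.u_inlet, cfl=self.cfl, **self.flow_overrides)

    def kinetics_params(self) -> kin.KineticsParams:
        return kin.KineticsParams(heparin=self.heparin, **self.kinetics_overrides)

    def transport_params(self) -> TransportParams:
        base = TransportParams(**self.transport_overrides)
        return scale_reaction_rates(base, self.chi)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["inlet"] = [float(x) for x in self.inlet]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "inlet" in d:
            d["inlet"] = tuple(float(x) for x in d["inlet"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def scale_reaction_rates(params: TransportParams, chi: float) -> TransportParams:
    """Multiply exactly {k_ra, k_aa, k_rpd_b, k_apd_b} by chi."""
    if chi < 1:
        raise ValueError("chi must be >= 1")
    return replace(
        params,
        k_ra=params.k_ra * chi,
        k_aa=params.k_aa * chi,
        k_rpd_b=params.k_rpd_b * chi,
        k_apd_b=params.k_apd_b * chi,
    )


def make_scenario(kind: str, base: ScenarioConfig):
    """Derive scenario configuration(s) from a baseline.

    heparin_bolus: heparin 0.1 -> 0.3 nmol/m^3 (bolus infusion analogue);
    surface_coating: k_apd_b and tau_sc_b divided by 10 (MPC-like surface);
    flow_sweep: inlet velocities in ratio 2.0 : 4.5 : 6.0 around nominal.
    """
    if kind == "baseline":
        return base
    if kind == "heparin_bolus":
        return replace(base, heparin=0.3, label=base.label + "_heparin")
    if kind == "surface_coating":
        tp = TransportParams(**base.transport_overrides)
        ov = dict(base.transport_overrides)
        ov["k_apd_b"] = tp.k_apd_b / 10.0
        ov["tau_sc_b"] = tp.tau_sc_b / 10.0
        return replace(base, transport_overrides=ov, label=base.label + "_coating")
    if kind == "flow_sweep":
        ratios = {"low": 2.0 / 4.5, "nominal": 1.0, "high": 6.0 / 4.5}
        return [
            replace(base, u_inlet=base.u_inlet * r, label=f"{base.label}_{name}")
            for name, r in ratios.items()
        ]
    raise ValueError(f"unknown scenario kind {kind!r}")


@dataclass
class ResultBundle:
    """Outputs of one run: time series, final fields, ledger diagnostics."""

    config: ScenarioConfig
    series: pd.DataFrame  # per-output-time rows; 'time' is the scaled axis
    grid: Grid2D
    flow: FlowState
    species: SpeciesState
    thrombus: ThrombusState
    outputs: dict = field(default_factory=dict)  # paths of files written

    @property
    def final_deposit(self) -> float:
        """Total deposited platelets (PLT per unit depth) at the end."""
        return float(self.series["deposit_total"].iloc[-1])

    @property
    def max_ledger_residual(self) -> float:
        return float(self.series["ledger_residual"].iloc[-1:].max())


class CheckpointError(RuntimeError):
    """Raised on checkpoint schema mismatch or corruption."""


class Simulation:
    """Coupled flow / transport / deposition time-stepping loop."""

    def __init__(self, config: ScenarioConfig):
        self.config = config
        self.grid = config.build_grid()
        self.fparams = config.flow_params()
        self.kparams = config.kinetics_params()
        self.tparams = config.transport_params()
        self.inlet = np.asarray(config.inlet, dtype=float)
        self.solver = FlowSolver(self.grid, self.fparams)
        self.species = make_species_state(self.grid, self.inlet)
        self.thrombus = update_thrombus(self.species, self.tparams, self.grid)
        self.flow = self.solver.solve_steady(self.thrombus.phi)
        self._phi_ref = self.thrombus.phi.copy()
        self._tau_cell = self._compute_tau()
        self.t = 0.0
        self.step_index = 0
        self._next_output = 0.0
        self.rows: list[dict] = []
        self._ledger = {"inflow": np.zeros(7), "outflow": np.zeros(7)}
        self._initial_inventory = self._platelet_inventory()
        self._record_row()
        self._next_output = config.output_every

    # -- diagnostics -------------------------------------------------------
    def _platelet_inventory(self) -> tuple[float, float]:
        V = self.grid.cell_volume
        fluid = self.grid.fluid_mask
        free = float(self.species.free[:2][:, fluid].sum() * V)
        dep = float(self.species.dep[:, fluid].sum() * V)
        return free, dep

    def _ledger_residual(self) -> float:
        free, dep = self._platelet_inventory()
        f0, d0 = self._initial_inventory
        inflow = float(self._ledger["inflow"][:2].sum())
        outflow = float(self._ledger["outflow"][:2].sum())
        residual = inflow - outflow - (free - f0) - (dep - d0)
        scale = max(abs(inflow), abs(outflow), f0, 1e-300)
        return residual / scale

    def _compute_tau(self) -> np.ndarray:
        """Cell shear stress for cleaning; wall cells take the wall value."""
        tau = cell_shear_stress(self.grid, self.flow, self.fparams.mu_eff)
        from .geometry import wall_faces

        tw = wall_shear_stress(self.grid, self.flow, self.fparams.mu_eff)
        for val, f in zip(tw, wall_faces(self.grid)):
            if val > tau[f.j, f.i]:
                tau[f.j, f.i] = val
        return tau

    def _record_row(self) -> None:
        V = self.grid.cell_volume
        fluid = self.grid.fluid_mask
        dep = self.species.dep
        free, dtot = self._platelet_inventory()
        row = {
            "time": self.config.chi * self.t,
            "sim_time": self.t,
            "step": self.step_index,
            "deposit_total": dtot,
            "deposit_rpd": float(dep[0][fluid].sum() * V),
            "deposit_apd": float(dep[1][fluid].sum() * V),
            "deposit_aps": float(dep[2][fluid].sum() * V),
            "free_platelets": free,
            "phi_max": float(self.thrombus.phi.max()),
            "n_core_cells": int(self.thrombus.core_mask.sum()),
            "ledger_residual": self._ledger_residual(),
        }
        self.rows.append(row)

    # -- stepping ----------------------------------------------------------
    def _reaction_dt_cap(self) -> float:
        kp, f = self.kparams, self.species.free
        omega = kin.activation_omega(f[kin.I_ADP], f[kin.I_TXA2], f[kin.I_T], kp)
        k_act = float(np.max(omega)) / kp.t_act
        k_max = max(k_act, kp.k1_ADP, kp.k1_TxA2, self.tparams.k_stab, 1e-12)
        return 0.25 / k_max

    def step_once(self) -> None:
        cfg = self.config
        # refresh the quasi-steady flow if the thrombus has grown
        if self.step_index % cfg.flow_check_every == 0 and self.step_index > 0:
            if np.abs(self.thrombus.phi - self._phi_ref).max() > cfg.flow_phi_retol:
                self.flow = self.solver.solve_steady(self.thrombus.phi, self.flow)
                self._phi_ref = self.thrombus.phi.copy()
                self._tau_cell = self._compute_tau()

        dt = stable_transport_dt(self.grid, self.flow, self.tparams, cfg.transport_cfl)
        dt = min(dt, self._reaction_dt_cap())
        if cfg.dt_max is not None:
            dt = min(dt, cfg.dt_max)
        dt = min(dt, self._next_output - self.t, cfg.duration - self.t)
        dt = max(dt, 1e-12)

        sources = kin.assemble_sources(
            self.species.free, self.species.dep, self._tau_cell, self.kparams
        )
        self.species = transport_step(
            self.grid,
            self.flow,
            self.species,
            sources,
            self.tparams,
            dt,
            inlet=self.inlet,
            record=self._ledger,
        )
        apply_surface_processes(
            self.grid, self.species, self.thrombus, self._tau_cell, self.tparams, dt
        )
        self.thrombus = update_thrombus(self.species, self.tparams, self.grid)
        self.t += dt
        self.step_index += 1
        if self.t >= self._next_output - 1e-12 or self.t >= cfg.duration - 1e-12:
            self._record_row()
            self._maybe_write_vtk()
            while self._next_output <= self.t + 1e-12:
                self._next_output += cfg.output_every

    def run(self) -> ResultBundle:
        while self.t < self.config.duration - 1e-12:
            self.step_once()
        return self.result()

    # -- outputs -----------------------------------------------------------
    def _maybe_write_vtk(self) -> None:
        cfg = self.config
        if not (cfg.write_vtk and cfg.outdir):
            return
        import os

        os.makedirs(cfg.outdir, exist_ok=True)
        path = os.path.join(cfg.outdir, f"{cfg.label}_{self.step_index:08d}.vtk")
        fields = {"phi": self.thrombus.phi, "pressure": self.flow.p}
        for n, name in enumerate(kin.SPECIES):
            fields[name] = self.species.free[n]
        for n, name in enumerate(kin.DEPOSITED):
            fields[name] = self.species.dep[n]
        write_vtk_cells(path, self.grid, fields)

    def result(self) -> ResultBundle:
        series = pd.DataFrame(self.rows)
        outputs = {}
        cfg = self.config
        if cfg.outdir:
            import os

            os.makedirs(cfg.outdir, exist_ok=True)
            csv_path = os.path.join(cfg.outdir, f"{cfg.label}_series.csv")
            series.to_csv(csv_path, index=False, float_format="%.12e")
            manifest = os.path.join(cfg.outdir, f"{cfg.label}_manifest.json")
            from .analysis import damkohler_report

            D = self.tparams.effective_D()
            payload = {
                "config": cfg.to_dict(),
                "damkohler": damkohler_report(
                    length=self.grid.nx * self.grid.dx,
                    velocity=max(cfg.u_inlet, 1e-12),
                    t_act=self.kparams.t_act,
                    deposition_rates={
                        "k_rpd_b": self.tparams.k_rpd_b,
                        "k_apd_b": self.tparams.k_apd_b,
                        "k_ra": self.tparams.k_ra,
                        "k_aa": self.tparams.k_aa,
                    },
                    diffusivities={
                        "k_rpd_b": D[kin.I_RP],
                        "k_apd_b": D[kin.I_AP],
                        "k_ra": D[kin.I_RP],
                        "k_aa": D[kin.I_AP],
                    },
                ),
            }
            with open(manifest, "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
            outputs = {"series": csv_path, "manifest": manifest}
        return ResultBundle(
            config=cfg,
            series=series,
            grid=self.grid,
            flow=self.flow,
            species=self.species,
            thrombus=self.thrombus,
            outputs=outputs,
        )


def run_simulation(config: ScenarioConfig) -> ResultBundle:
    """Execute one scenario to completion (deterministic)."""
    return Simulation(config).run()


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(sim: Simulation, path: str) -> str:
    """Serialize the full loop state; write-then-read is bit-exact."""
    arrays = {
        "u": sim.flow.u,
        "v": sim.flow.v,
        "p": sim.flow.p,
        "free": sim.species.free,
        "dep": sim.species.dep,
        "phi_ref": sim._phi_ref,
        "tau_cell": sim._tau_cell,
        "inflow": sim._ledger["inflow"],
        "outflow": sim._ledger["outflow"],
    }
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "config": sim.config.to_dict(),
        "t": sim.t,
        "step_index": sim.step_index,
        "next_output": sim._next_output,
        "initial_inventory": list(sim._initial_inventory),
        "rows": sim.rows,
    }
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        zf.writestr("arrays.npz", buf.getvalue())
    return path


def load_checkpoint(path: str) -> Simulation:
    """Restore a Simulation; resuming reproduces the uninterrupted run."""
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            arrays = np.load(io.BytesIO(zf.read("arrays.npz")))
            arrays = {k: arrays[k] for k in arrays.files}
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise CheckpointError(f"unreadable checkpoint {path!r}: {exc}") from exc
    if meta.get("schema") != CHECKPOINT_SCHEMA:
        raise CheckpointError(
            f"checkpoint schema {meta.get('schema')} != {CHECKPOINT_SCHEMA}"
        )
    sim = Simulation.__new__(Simulation)
    sim.config = ScenarioConfig.from_dict(meta["config"])
    sim.grid = sim.config.build_grid()
    sim.fparams = sim.config.flow_params()
    sim.kparams = sim.config.kinetics_params()
    sim.tparams = sim.config.transport_params()
    sim.inlet = np.asarray(sim.config.inlet, dtype=float)
    sim.solver = FlowSolver(sim.grid, sim.fparams)
    sim.flow = FlowState(arrays["u"], arrays["v"], arrays["p"])
    sim.species = SpeciesState(arrays["free"], arrays["dep"])
    sim.thrombus = update_thrombus(sim.species, sim.tparams, sim.grid)
    sim._phi_ref = arrays["phi_ref"]
    sim._tau_cell = arrays["tau_cell"]
    sim.t = float(meta["t"])
    sim.step_index = int(meta["step_index"])
    sim._next_output = float(meta["next_output"])
    sim.rows = list(meta["rows"])
    sim._ledger = {"inflow": arrays["inflow"], "outflow": arrays["outflow"]}
    sim._initial_inventory = tuple(meta["initial_inventory"])
    return sim


def checkpoint_roundtrip(sim: Simulation, path: str) -> Simulation:
    """Save then reload; the restored state is bit-identical."""
    save_checkpoint(sim, path)
    return load_checkpoint(path)
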