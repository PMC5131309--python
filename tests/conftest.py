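"""Shared fixtures.

The heavier scenario runs used by several acceptance criteria are
session-scoped so each is executed once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

from thrombosim.geometry import build_channel
from thrombosim.hemodynamics import FlowParams, solve_steady_flow
from thrombosim.simulation import ScenarioConfig, make_scenario, run_simulation


def scaled_crevice_config(**overrides) -> ScenarioConfig:
    """Baseline crevice scenario used across the acceptance suite."""
    defaults = dict(output_every=5.0, label="baseline")
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


@pytest.fixture(scope="session")
def crevice_baseline():
    """Baseline crevice run (150 simulated s, chi=30)."""
    return run_simulation(scaled_crevice_config())


@pytest.fixture(scope="session")
def crevice_flow_sweep(crevice_baseline):
    """Low/nominal/high flow-rate runs; nominal reuses the baseline."""
    base = crevice_baseline.config
    configs = {c.label: c for c in make_scenario("flow_sweep", base)}
    out = {"nominal": crevice_baseline}
    out["low"] = run_simulation(configs["baseline_low"])
    out["high"] = run_simulation(configs["baseline_high"])
    return out


@pytest.fixture(scope="session")
def crevice_heparin(crevice_baseline):
    """Heparin bolus (0.3 nmol/m^3) run."""
    return run_simulation(make_scenario("heparin_bolus", crevice_baseline.config))


@pytest.fixture(scope="session")
def crevice_heparin_coating(crevice_baseline):
    """Combined heparin bolus + MPC-like coating run."""
    cfg = make_scenario("surface_coating", make_scenario("heparin_bolus", crevice_baseline.config))
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def poiseuille_40():
    """Steady plane channel flow at n_across=40 (phi = 0)."""
    grid = build_channel(4e-3, 1e-3, 40)
    params = FlowParams(u_inlet=0.1)
    flow = solve_steady_flow(grid, np.zeros((grid.ny, grid.nx)), params)
    return grid, params, flow


@pytest.fixture(scope="session")
def washing_channel():
    """High-shear channel run: wall stress above 3x the surface cleaning
    threshold everywhere, to exercise the deposition/erosion equilibrium."""
    cfg = ScenarioConfig(
        geometry={"preset": "channel", "length": 4e-3, "height": 1e-3, "n_across": 8},
        u_inlet=0.025,
        duration=150.0,
        output_every=5.0,
        label="washing",
    )
    return run_simulation(cfg)
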