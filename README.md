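# thrombosim

Desk-scale 2D continuum simulation of platelet deposition and thrombus
growth in blood-wetted flow channels.

Blood is treated as a Newtonian fluid phase plus a static porous thrombus
phase that exerts a drag force `C2 * f(phi) * v` on the flow, with the
hindrance function `f(phi) = phi (1 + 6.5 phi)`. Ten chemical/biological
species are tracked: resting and activated free-stream platelets (RP, AP),
three deposited platelet states (RP_d, AP_d and stabilized AP_s), the
agonists ADP and TxA2, prothrombin, thrombin, and antithrombin III whose
thrombin inhibition is heparin-catalyzed (template kinetics). Mechanisms:
agonist/shear-triggered activation, agonist release/synthesis/inhibition,
platelet-surface and platelet-platelet deposition, thrombus propagation past
a packing threshold, shear cleaning ("washing") with characteristic stresses
for surface and platelet-platelet bonds, stabilization, and two-way
thrombus-flow coupling.

Geometries are generated programmatically (straight channel, backward-facing
step, bearing-like crevice channel). Deposition rate constants are scaled by
a factor chi (default 30) and reported times by the same factor, exploiting
the high Damköhler numbers of the reaction network.

## Layout

| module | contents |
| --- | --- |
| `thrombosim.geometry` | structured Cartesian grids, cell tagging, wall-face enumeration |
| `thrombosim.hemodynamics` | staggered-grid projection solver with implicit porous drag, wall shear stress |
| `thrombosim.kinetics` | 0D activation/agonist/thrombin network, stiff batch integrator |
| `thrombosim.transport_deposition` | species advection-diffusion-reaction, deposition fluxes, cleaning, stabilization, packing |
| `thrombosim.simulation` | scenario configs, chi scaling, coupled driver, checkpointing |
| `thrombosim.analysis` | regional/axial thrombus burden, thickness profiles, Damköhler numbers |

## CLI

```bash
# run the packaged baseline crevice scenario
thrombosim run src/thrombosim/data/example_config.yaml --outdir results/run1

# derived scenarios: flow_sweep | heparin_bolus | surface_coating | baseline
thrombosim scenario heparin_bolus src/thrombosim/data/example_config.yaml --outdir results/hep

# summarize CSV outputs in a results directory
thrombosim postprocess results/run1
```

Each run writes a CSV time series (scaled time, deposited inventories,
packing maximum, conservation-ledger residual), a JSON manifest of the
resolved configuration, and optional legacy-VTK field snapshots.

## Python API

```python
import numpy as np
from thrombosim import ScenarioConfig, make_scenario, run_simulation
from thrombosim.analysis import default_regions, regional_thrombus_percent

result = run_simulation(ScenarioConfig(duration=60.0))
regions = default_regions(result.grid)
pct = regional_thrombus_percent(result.thrombus.phi, regions["crevice"],
                                phi_max=0.8, cell_volume=result.grid.cell_volume)
print(result.series.tail(), pct)
```

## Units

SI internally: concentrations as configured at the inlet (platelets PLT/m^3,
agonists nmol/m^3, thrombin U/m^3), stresses in Pa (1 dyne/cm^2 = 0.1 Pa),
unit out-of-plane depth for all areas and volumes.
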