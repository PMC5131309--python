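"""Post-processing metrics: regional thrombus burden, axial distribution,
wall-normal thickness, and Damköhler diagnostics.

All metrics are pure functions of their input fields. "Occupied" volume is
interpreted as the volume-weighted ratio phi/phi_max for percent metrics and
as a thresholded indicator (default 0.5 * phi_max) for thickness.
"""

from __future__ import annotations

import numpy as np

from .geometry import Grid2D

__all__ = [
    "RegionMask",
    "regional_thrombus_percent",
    "axial_thrombus_distribution",
    "thrombus_thickness_profile",
    "damkohler_number",
    "damkohler_report",
    "default_regions",
    "plot_deposit_series",
    "plot_axial_distribution",
]


class RegionMask(dict):
    """Named per-cell boolean masks; masks must cover only FLUID cells."""

    @classmethod
    def from_grid(cls, grid: Grid2D, **masks: np.ndarray) -> "RegionMask":
        out = cls()
        for name, m in masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != (grid.ny, grid.nx):
                raise ValueError(f"mask {name!r} has wrong shape")
            out[name] = m & grid.fluid_mask
        return out


def default_regions(grid: Grid2D) -> RegionMask:
    """Preset-specific surrogate regions (documented per geometry preset)."""
    fluid = grid.fluid_mask
    preset = grid.meta.get("preset")
    masks = {"all": fluid}
    if preset == "crevice_channel":
        n_cd = grid.meta["n_cd"]
        cavity = np.zeros_like(fluid)
        cavity[:n_cd, :] = True
        near = np.zeros_like(fluid)
        near[n_cd : n_cd + 2, :] = True
        masks.update(crevice=cavity & fluid, near_wall=near & fluid)
        masks["channel_core"] = fluid & ~masks["crevice"] & ~masks["near_wall"]
    elif preset == "backward_facing_step":
        n_step = grid.meta["n_step"]
        n_block = grid.meta["n_block"]
        rec = np.zeros_like(fluid)
        rec[:n_block, n_step:] = True
        masks.update(recirculation=rec & fluid, channel=fluid & ~rec)
    return RegionMask(masks)


def regional_thrombus_percent(
    phi: np.ndarray, mask: np.ndarray, phi_max: float, cell_volume: float = 1.0
) -> float:
    """Percent of a region's fluid volume occupied by thrombus.

    100 * sum(phi * V) / (phi_max * sum(V)) over the masked cells.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    vol = mask.sum() * cell_volume
    return float(100.0 * (phi[mask] * cell_volume).sum() / (phi_max * vol))


def axial_thrombus_distribution(
    phi: np.ndarray, grid: Grid2D, phi_max: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-x-station occupied percent over the FLUID cells of each column.

    Returns (x_centers, percent); columns without fluid cells give NaN.
    """
    fluid = grid.fluid_mask
    num = np.where(fluid, phi, 0.0).sum(axis=0)
    den = phi_max * fluid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(den > 0, 100.0 * num / den, np.nan)
    return grid.x_centers(), pct


def thrombus_thickness_profile(
    phi: np.ndarray,
    grid: Grid2D,
    wall: str = "bottom",
    threshold_fraction: float = 0.5,
    phi_max: float = 0.8,
) -> np.ndarray:
    """Thrombus thickness (m) per axial station, measured from a wall.

    Counts the contiguous run of cells with phi >= threshold_fraction*phi_max
    starting at the named wall ("bottom" or "top") in each column.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold fraction must lie in (0, 1]")
    above = (phi >= threshold_fraction * phi_max) & grid.fluid_mask
    if wall == "top":
        above = above[::-1, :]
    elif wall != "bottom":
        raise ValueError("wall must be 'bottom' or 'top'")
    # first column-wise False stops the contiguous run from the wall
    run = np.cumprod(above, axis=0).sum(axis=0)
    return run * grid.dy


def damkohler_number(
    rate_constant: float,
    length: float,
    velocity: float = 1.0,
    diffusivity: float = 1.0,
    kind: str = "bulk",
) -> float:
    """Reaction/transport rate ratio.

    bulk: Da = k * L / U (k in 1/s); surface: Da = k_s * L / D (k_s in m/s).
    """
    if min(rate_constant, length) <= 0:
        raise ValueError("rate constant and length must be positive")
    if kind == "bulk":
        if velocity <= 0:
            raise ValueError("velocity must be positive")
        return rate_constant * length / velocity
    if kind == "surface":
        if diffusivity <= 0:
            raise ValueError("diffusivity must be positive")
        return rate_constant * length / diffusivity
    raise ValueError("kind must be 'bulk' or 'surface'")


def damkohler_report(
    length: float,
    velocity: float,
    t_act: float,
    deposition_rates: dict,
    diffusivities: dict,
) -> dict:
    """Per-process Damköhler numbers for a scenario (goes in the manifest).

    Bulk Da uses the activation rate 1/t_act; surface Da uses each (chi-scaled)
    deposition constant against the matching species diffusivity.
    """
    report = {"activation_bulk": damkohler_number(1.0 / t_act, length, velocity=velocity)}
    for name, k_s in deposition_rates.items():
        D = diffusivities[name]
        report[f"{name}_surface"] = damkohler_number(k_s, length, diffusivity=D, kind="surface")
    return report


def plot_deposit_series(series, path: str):
    """Time-series plot of deposited inventories (scaled time axis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for col in ("deposit_total", "deposit_rpd", "deposit_apd", "deposit_aps"):
        ax.plot(series["time"], series[col], label=col)
    ax.set_xlabel("time (s, scaled)")
    ax.set_ylabel("deposited platelets (PLT per unit depth)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_axial_distribution(phi, grid: Grid2D, phi_max: float, path: str):
    """Axial occupied-percent profile as an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, pct = axial_thrombus_distribution(phi, grid, phi_max)
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(x * 1e3, pct)
    ax.set_xlabel("axial position (mm)")
    ax.set_ylabel("thrombus volume (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
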