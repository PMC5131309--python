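"""Pointwise platelet/agonist reaction network.

Seven free-stream species (RP, AP, ADP, TxA2, PT, T, AT) plus three deposited
platelet states (RP_d, AP_d, AP_s). Functional forms follow the classical
agonist-weighted activation model: resting platelets convert to activated ones
when the weighted agonist sum crosses unity (characteristic time ``t_act``),
agonists are released/synthesized per activated platelet and inhibited by
first-order decay, thrombin is generated on platelet membranes from a finite
prothrombin pool, and thrombin inactivation by antithrombin III is
heparin-catalyzed with a template (dual-saturation) rate law.

Every constant is exposed in :class:`KineticsParams`; default values are
calibration choices for the desk-scale scenarios, with concentration units as
configured at the inlet (platelets PLT/m^3, agonists nmol/m^3, thrombin U/m^3).

All rate functions broadcast over numpy arrays so the transport solver can
evaluate them per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SPECIES",
    "DEPOSITED",
    "I_RP",
    "I_AP",
    "I_ADP",
    "I_TXA2",
    "I_PT",
    "I_T",
    "I_AT",
    "KineticsParams",
    "BatchState",
    "activation_omega",
    "activation_rate_constant",
    "platelet_activation_rate",
    "agonist_sources",
    "thrombin_sources",
    "griffith_inhibition_rate",
    "assemble_sources",
    "integrate_batch",
]

SPECIES = ("RP", "AP", "ADP", "TxA2", "PT", "T", "AT")
DEPOSITED = ("RPd", "APd", "APs")
I_RP, I_AP, I_ADP, I_TXA2, I_PT, I_T, I_AT = range(7)

# typical magnitudes per species, used to scale absolute integrator tolerances
_TYPICAL = np.array([3.0e14, 3.0e12, 1.0e5, 1.0e4, 1.1e-6, 1.0, 2.844e-6])


class IntegrationError(RuntimeError):
    """Batch integration failure; carries .last_state and .last_time."""


@dataclass(frozen=True)
class KineticsParams:
    """Rate constants of the activation / agonist / thrombin network."""

    t_act: float = 1.0  # activation time constant once the threshold is crossed, s
    crit_ADP: float = 2.0e6  # critical ADP concentration, nmol/m^3 (~2 uM)
    crit_TxA2: float = 6.0e5  # critical TxA2 concentration, nmol/m^3
    crit_T: float = 18.0  # critical thrombin concentration, U/m^3
    lambda_ADP: float = 2.4e-8  # ADP released per newly activated platelet, nmol/PLT
    beta_TxA2: float = 9.5e-12  # TxA2 synthesis per activated platelet, nmol/PLT/s
    k1_ADP: float = 0.01  # first-order ADP inhibition, 1/s
    k1_TxA2: float = 0.0161  # first-order TxA2 inhibition, 1/s
    phi_AT: float = 3.1e-13  # thrombin generation per activated platelet, U/PLT/s
    phi_RT: float = 3.1e-14  # thrombin generation per resting platelet, U/PLT/s
    K_PT: float = 5.0e-8  # prothrombin half-saturation for generation gating
    beta_PT: float = 1.0e-10  # prothrombin consumed per unit thrombin, nmol/U
    k_shear: float = 0.0  # shear-activation coefficient, 1/(s Pa^alpha); off
    alpha_shear: float = 1.0
    # Template-model constants for heparin-catalyzed AT-III inhibition.
    # Chosen so K_AT*[T] stays far below K_T*[AT] over the operating range:
    # the rate is then first-order in thrombin with effective constant
    # k_cat*heparin/K_T, and a heparin bolus scales the sink linearly.
    k_cat: float = 250.0  # 1/(s * heparin-unit)
    K_T: float = 100.0  # thrombin saturation constant, U/m^3
    K_AT: float = 1.0e-9  # antithrombin saturation constant, nmol/m^3
    k_uncat: float = 0.0  # uncatalyzed AT-III inhibition, optional, 1/s scale
    heparin: float = 0.1  # circulating heparin, nmol/m^3 (baseline)
    deposited_activate: bool = True  # RP_d activates at the free-RP rate
    # width of the C1 smoothing band just below the Omega = 1 threshold;
    # exact zero below 1 - omega_smooth, exact Omega/t_act at and above 1.
    # A sharp switch makes the ODE system non-integrable by adaptive solvers
    # when a trajectory grazes the threshold.
    omega_smooth: float = 1e-3

    def __post_init__(self) -> None:
        rates = (
            self.t_act,
            self.crit_ADP,
            self.crit_TxA2,
            self.crit_T,
            self.k_cat,
            self.K_T,
            self.K_AT,
        )
        if any(r <= 0 for r in rates):
            raise ValueError("rate and critical-concentration constants must be > 0")
        if self.heparin < 0:
            raise ValueError("heparin must be non-negative")


@dataclass
class BatchState:
    """0D state: free-stream concentrations, optional deposits, shear, time."""

    free: np.ndarray  # shape (7,)
    dep: np.ndarray = field(default_factory=lambda: np.zeros(3))
    tau: float = 0.0  # local shear stress, Pa
    t: float = 0.0

    def __post_init__(self) -> None:
        self.free = np.asarray(self.free, dtype=float)
        self.dep = np.asarray(self.dep, dtype=float)
        if self.free.shape != (7,) or self.dep.shape != (3,):
            raise ValueError("BatchState needs 7 free and 3 deposited species")
        if np.any(self.free < 0) or np.any(self.dep < 0):
            raise ValueError("concentrations must be non-negative")


def activation_omega(adp, txa2, t, params: KineticsParams):
    """Weighted agonist sum: unity marks the activation threshold."""
    return (
        np.asarray(adp) / params.crit_ADP
        + np.asarray(txa2) / params.crit_TxA2
        + np.asarray(t) / params.crit_T
    )


def activation_rate_constant(omega, tau, params: KineticsParams):
    """First-order RP->AP rate constant (1/s): thresholded agonists + shear.

    The threshold at Omega = 1 is C1-smoothed over a narrow band
    [1 - omega_smooth, 1]: exactly 0 below the band, exactly Omega/t_act at
    and above 1.
    """
    omega = np.asarray(omega, dtype=float)
    d = params.omega_smooth
    x = np.clip((omega - (1.0 - d)) / d, 0.0, 1.0)
    gate = x * x * (3.0 - 2.0 * x)
    k_ag = gate * omega / params.t_act
    k_sh = params.k_shear * np.asarray(tau, dtype=float) ** params.alpha_shear
    return k_ag + k_sh


def platelet_activation_rate(rp, adp, txa2, t, tau, params: KineticsParams):
    """RP->AP conversion rate (PLT/m^3/s); RP loss equals AP gain."""
    omega = activation_omega(adp, txa2, t, params)
    return np.asarray(rp) * activation_rate_constant(omega, tau, params)


def agonist_sources(adp, txa2, ap, total_activation_rate, params: KineticsParams):
    """(S_ADP, S_TxA2): release/synthesis minus first-order inhibition."""
    s_adp = params.lambda_ADP * np.asarray(total_activation_rate) - params.k1_ADP * np.asarray(adp)
    s_txa2 = params.beta_TxA2 * np.asarray(ap) - params.k1_TxA2 * np.asarray(txa2)
    return s_adp, s_txa2


def thrombin_generation_rate(rp_like, ap_like, pt, params: KineticsParams):
    """Thrombin generation (U/m^3/s) gated by the available prothrombin."""
    pt = np.asarray(pt, dtype=float)
    gate = np.where(pt > 0, pt / (pt + params.K_PT), 0.0)
    return (params.phi_AT * np.asarray(ap_like) + params.phi_RT * np.asarray(rp_like)) * gate


def thrombin_sources(rp_like, ap_like, pt, params: KineticsParams):
    """(S_T_generation, S_PT): thrombin produced, prothrombin consumed."""
    gen = thrombin_generation_rate(rp_like, ap_like, pt, params)
    return gen, -params.beta_PT * gen


def griffith_inhibition_rate(t, at, heparin, params: KineticsParams):
    """Template-model thrombin inactivation rate (U/m^3/s).

    rate = k_cat * heparin * [T][AT] / (K_T K_AT + K_T [AT] + K_AT [T]),
    plus an optional uncatalyzed first-order term (default 0). T and AT are
    consumed 1:1 (molar, via the configured U<->nmol conversion).
    """
    t = np.asarray(t, dtype=float)
    at = np.asarray(at, dtype=float)
    denom = params.K_T * params.K_AT + params.K_T * at + params.K_AT * t
    rate = params.k_cat * heparin * t * at / denom
    if params.k_uncat:
        rate = rate + params.k_uncat * t
    return rate


def assemble_sources(
    free: np.ndarray,
    dep: np.ndarray | None,
    tau,
    params: KineticsParams,
):
    """Source vector for the 7 free species (and 3 deposited, if given).

    ``free`` has shape (7, ...) and ``dep`` (3, ...); sources broadcast over
    trailing axes. Platelet number is conserved across RP<->AP conversion:
    only deposition/cleaning (handled by the transport module) moves platelets
    between the free and deposited pools.
    """
    free = np.asarray(free, dtype=float)
    rp, ap, adp, txa2, pt, t, at = free
    if dep is None:
        dep = np.zeros((3,) + rp.shape) if rp.ndim else np.zeros(3)
    dep = np.asarray(dep, dtype=float)
    rpd, apd, aps = dep

    omega = activation_omega(adp, txa2, t, params)
    k_act = activation_rate_constant(omega, tau, params)
    r_act = rp * k_act
    r_act_dep = rpd * k_act if params.deposited_activate else np.zeros_like(rpd)

    s_adp, s_txa2 = agonist_sources(adp, txa2, ap + apd, r_act + r_act_dep, params)
    gen_t, s_pt = thrombin_sources(rp + rpd, ap + apd, pt, params)
    inh = griffith_inhibition_rate(t, at, params.heparin, params)

    s_free = np.empty_like(free)
    s_free[I_RP] = -r_act
    s_free[I_AP] = r_act
    s_free[I_ADP] = s_adp
    s_free[I_TXA2] = s_txa2
    s_free[I_PT] = s_pt
    s_free[I_T] = gen_t - inh
    s_free[I_AT] = -params.beta_PT * inh
    s_dep = np.empty_like(dep)
    s_dep[0] = -r_act_dep
    s_dep[1] = r_act_dep
    s_dep[2] = np.zeros_like(aps)
    return s_free, s_dep


def integrate_batch(
    c0: BatchState,
    t_end: float,
    params: KineticsParams,
    n_out: int = 101,
    rtol: float = 1e-10,
    method: str = "LSODA",
):
    """Integrate the closed (0D) network to ``t_end``.

    Returns ``(times, free_traj, dep_traj)`` with shapes (n,), (n, 7), (n, 3).
    Concentrations are clipped at zero only to absorb integrator roundoff.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    y0 = np.concatenate([c0.free, c0.dep])
    scale = np.concatenate([np.maximum(np.abs(c0.free), _TYPICAL), np.maximum(np.abs(c0.dep), 1.0)])

    def rhs(_t, y):
        s_free, s_dep = assemble_sources(y[:7], y[7:], c0.tau, params)
        return np.concatenate([s_free, s_dep])

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method=method,
        rtol=rtol,
        atol=1e-13 * scale,
        t_eval=np.linspace(0.0, t_end, n_out),
    )
    if not sol.success:
        err = IntegrationError(f"batch integration failed: {sol.message}")
        err.last_state = sol.y[:, -1] if sol.y.size else y0
        err.last_time = sol.t[-1] if sol.t.size else 0.0
        raise err
    y = sol.y.T
    tiny = 1e-12 * scale
    y = np.where((y < 0) & (y > -tiny), 0.0, y)
    return sol.t, y[:, :7], y[:, 7:]
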