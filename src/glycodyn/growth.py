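"""Modified-Monod cell-culture dynamics.

Viable-cell, substrate and product balances for a (fed-)batch mammalian
cell culture.  Growth is a double Monod function of extracellular glucose
and glutamine; death is an inverse-Monod function of the same substrates;
specific productivity is growth-independent.  A dead-cell pool
``dX_dead/dt = k_d * X_V`` (no lysis) is tracked so that measured dead-cell
densities have a model counterpart.

All balances are written on the volume-scaled quantities (V*X_V, V*[Glc],
...) so that fed-batch dilution falls out naturally; in batch mode
(F_in = F_out = 0) the volume is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict


@dataclass
class GrowthParameters:
    """Kinetic constants of the culture model.

    Units: rates 1/h, saturation constants mM, yields cell/mmol,
    maintenance mmol/(h cell), q_mAb mmol/(h cell).
    """

    mu_max: float
    K_M_glc: float
    K_M_gln: float
    k_d_max_glc: float
    k_d_max_gln: float
    K_d_glc: float
    K_d_gln: float
    Y_Xv_glc: float
    Y_Xv_gln: float
    m_glc: float
    m_gln: float
    Y_mAb_Xv: float

    def __post_init__(self) -> None:
        strict = ("mu_max", "K_M_glc", "K_M_gln", "k_d_max_glc",
                  "k_d_max_gln", "K_d_glc", "K_d_gln", "Y_Xv_glc", "Y_Xv_gln")
        for name in strict:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("m_glc", "m_gln", "Y_mAb_Xv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CultureState:
    """Culture environment at one instant."""

    V: float  # L
    X_V: float  # viable cells/L
    X_dead: float  # dead cells/L
    Glc_ext: float  # mM
    Gln_ext: float  # mM
    mAb: float  # mM
    t: float = 0.0  # h

    def __post_init__(self) -> None:
        for name in ("V", "X_V", "X_dead", "Glc_ext", "Gln_ext", "mAb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class FeedSchedule:
    """Piecewise-constant inlet/outlet flows; batch mode by default."""

    F_in: Callable[[float], float] = field(default=lambda t: 0.0)
    F_out: Callable[[float], float] = field(default=lambda t: 0.0)
    Glc_feed: float = 0.0
    Gln_feed: float = 0.0

    @staticmethod
    def batch() -> "FeedSchedule":
        return FeedSchedule()


def growth_rate(state: CultureState, p: GrowthParameters) -> float:
    """Specific growth rate mu, 1/h (double Monod in Glc and Gln)."""
    if state.Glc_ext < 0 or state.Gln_ext < 0:
        raise ValueError("substrate concentrations must be >= 0")
    return (
        p.mu_max
        * state.Glc_ext / (p.K_M_glc + state.Glc_ext)
        * state.Gln_ext / (p.K_M_gln + state.Gln_ext)
    )


def death_rate(state: CultureState, p: GrowthParameters) -> float:
    """Specific death rate k_d, 1/h (inverse Monod, additive in Glc/Gln)."""
    if state.Glc_ext < 0 or state.Gln_ext < 0:
        raise ValueError("substrate concentrations must be >= 0")
    return (
        p.k_d_max_glc * p.K_d_glc / (p.K_d_glc + state.Glc_ext)
        + p.k_d_max_gln * p.K_d_gln / (p.K_d_gln + state.Gln_ext)
    )


def uptake_rates(mu: float, p: GrowthParameters) -> Dict[str, float]:
    """Specific consumption/production rates, mmol/(h cell)."""
    return {
        "q_glc": mu / p.Y_Xv_glc + p.m_glc,
        "q_gln": mu / p.Y_Xv_gln + p.m_gln,
        "q_mAb": p.Y_mAb_Xv,
    }


def substrate_availability(state: CultureState, eps: float = 1e-6):
    """Smooth depletion guards g(S) = S/(S+eps) for glucose and glutamine."""
    return (state.Glc_ext / (state.Glc_ext + eps),
            state.Gln_ext / (state.Gln_ext + eps))


def culture_rhs(
    state: CultureState,
    p: GrowthParameters,
    feed: FeedSchedule | None = None,
) -> Dict[str, float]:
    """Time derivatives of the volume-scaled culture balances.

    Returns d/dt of ``V*X_V``, ``V*X_dead``, ``V*Glc_ext``, ``V*Gln_ext``,
    ``V*mAb`` and ``V``.  The feed terms enter as sources
    ``+F_in*[feed]``; the outflow removes each species at its culture
    concentration.
    """
    feed = feed or FeedSchedule.batch()
    f_in = feed.F_in(state.t)
    f_out = feed.F_out(state.t)
    if f_in < 0 or f_out < 0:
        raise ValueError("feed flows must be >= 0")

    mu = growth_rate(state, p)
    kd = death_rate(state, p)
    q = uptake_rates(mu, p)
    vx = state.V * state.X_V
    # smooth positivity guard: uptake shuts off as a substrate is
    # exhausted (half-saturation 1 nM, unmeasurable above depletion)
    g_glc, g_gln = substrate_availability(state)
    return {
        "VXv": mu * vx - kd * vx - f_out * state.X_V,
        "VXd": kd * vx - f_out * state.X_dead,
        "VGlc": -q["q_glc"] * vx * g_glc + f_in * feed.Glc_feed
                - f_out * state.Glc_ext,
        "VGln": -q["q_gln"] * vx * g_gln + f_in * feed.Gln_feed
                - f_out * state.Gln_ext,
        "VmAb": q["q_mAb"] * vx - f_out * state.mAb,
        "V": f_in - f_out,
    }
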