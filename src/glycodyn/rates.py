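"""Enzyme mechanism rate laws for the NSD synthesis network.

All laws are saturation kinetics derived under rapid-equilibrium /
steady-state assumptions with irreversible rate-limiting steps.  Five
mechanism classes are supported:

==================  ============================================================
mechanism           rate law (uninhibited)
==================  ============================================================
``uni_uni``         v = kcat*E0 * A / (Km_A + A)
``random_bibi``     v = kcat*E0 * A*B / (Km_A*Km_B + Km_A*B + Km_B*A + A*B)
``ordered_bibi``    v = kcat*E0 * A*B / (Km_A*Km_B + Km_B*A + A*B)
``pingpong_bibi``   v = kcat*E0 * A*B / (Km_A*B + Km_B*A + A*B)
``pingpong_terter`` v = kcat*E0 * A*B^2 /
                        (2*Km_A*Km_B*B + 2*Km_B*A*B + Km_A*B^2*(1 + I/K_I)
                         + Km_B^2*A + A*B^2)
==================  ============================================================

The ter-ter mechanism consumes one molecule of A and two of B (the single
instance in the default network is UDP-glucose dehydrogenase, which
oxidises UDP-Glc with two NAD+); its printed denominator carries the
inhibitory factor on the ``Km_A*B^2`` term.

Modifier algebra (textbook forms, applied per term):

* competitive inhibition scales the Km of the target substrate by
  ``(1 + sum_i I_i/K_i)``;
* non-competitive inhibition divides the whole rate by
  ``(1 + sum_i I_i/K_i)``;
* un-competitive inhibition scales the fully-substrate-bound denominator
  term (``A`` for uni-uni, ``A*B`` for the bi-bi forms) by the same factor;
* allosteric activation replaces ``E0`` by
  ``E0 * A_act / (K_A + A_act)``;
* cooperative (Hill) binding of a substrate replaces ``[A]/(K + [A])``
  saturation by ``[A]^n / (K^n + [A]^n)``, implemented by raising that
  substrate's concentration and Km to the n-th power wherever they appear.

All functions are elementwise and accept numpy arrays; concentrations are
mM, rates mM/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

MECHANISMS = (
    "uni_uni",
    "random_bibi",
    "ordered_bibi",
    "pingpong_bibi",
    "pingpong_terter",
)

#: mechanism -> number of distinct substrate species
MECHANISM_ARITY = {
    "uni_uni": 1,
    "random_bibi": 2,
    "ordered_bibi": 2,
    "pingpong_bibi": 2,
    "pingpong_terter": 2,  # stoichiometry A + 2 B
}

INHIBITION_TYPES = ("competitive", "non_competitive", "un_competitive")


def v_uni_uni(vmax, a, km_a, beta=1.0):
    return vmax * a / (km_a + a * beta)


def v_random_bibi(vmax, a, b, km_a, km_b, beta=1.0):
    return vmax * a * b / (km_a * km_b + km_a * b + km_b * a + a * b * beta)


def v_ordered_bibi(vmax, a, b, km_a, km_b, beta=1.0):
    return vmax * a * b / (km_a * km_b + km_b * a + a * b * beta)


def v_pingpong_bibi(vmax, a, b, km_a, km_b, beta=1.0):
    # no constant denominator term: both substrates at zero is a 0/0
    # limit whose value is 0
    num = vmax * a * b
    denom = km_a * b + km_b * a + a * b * beta
    return np.divide(num, denom, out=np.zeros_like(np.asarray(num, dtype=float)),
                     where=np.asarray(denom) > 0)


def v_pingpong_terter(vmax, a, b, km_a, km_b, beta=1.0):
    """Ping-pong ter-ter rate with stoichiometry A + 2B.

    ``beta`` is the un-competitive factor ``(1 + I/K_I)`` sitting on the
    ``Km_A*B^2`` denominator term, as in the printed rate law.
    """
    b2 = b * b
    denom = (
        2.0 * km_a * km_b * b
        + 2.0 * km_b * a * b
        + km_a * b2 * beta
        + km_b * km_b * a
        + a * b2
    )
    num = vmax * a * b2
    return np.divide(num, denom, out=np.zeros_like(np.asarray(num, dtype=float)),
                     where=np.asarray(denom) > 0)


_LAWS = {
    "uni_uni": v_uni_uni,
    "random_bibi": v_random_bibi,
    "ordered_bibi": v_ordered_bibi,
    "pingpong_bibi": v_pingpong_bibi,
    "pingpong_terter": v_pingpong_terter,
}


def activation_factor(activator_conc, k_a):
    """Eq-20 style allosteric activation: saturation factor of the activator."""
    return activator_conc / (k_a + activator_conc)


@dataclass
class EnzymeKinetics:
    """Kinetic constants of one enzymatic reaction.

    Parameters
    ----------
    reaction_id : str
    k_cat : float
        Turnover rate, 1/h.
    E_0 : float
        Enzyme concentration, mM (held constant over the culture).
    K_m : mapping substrate id -> mM
    hill_n : float
        Cooperativity exponent applied to ``hill_species`` (>= 1).
    hill_species : substrate id carrying the Hill exponent, or None.
    """

    reaction_id: str
    k_cat: float
    E_0: float
    K_m: Mapping[str, float]
    hill_n: float = 1.0
    hill_species: Optional[str] = None

    def __post_init__(self) -> None:
        if self.k_cat <= 0 or self.E_0 < 0:
            raise ValueError(
                f"{self.reaction_id}: k_cat must be > 0 and E_0 >= 0"
            )
        for s, km in self.K_m.items():
            if km <= 0:
                raise ValueError(f"{self.reaction_id}: K_m[{s}] must be > 0")
        if self.hill_n < 1:
            raise ValueError(f"{self.reaction_id}: hill_n must be >= 1")


@dataclass
class InhibitionSpec:
    """One inhibitory term acting on a reaction."""

    type: str
    inhibitor: str
    K_i: float
    target_substrate: Optional[str] = None  # required for competitive

    def __post_init__(self) -> None:
        if self.type not in INHIBITION_TYPES:
            raise ValueError(f"unknown inhibition type {self.type!r}")
        if self.K_i <= 0:
            raise ValueError("K_i must be > 0")
        if self.type == "competitive" and self.target_substrate is None:
            raise ValueError("competitive inhibition needs a target substrate")


def enzymatic_rate(
    mechanism: str,
    kin: EnzymeKinetics,
    substrates: Sequence[str],
    concentrations: Mapping[str, float],
    inhibitions: Sequence[InhibitionSpec] = (),
    inhibitor_concentrations: Optional[Mapping[str, float]] = None,
    activator_concentration: Optional[float] = None,
    K_A: Optional[float] = None,
) -> float:
    """Rate of a single enzymatic reaction, mM/h.

    ``substrates`` is the ordered substrate list of the reaction (one id
    for uni-uni, two for the bi-bi and ter-ter forms).  Concentrations of
    all substrates must be present in ``concentrations`` and be
    non-negative.
    """
    if mechanism not in _LAWS:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    arity = MECHANISM_ARITY[mechanism]
    if len(substrates) != arity:
        raise ValueError(
            f"{kin.reaction_id}: mechanism {mechanism} expects {arity} "
            f"substrate(s), got {len(substrates)}"
        )
    conc = []
    for s in substrates:
        if s not in concentrations:
            raise KeyError(
                f"{kin.reaction_id}: missing concentration for species {s!r}"
            )
        c = concentrations[s]
        if c < 0:
            raise ValueError(
                f"{kin.reaction_id}: negative concentration for {s!r}"
            )
        conc.append(float(c))
    km = []
    for s in substrates:
        if s not in kin.K_m:
            raise KeyError(f"{kin.reaction_id}: missing K_m for species {s!r}")
        km.append(float(kin.K_m[s]))

    inhibitor_concentrations = inhibitor_concentrations or {}

    # accumulate modifier factors
    alpha = [1.0] * arity  # competitive, per substrate slot
    beta = 1.0  # un-competitive, on the fully-bound term
    gamma = 1.0  # non-competitive, on the whole rate
    for term in inhibitions:
        i_conc = inhibitor_concentrations.get(term.inhibitor)
        if i_conc is None:
            raise KeyError(
                f"{kin.reaction_id}: missing concentration for inhibitor "
                f"{term.inhibitor!r}"
            )
        if i_conc < 0:
            raise ValueError(
                f"{kin.reaction_id}: negative inhibitor concentration "
                f"{term.inhibitor!r}"
            )
        x = i_conc / term.K_i
        if term.type == "competitive":
            if term.target_substrate not in substrates:
                raise ValueError(
                    f"{kin.reaction_id}: competitive target "
                    f"{term.target_substrate!r} is not a substrate"
                )
            alpha[substrates.index(term.target_substrate)] += x
        elif term.type == "non_competitive":
            gamma += x
        else:  # un_competitive
            beta += x

    # Hill exponent: raise the cooperative substrate and its Km to power n
    if kin.hill_species is not None and kin.hill_n != 1.0:
        if kin.hill_species in substrates:
            i = substrates.index(kin.hill_species)
            conc[i] = conc[i] ** kin.hill_n
            km[i] = km[i] ** kin.hill_n

    km_eff = [k * a for k, a in zip(km, alpha)]
    vmax = kin.k_cat * kin.E_0
    if activator_concentration is not None:
        if K_A is None or K_A <= 0:
            raise ValueError(f"{kin.reaction_id}: activation requires K_A > 0")
        if activator_concentration < 0:
            raise ValueError(
                f"{kin.reaction_id}: negative activator concentration"
            )
        vmax = vmax * activation_factor(activator_concentration, K_A)

    law = _LAWS[mechanism]
    if arity == 1:
        v = law(vmax, conc[0], km_eff[0], beta)
    else:
        v = law(vmax, conc[0], conc[1], km_eff[0], km_eff[1], beta)
    return float(v) / gamma


def glycolysis_outlet_rate(fru6p: float, vmax: float, km: float, hill_n: float = 1.0):
    """Irreversible Hill-type outlet from Fru6P towards glycolysis.

    This lumps the phosphofructokinase step (Fru6P -> Fru-1,6-bisP), the
    main sink of hexose flux; its enzyme level ``E_glyc`` enters through
    ``vmax = k_cat * E_glyc``.
    """
    if np.any(np.asarray(fru6p) < 0):
        raise ValueError("negative Fru6P concentration")
    f = np.power(fru6p, hill_n)
    k = km**hill_n
    return vmax * f / (k + f)
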