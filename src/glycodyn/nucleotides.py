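"""Reduced nucleotide synthesis/interconversion network.

Six intracellular pools (ADP, AMP, ATP, CTP, GTP, UTP) are connected by
eight Monod-form reactions.  Glucose is the carbon source and glutamine
the nitrogen source for de-novo synthesis, both entering through their
*extracellular* concentrations.  Four growth-coupled outlets (AMP, CTP,
GTP, UTP) drain the pools into DNA and RNA synthesis; additional drains
towards NSD synthesis (UTP -> UDP-sugars, GTP -> GDP-sugars,
CTP -> CMP-Neu5Ac) are supplied by the NSD layer.

Rate-law classes
----------------
``nuc``         r = k * [Nuc]/(K_M_nuc + [Nuc])
``nuc_gln``     r = k * [Nuc]/(K_M_nuc + [Nuc]) * [Gln]/(K_M_gln + [Gln])
``nuc_glc``     r = k * [Nuc]/(K_M_nuc + [Nuc]) * [Glc]/(K_M_glc + [Glc])
``glc_gln``     r = k * [Glc]/(K_M_glc + [Glc]) * [Gln]/(K_M_gln + [Gln])

``k`` is a lumped maximal volumetric rate (mM/h).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

NUCLEOTIDES = ("ADP", "AMP", "ATP", "CTP", "GTP", "UTP")
OUTLET_NUCLEOTIDES = ("AMP", "CTP", "GTP", "UTP")

RATE_CLASSES = ("nuc", "nuc_gln", "nuc_glc", "glc_gln")

#: printed-equation aliases for the four rate-law classes
CLASS_ALIASES = {
    "Eq10": "nuc",
    "Eq11": "nuc_gln",
    "Eq12": "nuc_glc",
    "Eq13": "glc_gln",
}

PG_PER_MG = 1.0e-9


@dataclass
class NucleotideReactionParams:
    """Lumped kinetic constants of one nucleotide reaction."""

    k: float  # mM/h
    K_M_nuc: float = 1.0  # mM
    K_M_glc: float = 1.0  # mM
    K_M_gln: float = 0.3  # mM

    def __post_init__(self) -> None:
        for name in ("k", "K_M_nuc", "K_M_glc", "K_M_gln"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class NucleotideReaction:
    """One edge of the reduced network.

    ``factor_nuc`` is the nucleotide whose saturation enters the rate law
    (``None`` for the purely substrate-driven ``glc_gln`` class);
    ``consumes`` is the pool drained by the reaction (``None`` for de-novo
    synthesis); ``produces`` is the pool fed.
    """

    id: str
    rate_class: str
    produces: str
    consumes: Optional[str] = None
    factor_nuc: Optional[str] = None
    params: NucleotideReactionParams = field(
        default_factory=lambda: NucleotideReactionParams(k=1.0)
    )

    def __post_init__(self) -> None:
        cls = CLASS_ALIASES.get(self.rate_class, self.rate_class)
        if cls not in RATE_CLASSES:
            raise ValueError(f"unknown nucleotide rate class {self.rate_class!r}")
        self.rate_class = cls
        if self.produces not in NUCLEOTIDES:
            raise ValueError(f"unknown nucleotide {self.produces!r}")
        if self.consumes is not None and self.consumes not in NUCLEOTIDES:
            raise ValueError(f"unknown nucleotide {self.consumes!r}")
        if self.rate_class != "glc_gln" and self.factor_nuc is None:
            raise ValueError(f"{self.id}: rate class {self.rate_class} needs factor_nuc")


@dataclass
class CellComposition:
    """Per-cell composition driving the DNA/RNA outlet fluxes.

    ``m_DNA``/``m_RNA`` in pg/cell; ``DNA_f``/``RNA_f`` map each outlet
    nucleotide to its monomer fraction (each set sums to 1; thymidine
    demand is booked against the UTP pool); ``Mr_DNA``/``Mr_RNA`` are the
    fraction-weighted monomer masses in mg/mmol; ``V_cell`` in L.
    """

    V_cell: float = 1.2e-12
    m_DNA: float = 7.05
    m_RNA: float = 28.55
    DNA_f: Dict[str, float] = field(
        default_factory=lambda: {"AMP": 0.29, "CTP": 0.21, "GTP": 0.21, "UTP": 0.29}
    )
    RNA_f: Dict[str, float] = field(
        default_factory=lambda: {"AMP": 0.26, "CTP": 0.26, "GTP": 0.26, "UTP": 0.22}
    )
    Mr_DNA: float = 308.9
    Mr_RNA: float = 322.1
    K_TP_nuc: float = 0.2

    def __post_init__(self) -> None:
        for name in ("V_cell", "m_DNA", "m_RNA", "Mr_DNA", "Mr_RNA", "K_TP_nuc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for fractions in (self.DNA_f, self.RNA_f):
            for nuc, f in fractions.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"fraction for {nuc} outside [0, 1]")
            if abs(sum(fractions.values()) - 1.0) > 1e-6:
                raise ValueError("nucleotide fractions must sum to 1")


def _monod(c: float, k: float) -> float:
    return c / (k + c)


def nucleotide_rate(
    rate_class: str,
    nuc: float,
    glc_ext: float,
    gln_ext: float,
    p: NucleotideReactionParams,
) -> float:
    """Rate of one reduced-network reaction, mM/h."""
    cls = CLASS_ALIASES.get(rate_class, rate_class)
    if cls not in RATE_CLASSES:
        raise ValueError(f"unknown nucleotide rate class {rate_class!r}")
    if min(nuc, glc_ext, gln_ext) < 0:
        raise ValueError("concentrations must be >= 0")
    if cls == "nuc":
        return p.k * _monod(nuc, p.K_M_nuc)
    if cls == "nuc_gln":
        return p.k * _monod(nuc, p.K_M_nuc) * _monod(gln_ext, p.K_M_gln)
    if cls == "nuc_glc":
        return p.k * _monod(nuc, p.K_M_nuc) * _monod(glc_ext, p.K_M_glc)
    return p.k * _monod(glc_ext, p.K_M_glc) * _monod(gln_ext, p.K_M_gln)


def nucleic_acid_demand(
    nuc_id: str,
    nuc_conc: float,
    mu: float,
    comp: CellComposition,
) -> float:
    """Growth-coupled DNA/RNA outlet flux for one nucleotide, mM/h.

    The per-cell monomer demand
    ``DNA_f*m_DNA/Mr_DNA + RNA_f*m_RNA/Mr_RNA`` (mmol/cell) is scaled by
    the growth rate and converted to a concentration rate with the cell
    volume; a saturation factor in the nucleotide concentration shuts the
    flux down as the pool empties.
    """
    if nuc_id not in OUTLET_NUCLEOTIDES:
        raise ValueError(
            f"no nucleic-acid outlet for {nuc_id!r}; outlets exist for "
            f"{OUTLET_NUCLEOTIDES}"
        )
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if nuc_conc < 0:
        raise ValueError("concentration must be >= 0")
    per_cell = (
        comp.DNA_f[nuc_id] * comp.m_DNA * PG_PER_MG / comp.Mr_DNA
        + comp.RNA_f[nuc_id] * comp.m_RNA * PG_PER_MG / comp.Mr_RNA
    )  # mmol monomer per cell
    return _monod(nuc_conc, comp.K_TP_nuc) * mu * per_cell / comp.V_cell


def default_reactions(params: Mapping[str, NucleotideReactionParams] | None = None):
    """The eight-reaction default wiring of the reduced network.

    Adenylate interconversions (ATP<->ADP<->AMP), de-novo synthesis of
    ATP, UTP and GTP, and UTP->CTP amination.  The de-novo GTP reaction
    carries an ATP saturation factor as its nucleotide term (purine
    precursor availability).
    """
    params = params or {}

    def p(rid: str, k: float) -> NucleotideReactionParams:
        return params.get(rid, NucleotideReactionParams(k=k))

    return [
        NucleotideReaction("atp_to_adp", "nuc", produces="ADP", consumes="ATP",
                           factor_nuc="ATP", params=p("atp_to_adp", 12.0)),
        NucleotideReaction("adp_to_amp", "nuc", produces="AMP", consumes="ADP",
                           factor_nuc="ADP", params=p("adp_to_amp", 2.0)),
        NucleotideReaction("amp_to_adp", "nuc_glc", produces="ADP", consumes="AMP",
                           factor_nuc="AMP", params=p("amp_to_adp", 2.0)),
        NucleotideReaction("adp_to_atp", "nuc_glc", produces="ATP", consumes="ADP",
                           factor_nuc="ADP", params=p("adp_to_atp", 13.0)),
        NucleotideReaction("denovo_atp", "glc_gln", produces="ATP",
                           params=p("denovo_atp", 1.0)),
        NucleotideReaction("denovo_utp", "glc_gln", produces="UTP",
                           params=p("denovo_utp", 13.0)),
        NucleotideReaction("utp_to_ctp", "nuc_gln", produces="CTP", consumes="UTP",
                           factor_nuc="UTP", params=p("utp_to_ctp", 3.5)),
        NucleotideReaction("denovo_gtp", "nuc_gln", produces="GTP",
                           factor_nuc="ATP", params=p("denovo_gtp", 7.0)),
    ]


def nucleotide_rhs(
    state: Mapping[str, float],
    glc_ext: float,
    gln_ext: float,
    mu: float,
    comp: CellComposition,
    reactions,
    nsd_drain: Mapping[str, float] | None = None,
    outlets_enabled: bool = True,
) -> Dict[str, float]:
    """Time derivatives of the six nucleotide balances, mM/h.

    Each balance sums incoming reactions minus outgoing reactions, the
    growth-coupled nucleic-acid outlet (AMP/CTP/GTP/UTP) and the NSD
    synthesis drain supplied by the NSD layer.
    """
    nsd_drain = nsd_drain or {}
    d = {n: 0.0 for n in NUCLEOTIDES}
    for rxn in reactions:
        nuc_c = state[rxn.factor_nuc] if rxn.factor_nuc is not None else 0.0
        r = nucleotide_rate(rxn.rate_class, nuc_c, glc_ext, gln_ext, rxn.params)
        d[rxn.produces] += r
        if rxn.consumes is not None:
            d[rxn.consumes] -= r
    if outlets_enabled:
        for nuc in OUTLET_NUCLEOTIDES:
            d[nuc] -= nucleic_acid_demand(nuc, state[nuc], mu, comp)
    for nuc, drain in nsd_drain.items():
        d[nuc] -= drain
    return d
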