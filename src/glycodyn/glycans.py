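"""Glycan demand arithmetic: from glycan composition tables to NSD consumption.

Host-cell protein glycosylation and product (mAb) glycosylation drain the
cytosolic NSD pools through the Golgi/ER transporters.  The demand side of
each transport flux is assembled from

* the per-cell glycan concentration ``N_gly_cell`` (mmol glycans/cell,
  O-linked + N-linked),
* the abundance-weighted mean sugar composition of an average glycan
  (``N_NSD_gly``, mmol NSD consumed per mmol glycan), and
* the product terms ``N_gly_mAb`` (glycans per antibody, 2 for the two
  Fc N-glycans) and ``N_NSD_mAb`` (sugar composition of the product
  glycan).

Two salvage routes feed sugars back into the cytosol: trimming of the
Glc3Man9GlcNAc2 precursor returns mannose (9 minus the mean residual
mannose count per glycan), and the four glucose units cycled through
calnexin/calreticulin return as intracellular glucose (paired with the
four UDP-Glc consumed per N-glycan).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping

SUGARS = ("GlcNAc", "GalNAc", "Man", "Gal", "Neu5Ac", "Fuc")

#: sugar moiety -> NSD species that donates it
SUGAR_TO_NSD = {
    "GlcNAc": "UDP-GlcNAc",
    "GalNAc": "UDP-GalNAc",
    "Man": "GDP-Man",
    "Gal": "UDP-Gal",
    "Neu5Ac": "CMP-Neu5Ac",
    "Fuc": "GDP-Fuc",
}

#: mannose residues on the unprocessed N-glycan precursor
PRECURSOR_MAN = 9.0
#: UDP-Glc consumed (and glucose salvaged) per N-glycan in the
#: calnexin/calreticulin cycle
UDPGLC_PER_GLYCAN = 4.0


@dataclass
class GlycanCompositionTable:
    """Mean sugar counts per glycan type plus per-cell glycan abundances.

    ``counts`` maps glycan type ('N_linked', 'O_linked', ...) to a mapping
    sugar -> mean residue count; ``abundances`` maps the same types to
    per-cell glycan concentrations in mmol/cell.
    """

    counts: Dict[str, Dict[str, float]]
    abundances: Dict[str, float]

    def __post_init__(self) -> None:
        for gtype, row in self.counts.items():
            for sugar, n in row.items():
                if n < 0:
                    raise ValueError(f"negative count for {sugar} in {gtype}")
        for gtype, a in self.abundances.items():
            if a < 0:
                raise ValueError(f"negative abundance for {gtype}")
            if gtype not in self.counts:
                raise KeyError(f"abundance for unknown glycan type {gtype!r}")


@dataclass
class GlycanDemand:
    """Per-cell and per-product NSD consumption coefficients.

    Attributes
    ----------
    N_gly_cell : float
        Total glycans per cell, mmol/cell (all types).
    N_gly_cell_N_linked : float
        N-linked glycans per cell, mmol/cell (drives UDP-Glc consumption
        and mannose/glucose salvage).
    N_NSD_gly : dict
        NSD id -> mmol consumed per mmol of average host glycan.
    N_gly_mAb : float
        Glycans per antibody molecule (2: one per Fc heavy chain).
    N_NSD_mAb : dict
        NSD id -> mmol consumed per mmol of product glycan.
    udpglc_per_glycan : float
        UDP-Glc consumed per N-glycan in the calnexin/calreticulin cycle.
    man_salvage_per_glycan : float
        Mannose units returned per processed N-glycan
        (precursor 9 minus the mean residual mannose count).
    extra_demand : dict
        Additional per-glycan demand coefficients for NSDs not covered by
        the composition table (e.g. UDP-GlcA / UDP-Xyl towards
        glycosaminoglycan synthesis).
    """

    N_gly_cell: float
    N_gly_cell_N_linked: float
    N_NSD_gly: Dict[str, float]
    N_gly_mAb: float = 2.0
    N_NSD_mAb: Dict[str, float] = field(default_factory=dict)
    udpglc_per_glycan: float = UDPGLC_PER_GLYCAN
    man_salvage_per_glycan: float = 0.0
    extra_demand: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("N_gly_cell", "N_gly_cell_N_linked", "N_gly_mAb",
                     "udpglc_per_glycan", "man_salvage_per_glycan"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for d in (self.N_NSD_gly, self.N_NSD_mAb, self.extra_demand):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"negative demand coefficient for {k}")


def glycan_demand_from_composition(
    tbl: GlycanCompositionTable,
    N_gly_mAb: float = 2.0,
    mab_counts: Mapping[str, float] | None = None,
    extra_demand: Mapping[str, float] | None = None,
) -> GlycanDemand:
    """Collapse a composition table into the demand coefficients.

    ``N_gly_cell`` is the sum of the per-type abundances and each sugar's
    ``N_NSD_gly`` entry is the abundance-weighted mean of the per-type
    counts.  The mannose salvage coefficient is ``9 - mean Man per
    glycan``.
    """
    total = sum(tbl.abundances.values())
    if total <= 0:
        raise ValueError("total glycan abundance must be positive")
    avg: Dict[str, float] = {}
    for sugar in SUGARS:
        avg[sugar] = (
            sum(tbl.abundances[g] * tbl.counts[g].get(sugar, 0.0)
                for g in tbl.abundances)
            / total
        )
    if avg["Man"] > PRECURSOR_MAN:
        raise ValueError(
            f"mean mannose per glycan ({avg['Man']:.3f}) exceeds the "
            f"precursor count of {PRECURSOR_MAN:g}"
        )
    n_linked = tbl.abundances.get("N_linked", 0.0)
    nsd_gly = {SUGAR_TO_NSD[s]: avg[s] for s in SUGARS}
    mab_nsd: Dict[str, float] = {}
    if mab_counts:
        mab_nsd = {SUGAR_TO_NSD[s]: float(mab_counts.get(s, 0.0)) for s in SUGARS}
    return GlycanDemand(
        N_gly_cell=total,
        N_gly_cell_N_linked=n_linked,
        N_NSD_gly=nsd_gly,
        N_gly_mAb=N_gly_mAb,
        N_NSD_mAb=mab_nsd,
        udpglc_per_glycan=UDPGLC_PER_GLYCAN,
        man_salvage_per_glycan=PRECURSOR_MAN - avg["Man"],
        extra_demand=dict(extra_demand or {}),
    )


def salvage_fluxes(
    d: GlycanDemand,
    host_glycan_flux: float,
    mab_glycan_flux: float,
    volume: float,
) -> Dict[str, float]:
    """Mannose and glucose salvage source fluxes, mM/h.

    ``host_glycan_flux`` and ``mab_glycan_flux`` are N-glycan synthesis
    rates in mmol glycans/h; ``volume`` is the volume (L) over which the
    returned concentration rates are expressed (the aggregate cell volume
    when feeding intracellular pools).

    Mannose salvage applies the host coefficient ``9 - mean Man per
    glycan`` to the host flux and ``9 - product glycan Man count`` to the
    product flux; glucose salvage returns the four precursor glucoses per
    N-glycan of either origin.
    """
    if host_glycan_flux < 0 or mab_glycan_flux < 0:
        raise ValueError("glycan fluxes must be >= 0")
    if volume <= 0:
        raise ValueError("volume must be > 0")
    mab_man = d.N_NSD_mAb.get("GDP-Man", 0.0)
    if mab_man > PRECURSOR_MAN:
        raise ValueError("product glycan mannose count exceeds the precursor")
    man = (
        d.man_salvage_per_glycan * host_glycan_flux
        + (PRECURSOR_MAN - mab_man) * mab_glycan_flux
    ) / volume
    glc = d.udpglc_per_glycan * (host_glycan_flux + mab_glycan_flux) / volume
    return {"Man": man, "Glc": glc}


def transport_demand(
    nsd_id: str,
    d: GlycanDemand,
    mu: float,
    q_mab: float,
    v_cell: float,
) -> float:
    """Volumetric NSD consumption demand, mM/h of cell volume.

    The host term converts the per-cell glycan synthesis rate
    ``mu * N_gly_cell`` (mmol glycans/(cell h)) into a concentration rate
    by dividing with the single-cell volume ``v_cell``; the product term
    uses the specific productivity ``q_mab`` (mmol mAb/(cell h)) the same
    way.  UDP-Glc demand and the extra (glycosaminoglycan) demands are
    driven by the N-linked glycan flux only.
    """
    if mu < 0 or q_mab < 0:
        raise ValueError("mu and q_mab must be >= 0")
    if v_cell <= 0:
        raise ValueError("v_cell must be > 0")
    if nsd_id == "UDP-Glc":
        host = mu * d.N_gly_cell_N_linked * d.udpglc_per_glycan
        mab = q_mab * d.N_gly_mAb * d.udpglc_per_glycan
    elif nsd_id in d.N_NSD_gly:
        host = mu * d.N_gly_cell * d.N_NSD_gly[nsd_id]
        mab = q_mab * d.N_gly_mAb * d.N_NSD_mAb.get(nsd_id, 0.0)
    elif nsd_id in d.extra_demand:
        host = mu * d.N_gly_cell * d.extra_demand[nsd_id]
        mab = 0.0
    else:
        raise KeyError(f"no demand coefficient for NSD {nsd_id!r}")
    return (host + mab) / v_cell
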