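"""Reduced nucleotide network: rate classes, outlets and conservation."""

from __future__ import annotations

import numpy as np
import pytest

from glycodyn.nucleotides import (
    CellComposition,
    NUCLEOTIDES,
    NucleotideReaction,
    NucleotideReactionParams,
    default_reactions,
    nucleic_acid_demand,
    nucleotide_rate,
    nucleotide_rhs,
)

P = NucleotideReactionParams(k=2.0, K_M_nuc=1.0, K_M_glc=1.0, K_M_gln=0.3)


def test_rate_class_factor_structure():
    # double half-saturation in the co-substrates
    assert nucleotide_rate("glc_gln", 0.0, 1.0, 0.3, P) == pytest.approx(0.5)
    # saturation in the nucleotide alone
    assert nucleotide_rate("nuc", 1e12, 5.0, 5.0, P) == pytest.approx(2.0, rel=1e-9)
    # nucleotide x glutamine: 1/2 * 3/4
    assert nucleotide_rate("nuc_gln", 1.0, 0.0, 0.9, P) == pytest.approx(
        2.0 * 0.5 * 0.75)
    # nucleotide x glucose
    assert nucleotide_rate("nuc_glc", 1.0, 1.0, 0.0, P) == pytest.approx(
        2.0 * 0.5 * 0.5)


def test_printed_equation_aliases():
    assert nucleotide_rate("Eq10", 1.0, 0, 0, P) == nucleotide_rate("nuc", 1.0, 0, 0, P)
    assert nucleotide_rate("Eq13", 0, 1.0, 0.3, P) == nucleotide_rate(
        "glc_gln", 0, 1.0, 0.3, P)
    with pytest.raises(ValueError):
        nucleotide_rate("Eq99", 1.0, 1.0, 1.0, P)


def test_nucleic_acid_demand_boundaries():
    comp = CellComposition()
    assert nucleic_acid_demand("UTP", 5.0, 0.0, comp) == 0.0
    assert nucleic_acid_demand("UTP", 0.0, 0.05, comp) == 0.0
    with pytest.raises(ValueError):
        nucleic_acid_demand("ATP", 1.0, 0.05, comp)  # outlets: AMP/CTP/GTP/UTP
    with pytest.raises(ValueError):
        nucleic_acid_demand("ADP", 1.0, 0.05, comp)


def test_nucleic_acid_demand_saturated_hand_value():
    """At Nuc >> K the flux equals mu * per-cell monomer demand / V_cell,
    evaluated here independently from the composition constants."""
    comp = CellComposition()
    mu = 0.03
    pg_to_mg = 1e-9
    per_cell = (comp.DNA_f["UTP"] * comp.m_DNA * pg_to_mg / comp.Mr_DNA
                + comp.RNA_f["UTP"] * comp.m_RNA * pg_to_mg / comp.Mr_RNA)
    expect = mu * per_cell / comp.V_cell
    got = nucleic_acid_demand("UTP", 1e9, mu, comp)
    assert got == pytest.approx(expect, rel=1e-6)
    # magnitude sanity: order 1 mM/h at exponential-phase growth
    assert 0.1 < got < 10.0


def test_fractions_must_sum_to_one():
    with pytest.raises(ValueError):
        CellComposition(DNA_f={"AMP": 0.5, "CTP": 0.2, "GTP": 0.2, "UTP": 0.2})


def test_rhs_zero_everywhere_at_equilibrium():
    state = {n: 0.0 for n in NUCLEOTIDES}
    d = nucleotide_rhs(state, 0.0, 0.0, 0.0, CellComposition(),
                       default_reactions())
    assert all(v == 0.0 for v in d.values())


def test_single_flux_bookkeeping():
    rxn = NucleotideReaction("denovo_atp", "glc_gln", produces="ATP",
                             params=NucleotideReactionParams(k=3.0))
    state = {n: 1.0 for n in NUCLEOTIDES}
    d = nucleotide_rhs(state, 1.0, 0.3, 0.0, CellComposition(), [rxn],
                       outlets_enabled=False)
    r = nucleotide_rate("glc_gln", 0, 1.0, 0.3, rxn.params)
    assert d["ATP"] == pytest.approx(r)
    assert all(d[n] == 0.0 for n in NUCLEOTIDES if n != "ATP")


@pytest.mark.parametrize("state_seed", [0, 1, 2])
def test_adenylate_conservation_without_outlets_and_drains(state_seed):
    """The interconversion wiring conserves ATP+ADP+AMP up to de-novo
    synthesis: d(ATP+ADP+AMP)/dt equals the de-novo ATP input exactly
    (1e-9 relative), at random states."""
    rng = np.random.default_rng(state_seed)
    state = {n: float(rng.uniform(0.05, 5.0)) for n in NUCLEOTIDES}
    glc, gln = float(rng.uniform(1, 25)), float(rng.uniform(0.1, 4))
    reactions = default_reactions()
    d = nucleotide_rhs(state, glc, gln, 0.04, CellComposition(), reactions,
                       outlets_enabled=False)
    denovo = [r for r in reactions if r.id == "denovo_atp"][0]
    input_rate = nucleotide_rate("glc_gln", 0, glc, gln, denovo.params)
    total = d["ATP"] + d["ADP"] + d["AMP"]
    assert total == pytest.approx(input_rate, rel=1e-9)


def test_drains_subtract_from_named_pools():
    state = {n: 1.0 for n in NUCLEOTIDES}
    base = nucleotide_rhs(state, 5.0, 2.0, 0.0, CellComposition(),
                          default_reactions(), outlets_enabled=False)
    drained = nucleotide_rhs(state, 5.0, 2.0, 0.0, CellComposition(),
                             default_reactions(),
                             nsd_drain={"UTP": 0.7, "GTP": 0.2, "CTP": 0.1},
                             outlets_enabled=False)
    assert drained["UTP"] == pytest.approx(base["UTP"] - 0.7)
    assert drained["GTP"] == pytest.approx(base["GTP"] - 0.2)
    assert drained["CTP"] == pytest.approx(base["CTP"] - 0.1)
    assert drained["ATP"] == pytest.approx(base["ATP"])


def test_default_network_shape():
    """Six pools connected by eight reactions; outlets for AMP/CTP/GTP/UTP."""
    reactions = default_reactions()
    assert len(reactions) == 8
    assert len(NUCLEOTIDES) == 6
    consumed = {r.consumes for r in reactions if r.consumes}
    produced = {r.produces for r in reactions}
    assert produced == {"ATP", "ADP", "AMP", "CTP", "GTP", "UTP"}
    assert consumed <= set(NUCLEOTIDES)
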