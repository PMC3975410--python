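"""Glycan demand arithmetic: worked examples from the host-cell B-cell
glycoform table and the salvage bookkeeping."""

from __future__ import annotations

import pytest

from glycodyn.glycans import (
    GlycanCompositionTable,
    glycan_demand_from_composition,
    salvage_fluxes,
    transport_demand,
)

# mean sugar counts per glycan of mature B-cells plus per-cell abundances
N_ROW = {"GlcNAc": 2.896, "GalNAc": 0.0, "Man": 5.813, "Gal": 0.759,
         "Neu5Ac": 0.516, "Fuc": 0.332}
O_ROW = {"GlcNAc": 0.156, "GalNAc": 1.0, "Man": 0.0, "Gal": 1.156,
         "Neu5Ac": 1.543, "Fuc": 0.0}
N_ABUND = 1.41e-11  # mmol glycans per cell
O_ABUND = 1.31e-11


@pytest.fixture()
def table():
    return GlycanCompositionTable(
        counts={"N_linked": N_ROW, "O_linked": O_ROW},
        abundances={"N_linked": N_ABUND, "O_linked": O_ABUND},
    )


def test_total_glycans_per_cell(table):
    """The per-type abundances sum to 2.72e-8 umol (2.72e-11 mmol)/cell."""
    d = glycan_demand_from_composition(table)
    assert d.N_gly_cell == pytest.approx(2.72e-11, rel=1e-12)
    assert d.N_gly_cell_N_linked == pytest.approx(1.41e-11, rel=1e-12)


def test_abundance_weighted_sugar_averages(table):
    """Average-glycan demand coefficients match the published averages
    (Gal 0.950, Neu5Ac 1.010, GalNAc 0.481) to the rounding of the
    printed weights."""
    d = glycan_demand_from_composition(table)
    assert d.N_NSD_gly["UDP-Gal"] == pytest.approx(0.950, abs=2e-3)
    assert d.N_NSD_gly["CMP-Neu5Ac"] == pytest.approx(1.010, abs=2e-3)
    assert d.N_NSD_gly["UDP-GalNAc"] == pytest.approx(0.481, abs=2e-3)
    assert d.N_NSD_gly["GDP-Man"] == pytest.approx(3.018, abs=6e-3)
    assert d.N_NSD_gly["UDP-GlcNAc"] == pytest.approx(1.579, abs=4e-3)
    assert d.N_NSD_gly["GDP-Fuc"] == pytest.approx(0.173, abs=2e-3)
    assert d.man_salvage_per_glycan == pytest.approx(9.0 - 3.018, abs=6e-3)


def test_degenerate_weighting_returns_single_row(table):
    """With zero O-linked abundance the averages equal the N-linked row."""
    tbl = GlycanCompositionTable(
        counts={"N_linked": N_ROW, "O_linked": O_ROW},
        abundances={"N_linked": N_ABUND, "O_linked": 0.0},
    )
    d = glycan_demand_from_composition(tbl)
    assert d.N_NSD_gly["UDP-GlcNAc"] == pytest.approx(N_ROW["GlcNAc"], rel=1e-12)
    assert d.N_NSD_gly["GDP-Man"] == pytest.approx(N_ROW["Man"], rel=1e-12)


def test_zero_total_abundance_is_an_error():
    tbl = GlycanCompositionTable(
        counts={"N_linked": N_ROW}, abundances={"N_linked": 0.0},
    )
    with pytest.raises(ValueError):
        glycan_demand_from_composition(tbl)


def test_excess_mannose_rejected(table):
    tbl = GlycanCompositionTable(
        counts={"N_linked": dict(N_ROW, Man=9.5)},
        abundances={"N_linked": N_ABUND},
    )
    with pytest.raises(ValueError):
        glycan_demand_from_composition(tbl)


def test_salvage_worked_example(table):
    """Mannose salvage = (9 - mean Man per glycan) x N-glycan flux / V."""
    d = glycan_demand_from_composition(table)
    s = salvage_fluxes(d, host_glycan_flux=1e-9, mab_glycan_flux=0.0,
                       volume=0.4)
    assert s["Man"] == pytest.approx(d.man_salvage_per_glycan * 1e-9 / 0.4,
                                     rel=1e-12)
    assert s["Man"] == pytest.approx((9 - 3.018) * 1e-9 / 0.4, rel=2e-3)
    assert s["Glc"] == pytest.approx(4.0 * 1e-9 / 0.4, rel=1e-12)


def test_salvage_boundaries(table):
    d = glycan_demand_from_composition(table)
    assert salvage_fluxes(d, 0.0, 0.0, 0.4) == {"Man": 0.0, "Glc": 0.0}
    # fully unprocessed high-mannose glycans salvage nothing
    tbl = GlycanCompositionTable(
        counts={"N_linked": dict(N_ROW, Man=9.0)},
        abundances={"N_linked": N_ABUND},
    )
    d9 = glycan_demand_from_composition(tbl)
    assert salvage_fluxes(d9, 1e-9, 0.0, 0.4)["Man"] == pytest.approx(0.0)
    with pytest.raises(ValueError):
        salvage_fluxes(d, -1.0, 0.0, 0.4)


def test_transport_demand_structure(table):
    d = glycan_demand_from_composition(
        table, mab_counts={"GlcNAc": 4.0, "Man": 3.0, "Fuc": 1.0},
        extra_demand={"UDP-Xyl": 0.05},
    )
    v_cell = 1.2e-12
    # no growth, no product: no demand
    assert transport_demand("GDP-Man", d, 0.0, 0.0, v_cell) == 0.0
    # host term scales with mu
    mu = 0.05
    expect = mu * d.N_gly_cell * d.N_NSD_gly["GDP-Man"] / v_cell
    assert transport_demand("GDP-Man", d, mu, 0.0, v_cell) == pytest.approx(expect)
    # UDP-Glc demand uses 4 per N-glycan
    expect = mu * d.N_gly_cell_N_linked * 4.0 / v_cell
    assert transport_demand("UDP-Glc", d, mu, 0.0, v_cell) == pytest.approx(expect)
    # glycosaminoglycan extras route through extra_demand
    assert transport_demand("UDP-Xyl", d, mu, 0.0, v_cell) > 0
    with pytest.raises(KeyError):
        transport_demand("not-an-nsd", d, mu, 0.0, v_cell)
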