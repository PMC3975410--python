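"""Regenerate the shipped default configuration.

Writes ``src/glycodyn/data/default_config.yaml``.  The default network is
assembled here so that the structural contract (34 dynamic species,
35 primary steps + 24 reverse/parallel enzymatic reactions + 9 transports
+ 1 glycolysis outlet = 69 distinct reactions, mechanism census
20/7/14/17/1, 76 inhibitory terms, 5 activations, 6 Hill species) is
correct by construction.  All kinetic constants are literature-plausible
placeholders (``provenance: placeholder``); calibration overwrites them.

Run from the repository root:  python scripts/make_default_config.py
"""

from __future__ import annotations

import pathlib

import yaml

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "glycodyn" / "data" / "default_config.yaml"

E0 = 0.0039  # mM; average molar enzyme concentration of the host cell

MEASURED_INITIAL = {
    "UDP-Glc": 0.8,
    "UDP-Gal": 0.25,
    "UDP-GlcNAc": 4.0,
    "UDP-GalNAc": 0.8,
    "GDP-Man": 0.6,
    "GDP-Fuc": 0.05,
    "CMP-Neu5Ac": 0.7,
}

DYNAMIC = [
    "Glc", "Glc6P", "Fru6P", "Glc1P", "UDP-Glc", "UDP-Gal", "Gal", "Gal1P",
    "UDP-GlcA", "UDP-Xyl", "GlcN", "GlcN6P", "GlcN1P", "GlcNAc", "GlcNAc6P",
    "GlcNAc1P", "UDP-GlcNAc", "GalNAc", "GalNAc1P", "UDP-GalNAc", "ManNAc",
    "ManNAc6P", "Neu5Ac9P", "Neu5Ac", "CMP-Neu5Ac", "Man", "Man6P", "Man1P",
    "GDP-Man", "GDP-4k6dMan", "GDP-Fuc", "Fuc", "Fuc1P", "Fru",
]

CONSTANT = {
    "PEP": 0.1, "Pyr": 0.5, "Glu": 4.0, "AcCoA": 0.1, "PPi": 0.5,
    "Pi": 5.0, "NAD": 0.5, "NADH": 0.05, "H2O": 55000.0,
}

# nucleotide pools and the intracellular-glutamine proxy live in other
# layers of the coupled model
BOUNDARY = ["ATP", "ADP", "AMP", "UTP", "CTP", "GTP", "Gln_int"]

# (id, enzyme, mechanism, substrates, products, role, partner, kcat, {Km})
R = []


def rxn(rid, enzyme, mech, subs, prods, role, partner, kcat, km):
    R.append(dict(id=rid, enzyme=enzyme, mechanism=mech, substrates=subs,
                  products=prods, role=role, partner=partner, kcat=kcat, km=km))


# --- 35 primary steps -------------------------------------------------------
rxn("HK", "HK", "ordered_bibi", ["Glc", "ATP"], ["Glc6P", "ADP"], "primary", None,
    9.0e4, {"Glc": 4.0, "ATP": 0.4})
rxn("PGI", "PGI", "uni_uni", ["Glc6P"], ["Fru6P"], "primary", None,
    1.6e5, {"Glc6P": 0.3})
rxn("PGM", "PGM", "uni_uni", ["Glc6P"], ["Glc1P"], "primary", None,
    2.2e3, {"Glc6P": 0.2})
rxn("UGP", "UGP", "pingpong_bibi", ["Glc1P", "UTP"], ["UDP-Glc", "PPi"], "primary", None,
    2.5e3, {"Glc1P": 0.1, "UTP": 0.3})
rxn("GALE", "GALE", "uni_uni", ["UDP-Glc"], ["UDP-Gal"], "primary", None,
    700.0, {"UDP-Glc": 0.3})
rxn("UGDH", "UGDH", "pingpong_terter", ["UDP-Glc", "NAD"], ["UDP-GlcA", "NADH"], "primary", None,
    50.0, {"UDP-Glc": 0.5, "NAD": 0.1})
rxn("UXS", "UXS", "uni_uni", ["UDP-GlcA"], ["UDP-Xyl"], "primary", None,
    100.0, {"UDP-GlcA": 0.2})
rxn("GALK", "GALK", "ordered_bibi", ["Gal", "ATP"], ["Gal1P", "ADP"], "primary", None,
    800.0, {"Gal": 0.2, "ATP": 0.4})
rxn("GALT", "GALT", "pingpong_bibi", ["Gal1P", "UDP-Glc"], ["UDP-Gal", "Glc1P"], "primary", None,
    800.0, {"Gal1P": 0.2, "UDP-Glc": 0.3})
rxn("GFPT", "GFPT", "pingpong_bibi", ["Fru6P", "Gln_int"], ["GlcN6P", "Glu"], "primary", None,
    6.0e3, {"Fru6P": 0.1, "Gln_int": 0.3})
rxn("GNPNAT", "GNPNAT", "random_bibi", ["GlcN6P", "AcCoA"], ["GlcNAc6P"], "primary", None,
    4.0e3, {"GlcN6P": 0.2, "AcCoA": 0.02})
rxn("PGM3", "PGM3", "uni_uni", ["GlcNAc6P"], ["GlcNAc1P"], "primary", None,
    2.5e3, {"GlcNAc6P": 0.1})
rxn("UAP", "UAP", "ordered_bibi", ["GlcNAc1P", "UTP"], ["UDP-GlcNAc", "PPi"], "primary", None,
    1.2e3, {"GlcNAc1P": 0.1, "UTP": 0.3})
rxn("GALE2", "GALE2", "uni_uni", ["UDP-GlcNAc"], ["UDP-GalNAc"], "primary", None,
    250.0, {"UDP-GlcNAc": 0.3})
rxn("GNE", "GNE", "uni_uni", ["UDP-GlcNAc"], ["ManNAc"], "primary", None,
    1.2e3, {"UDP-GlcNAc": 0.5})
rxn("MNK", "MNK", "ordered_bibi", ["ManNAc", "ATP"], ["ManNAc6P", "ADP"], "primary", None,
    3.0e3, {"ManNAc": 0.2, "ATP": 0.4})
rxn("NANS", "NANS", "random_bibi", ["ManNAc6P", "PEP"], ["Neu5Ac9P", "Pi"], "primary", None,
    3.0e3, {"ManNAc6P": 0.1, "PEP": 0.02})
rxn("NANP", "NANP", "uni_uni", ["Neu5Ac9P"], ["Neu5Ac"], "primary", None,
    2.0e3, {"Neu5Ac9P": 0.1})
rxn("CMAS", "CMAS", "ordered_bibi", ["Neu5Ac", "CTP"], ["CMP-Neu5Ac", "PPi"], "primary", None,
    2.5e3, {"Neu5Ac": 0.2, "CTP": 0.2})
rxn("HK_GlcN", "HK_GlcN", "ordered_bibi", ["GlcN", "ATP"], ["GlcN6P", "ADP"], "primary", None,
    800.0, {"GlcN": 0.3, "ATP": 0.4})
rxn("PGNM", "PGNM", "uni_uni", ["GlcN6P"], ["GlcN1P"], "primary", None,
    300.0, {"GlcN6P": 0.2})
rxn("GNA", "GNA", "random_bibi", ["GlcN1P", "AcCoA"], ["GlcNAc1P"], "primary", None,
    300.0, {"GlcN1P": 0.2, "AcCoA": 0.02})
rxn("NAGK", "NAGK", "ordered_bibi", ["GlcNAc", "ATP"], ["GlcNAc6P", "ADP"], "primary", None,
    500.0, {"GlcNAc": 0.2, "ATP": 0.4})
rxn("GALK2", "GALK2", "ordered_bibi", ["GalNAc", "ATP"], ["GalNAc1P", "ADP"], "primary", None,
    500.0, {"GalNAc": 0.2, "ATP": 0.4})
rxn("UAP2", "UAP2", "ordered_bibi", ["GalNAc1P", "UTP"], ["UDP-GalNAc", "PPi"], "primary", None,
    800.0, {"GalNAc1P": 0.1, "UTP": 0.3})
rxn("MPI", "MPI", "uni_uni", ["Fru6P"], ["Man6P"], "primary", None,
    2.0e3, {"Fru6P": 0.2})
rxn("PMM", "PMM", "uni_uni", ["Man6P"], ["Man1P"], "primary", None,
    2.0e3, {"Man6P": 0.2})
rxn("GMPPB", "GMPPB", "ordered_bibi", ["Man1P", "GTP"], ["GDP-Man", "PPi"], "primary", None,
    1.8e3, {"Man1P": 0.1, "GTP": 0.3})
rxn("GMDS", "GMDS", "uni_uni", ["GDP-Man"], ["GDP-4k6dMan"], "primary", None,
    40.0, {"GDP-Man": 0.2})
rxn("FX", "FX", "random_bibi", ["GDP-4k6dMan", "NADH"], ["GDP-Fuc", "NAD"], "primary", None,
    60.0, {"GDP-4k6dMan": 0.05, "NADH": 0.02})
rxn("FUK", "FUK", "ordered_bibi", ["Fuc", "ATP"], ["Fuc1P", "ADP"], "primary", None,
    500.0, {"Fuc": 0.2, "ATP": 0.4})
rxn("FPGT", "FPGT", "ordered_bibi", ["Fuc1P", "GTP"], ["GDP-Fuc", "PPi"], "primary", None,
    200.0, {"Fuc1P": 0.1, "GTP": 0.3})
rxn("HK_Man", "HK_Man", "ordered_bibi", ["Man", "ATP"], ["Man6P", "ADP"], "primary", None,
    2.0e3, {"Man": 0.2, "ATP": 0.4})
rxn("HK_Fru", "HK_Fru", "ordered_bibi", ["Fru", "ATP"], ["Fru6P", "ADP"], "primary", None,
    800.0, {"Fru": 0.5, "ATP": 0.4})
rxn("GNPDA", "GNPDA", "uni_uni", ["GlcN6P"], ["Fru6P"], "primary", None,
    200.0, {"GlcN6P": 0.3})

# --- reverse reactions (17): mutases, epimerases, isomerases run uni-uni;
# transferase/pyrophosphorylase reverses keep the substituted-enzyme form
rxn("PGI_r", "PGI", "uni_uni", ["Fru6P"], ["Glc6P"], "reverse", "PGI",
    8.0e4, {"Fru6P": 0.15})
rxn("PGM_r", "PGM", "uni_uni", ["Glc1P"], ["Glc6P"], "reverse", "PGM",
    1.5e3, {"Glc1P": 0.1})
rxn("GALE_r", "GALE", "uni_uni", ["UDP-Gal"], ["UDP-Glc"], "reverse", "GALE",
    800.0, {"UDP-Gal": 0.3})
rxn("PGM3_r", "PGM3", "uni_uni", ["GlcNAc1P"], ["GlcNAc6P"], "reverse", "PGM3",
    400.0, {"GlcNAc1P": 0.1})
rxn("GALE2_r", "GALE2", "uni_uni", ["UDP-GalNAc"], ["UDP-GlcNAc"], "reverse", "GALE2",
    250.0, {"UDP-GalNAc": 0.3})
rxn("MPI_r", "MPI", "uni_uni", ["Man6P"], ["Fru6P"], "reverse", "MPI",
    1.2e3, {"Man6P": 0.2})
rxn("PMM_r", "PMM", "uni_uni", ["Man1P"], ["Man6P"], "reverse", "PMM",
    500.0, {"Man1P": 0.2})
rxn("UGP_r", "UGP", "pingpong_bibi", ["UDP-Glc", "PPi"], ["Glc1P", "UTP"], "reverse", "UGP",
    600.0, {"UDP-Glc": 0.3, "PPi": 0.3})
rxn("GALT_r", "GALT", "pingpong_bibi", ["UDP-Gal", "Glc1P"], ["Gal1P", "UDP-Glc"], "reverse", "GALT",
    200.0, {"UDP-Gal": 0.3, "Glc1P": 0.2})
rxn("UAP_r", "UAP", "pingpong_bibi", ["UDP-GlcNAc", "PPi"], ["GlcNAc1P", "UTP"], "reverse", "UAP",
    500.0, {"UDP-GlcNAc": 0.3, "PPi": 0.3})
rxn("UAP2_r", "UAP2", "pingpong_bibi", ["UDP-GalNAc", "PPi"], ["GalNAc1P", "UTP"], "reverse", "UAP2",
    150.0, {"UDP-GalNAc": 0.3, "PPi": 0.3})
rxn("GMPPB_r", "GMPPB", "pingpong_bibi", ["GDP-Man", "PPi"], ["Man1P", "GTP"], "reverse", "GMPPB",
    400.0, {"GDP-Man": 0.3, "PPi": 0.3})
rxn("FPGT_r", "FPGT", "pingpong_bibi", ["GDP-Fuc", "PPi"], ["Fuc1P", "GTP"], "reverse", "FPGT",
    50.0, {"GDP-Fuc": 0.1, "PPi": 0.3})
rxn("CMAS_r", "CMAS", "pingpong_bibi", ["CMP-Neu5Ac", "PPi"], ["Neu5Ac", "CTP"], "reverse", "CMAS",
    50.0, {"CMP-Neu5Ac": 0.3, "PPi": 0.3})
rxn("GFPT_r", "GFPT", "pingpong_bibi", ["GlcN6P", "Glu"], ["Fru6P", "Gln_int"], "reverse", "GFPT",
    300.0, {"GlcN6P": 0.3, "Glu": 2.0})
rxn("NANS_r", "NANS", "pingpong_bibi", ["Neu5Ac9P", "Pi"], ["ManNAc6P", "PEP"], "reverse", "NANS",
    150.0, {"Neu5Ac9P": 0.2, "Pi": 2.0})
rxn("FX_r", "FX", "pingpong_bibi", ["GDP-Fuc", "NAD"], ["GDP-4k6dMan", "NADH"], "reverse", "FX",
    30.0, {"GDP-Fuc": 0.1, "NAD": 0.1})

# --- parallel reactions (7): isoenzymes and hexosamine deacetylases
rxn("UGP_p", "UGP2B", "pingpong_bibi", ["Glc1P", "UTP"], ["UDP-Glc", "PPi"], "parallel", "UGP",
    500.0, {"Glc1P": 0.2, "UTP": 0.5})
rxn("UAP_p", "AGX2", "pingpong_bibi", ["GlcNAc1P", "UTP"], ["UDP-GlcNAc", "PPi"], "parallel", "UAP",
    400.0, {"GlcNAc1P": 0.2, "UTP": 0.5})
rxn("NAGA1", "NAGA1", "pingpong_bibi", ["GlcNAc6P", "H2O"], ["GlcN6P"], "parallel", None,
    100.0, {"GlcNAc6P": 0.3, "H2O": 1000.0})
rxn("NAGA2", "NAGA2", "pingpong_bibi", ["GlcNAc1P", "H2O"], ["GlcN1P"], "parallel", None,
    100.0, {"GlcNAc1P": 0.3, "H2O": 1000.0})
rxn("GCK_p", "GCK", "random_bibi", ["Glc", "ATP"], ["Glc6P", "ADP"], "parallel", "HK",
    500.0, {"Glc": 5.0, "ATP": 0.4})
rxn("KHK_p", "KHK", "random_bibi", ["Fru", "ATP"], ["Fru6P", "ADP"], "parallel", "HK_Fru",
    300.0, {"Fru": 0.8, "ATP": 0.4})
rxn("NAGK_p", "NAGK2", "random_bibi", ["GlcNAc", "ATP"], ["GlcNAc6P", "ADP"], "parallel", "NAGK",
    300.0, {"GlcNAc": 0.3, "ATP": 0.4})

# --- 9 transports + glycolysis outlet --------------------------------------
TRANSPORTS = {
    "UDP-Glc": {"K_TP": 0.1},
    "UDP-Gal": {"K_TP": 0.0024},
    "UDP-GlcNAc": {"K_TP": 0.1},
    "UDP-GalNAc": {"K_TP": 0.1},
    "GDP-Man": {"K_TP": 0.05},
    "GDP-Fuc": {"K_TP": 0.03},
    "CMP-Neu5Ac": {
        "K_TP": 0.1,
        "inhibitors": [
            {"species": "UDP-GlcNAc", "K_i": 2.0},
            {"species": "UDP-GalNAc", "K_i": 2.0},
        ],
    },
    "UDP-GlcA": {"K_TP": 0.1},
    "UDP-Xyl": {"K_TP": 0.1},
}

# --- inhibition terms (76) --------------------------------------------------
INHIBITIONS = []
# competitive product inhibition on every enzymatic reaction (59 terms);
# the leading product competes with the leading substrate
PRODUCT_KI = 8.0
for r in R:
    INHIBITIONS.append(dict(
        reaction=r["id"], inhibitor=r["products"][0], type="competitive",
        K_i=PRODUCT_KI, target=r["substrates"][0],
    ))
# pathway feedbacks (11)
FEEDBACKS = [
    ("GFPT", "UDP-GlcNAc", "non_competitive", 4.0),
    ("GNE", "CMP-Neu5Ac", "non_competitive", 0.2),
    ("GMDS", "GDP-Fuc", "non_competitive", 0.3),
    ("UGDH", "UDP-Xyl", "un_competitive", 1.0),
    ("PGM", "UDP-Glc", "non_competitive", 8.0),
    ("UGP", "PPi", "non_competitive", 5.0),
    ("GMPPB", "GDP-Man", "non_competitive", 1.5),
    ("UAP", "UDP-GlcNAc", "non_competitive", 10.0),
    ("CMAS", "CMP-Neu5Ac", "non_competitive", 5.0),
    ("NANS", "CMP-Neu5Ac", "non_competitive", 2.0),
    ("MNK", "CMP-Neu5Ac", "non_competitive", 2.0),
]
for rid, sp, typ, ki in FEEDBACKS:
    INHIBITIONS.append(dict(reaction=rid, inhibitor=sp, type=typ, K_i=ki))
# ADP (energy-charge) un-competitive terms on six kinases (6)
for rid in ("HK", "GALK", "MNK", "HK_Man", "GCK_p", "KHK_p"):
    INHIBITIONS.append(dict(reaction=rid, inhibitor="ADP",
                            type="un_competitive", K_i=8.0))

ACTIVATIONS = [
    {"reaction": "GFPT", "activator": "Glc6P", "K_A": 0.5},
    {"reaction": "UAP", "activator": "GlcNAc6P", "K_A": 0.05},
    {"reaction": "GNE", "activator": "ATP", "K_A": 1.0},
    {"reaction": "CMAS", "activator": "ATP", "K_A": 1.0},
    {"reaction": "GNPNAT", "activator": "Fru6P", "K_A": 0.2},
]

HILL = {
    "GFPT": {"species": "Fru6P", "n": 1.5},
    "GNE": {"species": "UDP-GlcNAc", "n": 1.8},
    "MNK": {"species": "ManNAc", "n": 1.3},
    "NANS": {"species": "ManNAc6P", "n": 1.4},
    "CMAS": {"species": "Neu5Ac", "n": 1.2},
    "UAP": {"species": "UTP", "n": 1.3},
}

SPECIAL_E0 = {"UGP2B": 0.001, "AGX2": 0.001}


def build() -> dict:
    species_dynamic = []
    for sid in DYNAMIC:
        entry = {"id": sid}
        if sid in MEASURED_INITIAL:
            entry["measured"] = True
            entry["initial"] = MEASURED_INITIAL[sid]
        species_dynamic.append(entry)
    species_constant = [{"id": k, "initial": v} for k, v in CONSTANT.items()]
    species_boundary = [{"id": k} for k in BOUNDARY]

    reactions = []
    for r in R:
        entry = {
            "id": r["id"], "mechanism": r["mechanism"],
            "substrates": r["substrates"], "products": r["products"],
            "kinetics_ref": r["enzyme"], "role": r["role"],
        }
        if r["partner"]:
            entry["reversible_partner"] = r["partner"]
        reactions.append(entry)
    for nsd in TRANSPORTS:
        reactions.append({
            "id": f"T_{nsd}", "mechanism": "transport", "substrates": [nsd],
            "products": [], "kinetics_ref": f"T_{nsd}", "role": "transport",
        })
    reactions.append({
        "id": "GLYC_OUT", "mechanism": "glycolysis_outlet",
        "substrates": ["Fru6P"], "products": [], "kinetics_ref": "E_glyc",
        "role": "outlet",
    })

    mech_census = {}
    for r in R:
        mech_census[r["mechanism"]] = mech_census.get(r["mechanism"], 0) + 1

    enzymes = {}
    for r in R:
        enzymes.setdefault(r["enzyme"], {"E0": SPECIAL_E0.get(r["enzyme"], E0)})
    rxn_params = {
        r["id"]: {"kcat": r["kcat"], "Km": dict(r["km"])} for r in R
    }

    free = []
    for enz in ["HK", "PGI", "PGM", "UGP", "GALE", "UGDH", "UXS", "GALT",
                "GFPT", "GNPNAT", "PGM3", "UAP", "GALE2", "GNE", "MNK",
                "NANS", "NANP", "CMAS", "PGNM", "GNA", "MPI", "PMM",
                "GMPPB", "GMDS", "FX", "FPGT", "HK_Man", "UAP2", "NAGA1",
                "NAGK"]:
        free.append(f"E0:{enz}")
    for rid, sp in [("GFPT", "Fru6P"), ("GNE", "UDP-GlcNAc"),
                    ("CMAS", "Neu5Ac"), ("GMPPB", "Man1P"),
                    ("GMDS", "GDP-Man"), ("UGDH", "UDP-Glc"),
                    ("GALE", "UDP-Glc"), ("UAP", "GlcNAc1P")]:
        free.append(f"Km:{rid}:{sp}")
    for rid in ["GFPT", "GNE", "CMAS", "GMDS", "UGP", "UAP", "GMPPB"]:
        free.append(f"kcat:{rid}")
    free.append("hill:GFPT")
    assert len(free) == 46, len(free)

    cfg = {
        "meta": {
            "name": "default-hybridoma-nsd",
            "description": (
                "Default batch hybridoma culture with the full "
                "nucleotide-sugar-donor synthesis network. All kinetic "
                "constants are literature-plausible placeholders."
            ),
            "provenance": "placeholder",
        },
        "units": {"time": "h", "concentration": "mM", "volume": "L",
                  "cells": "cells/L", "amount": "mmol"},
        "culture": {
            "initial": {"V": 0.4, "Xv": 2.0e8, "Xd": 0.0,
                        "Glc_ext": 25.0, "Gln_ext": 4.0, "mAb": 0.0},
        },
        "growth": {
            "mu_max": 0.055, "K_M_glc": 1.0, "K_M_gln": 0.3,
            "k_d_max_glc": 0.008, "k_d_max_gln": 0.012,
            "K_d_glc": 0.5, "K_d_gln": 0.3,
            "Y_Xv_glc": 3.5e8, "Y_Xv_gln": 8.0e8,
            "m_glc": 9.5e-11, "m_gln": 2.0e-11,
            "Y_mAb_Xv": 6.0e-15,
        },
        "nucleotides": {
            "initial": {"ATP": 4.1, "ADP": 2.4, "AMP": 0.45,
                        "UTP": 3.0, "CTP": 0.9, "GTP": 2.2},
            "composition": {
                "V_cell": 1.2e-12, "m_DNA": 7.05, "m_RNA": 28.55,
                "DNA_f": {"AMP": 0.29, "CTP": 0.21, "GTP": 0.21, "UTP": 0.29},
                "RNA_f": {"AMP": 0.26, "CTP": 0.26, "GTP": 0.26, "UTP": 0.22},
                "Mr_DNA": 308.9, "Mr_RNA": 322.1, "K_TP_nuc": 0.2,
            },
            "reactions": [
                {"id": "atp_to_adp", "rate_class": "nuc", "produces": "ADP",
                 "consumes": "ATP", "factor_nuc": "ATP", "k": 12.0, "K_M_nuc": 1.0},
                {"id": "adp_to_amp", "rate_class": "nuc", "produces": "AMP",
                 "consumes": "ADP", "factor_nuc": "ADP", "k": 2.0, "K_M_nuc": 1.0},
                {"id": "amp_to_adp", "rate_class": "nuc_glc", "produces": "ADP",
                 "consumes": "AMP", "factor_nuc": "AMP", "k": 2.0, "K_M_nuc": 1.0},
                {"id": "adp_to_atp", "rate_class": "nuc_glc", "produces": "ATP",
                 "consumes": "ADP", "factor_nuc": "ADP", "k": 13.0, "K_M_nuc": 1.0},
                {"id": "denovo_atp", "rate_class": "glc_gln", "produces": "ATP",
                 "k": 1.0},
                {"id": "denovo_utp", "rate_class": "glc_gln", "produces": "UTP",
                 "k": 10.0},
                {"id": "utp_to_ctp", "rate_class": "nuc_gln", "produces": "CTP",
                 "consumes": "UTP", "factor_nuc": "UTP", "k": 2.3, "K_M_nuc": 1.0},
                {"id": "denovo_gtp", "rate_class": "nuc_gln", "produces": "GTP",
                 "factor_nuc": "ATP", "k": 6.0, "K_M_nuc": 1.0},
            ],
        },
        "glycans": {
            "composition": {
                "N_linked": {
                    "abundance": 1.41e-11,
                    "counts": {"GlcNAc": 2.896, "GalNAc": 0.0, "Man": 5.813,
                               "Gal": 0.759, "Neu5Ac": 0.516, "Fuc": 0.332},
                },
                "O_linked": {
                    "abundance": 1.31e-11,
                    "counts": {"GlcNAc": 0.156, "GalNAc": 1.0, "Man": 0.0,
                               "Gal": 1.156, "Neu5Ac": 1.543, "Fuc": 0.0},
                },
            },
            "N_gly_mAb": 2,
            "mab_counts": {"GlcNAc": 4.0, "GalNAc": 0.0, "Man": 3.0,
                           "Gal": 0.7, "Neu5Ac": 0.1, "Fuc": 1.0},
            "extra_demand": {"UDP-GlcA": 0.05, "UDP-Xyl": 0.05},
        },
        "network": {
            "species": {"dynamic": species_dynamic,
                        "constant": species_constant,
                        "boundary": species_boundary},
            "reactions": reactions,
            "inhibitions": INHIBITIONS,
            "activations": ACTIVATIONS,
            "hill": HILL,
            "expected": {
                "dynamic_species": 34,
                "measured_species": 7,
                "primary_steps": 35,
                "transports": 9,
                "total_reactions": 69,
                "inhibition_terms": 76,
                "activation_terms": 5,
                "hill_terms": 6,
                "mechanism_census": mech_census,
            },
        },
        "parameters": {
            "provenance": "placeholder",
            "enzymes": enzymes,
            "reactions": rxn_params,
            "transports": {k: dict(v) for k, v in TRANSPORTS.items()},
            "glycolysis": {"E0": E0, "kcat": 2.0e5, "Km": 0.45, "hill_n": 2.0},
        },
        "estimation": {
            "free_parameters": free,
            "bounds_factor": 10.0,
            "transform": "log10",
        },
        "sensitivity": {
            "significance_threshold": 0.036,
            "output_times": [20.0, 40.0, 60.0, 80.0, 120.0],
            "excluded": ["E0:E_glyc"],
        },
    }

    census = dict(mech_census)
    assert census == {"uni_uni": 20, "random_bibi": 7, "ordered_bibi": 14,
                      "pingpong_bibi": 17, "pingpong_terter": 1}, census
    assert len(reactions) == 69, len(reactions)
    assert len(INHIBITIONS) == 76, len(INHIBITIONS)
    assert len(species_dynamic) == 34
    return cfg


if __name__ == "__main__":
    cfg = build()
    OUT.parent.mkdir(parents=True, exist_ok=True)
    with open(OUT, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False, width=100)
    print(f"wrote {OUT}")
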