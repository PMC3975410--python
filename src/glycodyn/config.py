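"""Configuration loading: one YAML/JSON document drives the whole model.

The document has sections ``culture``, ``growth``, ``nucleotides``,
``glycans``, ``network``, ``parameters``, ``estimation`` and
``sensitivity``.  :func:`load_config` returns a :class:`ModelConfig`
bundle of typed objects; :func:`default_config` loads the packaged
default (batch hybridoma culture, placeholder kinetics).
"""

from __future__ import annotations

import copy
import importlib.resources
import json
import pathlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import yaml

from glycodyn.network import NetworkDefinition, load_network
from glycodyn.growth import GrowthParameters, CultureState
from glycodyn.nucleotides import (
    CellComposition,
    NucleotideReaction,
    NucleotideReactionParams,
)
from glycodyn.glycans import (
    GlycanCompositionTable,
    GlycanDemand,
    glycan_demand_from_composition,
)


@dataclass
class ModelConfig:
    """Typed bundle of everything needed to build a coupled model."""

    raw: dict
    network: NetworkDefinition
    growth: GrowthParameters
    culture0: CultureState
    nucleotides0: Dict[str, float]
    nucleotide_reactions: List[NucleotideReaction]
    composition: CellComposition
    glycan_table: GlycanCompositionTable
    demand: GlycanDemand
    parameters: dict
    estimation: dict = field(default_factory=dict)
    sensitivity: dict = field(default_factory=dict)

    def copy(self) -> "ModelConfig":
        return load_config(copy.deepcopy(self.raw))


def _culture_state(doc: dict) -> CultureState:
    ini = doc["culture"]["initial"]
    return CultureState(
        V=float(ini["V"]), X_V=float(ini["Xv"]), X_dead=float(ini.get("Xd", 0.0)),
        Glc_ext=float(ini["Glc_ext"]), Gln_ext=float(ini["Gln_ext"]),
        mAb=float(ini.get("mAb", 0.0)), t=0.0,
    )


def _nucleotide_reactions(doc: dict) -> List[NucleotideReaction]:
    out = []
    for entry in doc["nucleotides"]["reactions"]:
        params = NucleotideReactionParams(
            k=float(entry["k"]),
            K_M_nuc=float(entry.get("K_M_nuc", 1.0)),
            K_M_glc=float(entry.get("K_M_glc", 1.0)),
            K_M_gln=float(entry.get("K_M_gln", 0.3)),
        )
        out.append(NucleotideReaction(
            id=entry["id"], rate_class=entry["rate_class"],
            produces=entry["produces"], consumes=entry.get("consumes"),
            factor_nuc=entry.get("factor_nuc"), params=params,
        ))
    return out


def _glycans(doc: dict):
    g = doc["glycans"]
    counts = {k: dict(v["counts"]) for k, v in g["composition"].items()}
    abund = {k: float(v["abundance"]) for k, v in g["composition"].items()}
    # internal type keys use underscores already in the shipped config
    tbl = GlycanCompositionTable(counts=counts, abundances=abund)
    demand = glycan_demand_from_composition(
        tbl,
        N_gly_mAb=float(g.get("N_gly_mAb", 2.0)),
        mab_counts=g.get("mab_counts"),
        extra_demand=g.get("extra_demand"),
    )
    return tbl, demand


def load_config(source) -> ModelConfig:
    """Load a configuration from a path, a YAML/JSON string or a mapping."""
    if isinstance(source, (str, pathlib.Path)) and "\n" not in str(source):
        text = pathlib.Path(source).read_text()
        doc = yaml.safe_load(text)
    elif isinstance(source, str):
        doc = yaml.safe_load(source)
    else:
        doc = source
    if not isinstance(doc, dict):
        raise ValueError("configuration document must be a mapping")

    for section in ("culture", "growth", "nucleotides", "glycans",
                    "network", "parameters"):
        if section not in doc:
            raise ValueError(f"configuration lacks section {section!r}")

    network = load_network(doc["network"])
    growth = GrowthParameters(**{k: float(v) for k, v in doc["growth"].items()})
    comp_doc = doc["nucleotides"]["composition"]
    composition = CellComposition(
        V_cell=float(comp_doc["V_cell"]),
        m_DNA=float(comp_doc["m_DNA"]), m_RNA=float(comp_doc["m_RNA"]),
        DNA_f=dict(comp_doc["DNA_f"]), RNA_f=dict(comp_doc["RNA_f"]),
        Mr_DNA=float(comp_doc["Mr_DNA"]), Mr_RNA=float(comp_doc["Mr_RNA"]),
        K_TP_nuc=float(comp_doc.get("K_TP_nuc", 0.2)),
    )
    tbl, demand = _glycans(doc)
    return ModelConfig(
        raw=doc,
        network=network,
        growth=growth,
        culture0=_culture_state(doc),
        nucleotides0={k: float(v) for k, v in doc["nucleotides"]["initial"].items()},
        nucleotide_reactions=_nucleotide_reactions(doc),
        composition=composition,
        glycan_table=tbl,
        demand=demand,
        parameters=doc["parameters"],
        estimation=doc.get("estimation", {}),
        sensitivity=doc.get("sensitivity", {}),
    )


def default_config() -> ModelConfig:
    """The packaged default configuration (fresh copy on every call)."""
    text = (
        importlib.resources.files("glycodyn")
        .joinpath("data/default_config.yaml")
        .read_text()
    )
    return load_config(yaml.safe_load(text))


def dump_config(cfg_doc: dict, path) -> None:
    path = pathlib.Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg_doc, indent=2))
    else:
        with open(path, "w") as fh:
            yaml.safe_dump(cfg_doc, fh, sort_keys=False, width=100)
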