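"""Minimal SBML Level 3 export/import of the reaction network.

The writer emits SBML L3v2 core: one compartment, one ``species`` element
per declared species (constant species flagged ``constant="true"``), and
one ``reaction`` per network reaction.  Kinetic metadata (mechanism tag,
kcat, E0, Km) is attached as a structured annotation in the package's own
namespace rather than as MathML, which keeps the document round-trippable
by :func:`import_sbml` without a full math parser.  This is a
self-contained core writer, not a general SBML toolkit.
"""

from __future__ import annotations

import pathlib
import re
import xml.etree.ElementTree as ET
from typing import Dict, Optional

from glycodyn.network import (
    NetworkDefinition,
    ReactionDef,
    SpeciesDef,
    load_network,
)

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
GLY_NS = "https://glycodyn.invalid/ns/kinetics"


class SBMLExportError(ValueError):
    pass


def _sid(raw: str) -> str:
    """SBML ids must match [A-Za-z_][A-Za-z0-9_]*."""
    s = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    if not re.match(r"[A-Za-z_]", s):
        s = "_" + s
    return s


def export_sbml(
    net: NetworkDefinition,
    parameters: Optional[dict] = None,
    path=None,
) -> str:
    """Serialize a network (plus its parameter table) to SBML L3.

    Every enzymatic reaction must be parameterized (kcat + Km per
    substrate under ``parameters['reactions']``); a missing entry raises
    :class:`SBMLExportError` naming the kinetics reference.
    """
    parameters = parameters or {}
    rxn_params = parameters.get("reactions", {})
    enz_params = parameters.get("enzymes", {})

    ET.register_namespace("", SBML_NS)
    ET.register_namespace("gly", GLY_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(root, f"{{{SBML_NS}}}model", {"id": "glycodyn_nsd"})
    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment", {
        "id": "cytosol", "constant": "true", "spatialDimensions": "3",
    })
    species_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for s in net.species:
        attrs = {
            "id": _sid(s.id),
            "name": s.id,
            "compartment": "cytosol",
            "constant": "true" if s.role == "constant" else "false",
            "hasOnlySubstanceUnits": "false",
            "boundaryCondition": "true" if s.role == "boundary" else "false",
        }
        if s.initial_concentration is not None:
            attrs["initialConcentration"] = repr(float(s.initial_concentration))
        el = ET.SubElement(species_el, f"{{{SBML_NS}}}species", attrs)
        ann = ET.SubElement(el, f"{{{SBML_NS}}}annotation")
        ET.SubElement(ann, f"{{{GLY_NS}}}speciesInfo", {
            "role": s.role, "measured": str(s.measured).lower(),
        })

    rxns_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    enzymatic = {"uni_uni", "random_bibi", "ordered_bibi",
                 "pingpong_bibi", "pingpong_terter"}
    for r in net.reactions:
        if r.mechanism in enzymatic and r.id not in rxn_params:
            raise SBMLExportError(
                f"reaction {r.id}: no kinetic parameters for "
                f"kinetics_ref {r.kinetics_ref!r}"
            )
        el = ET.SubElement(rxns_el, f"{{{SBML_NS}}}reaction", {
            "id": _sid(r.id), "name": r.id, "reversible": "false",
        })
        ann = ET.SubElement(el, f"{{{SBML_NS}}}annotation")
        kin_attrs = {"mechanism": r.mechanism, "role": r.role,
                     "kineticsRef": r.kinetics_ref}
        if r.reversible_partner:
            kin_attrs["reversiblePartner"] = r.reversible_partner
        if r.id in rxn_params:
            kin_attrs["kcat"] = repr(float(rxn_params[r.id]["kcat"]))
            if r.kinetics_ref in enz_params:
                kin_attrs["E0"] = repr(float(enz_params[r.kinetics_ref]["E0"]))
        kin = ET.SubElement(ann, f"{{{GLY_NS}}}kinetics", kin_attrs)
        if r.id in rxn_params:
            for sp, km in rxn_params[r.id].get("Km", {}).items():
                ET.SubElement(kin, f"{{{GLY_NS}}}km",
                              {"species": sp, "value": repr(float(km))})
        if r.substrates:
            lor = ET.SubElement(el, f"{{{SBML_NS}}}listOfReactants")
            for sp in r.substrates:
                ET.SubElement(lor, f"{{{SBML_NS}}}speciesReference", {
                    "species": _sid(sp), "stoichiometry": "1", "constant": "true",
                })
        if r.products:
            lop = ET.SubElement(el, f"{{{SBML_NS}}}listOfProducts")
            for sp in r.products:
                ET.SubElement(lop, f"{{{SBML_NS}}}speciesReference", {
                    "species": _sid(sp), "stoichiometry": "1", "constant": "true",
                })

    ET.indent(root)
    text = ET.tostring(root, encoding="unicode", xml_declaration=True)
    if path is not None:
        pathlib.Path(path).write_text(text)
    return text


def import_sbml(source) -> NetworkDefinition:
    """Rebuild a :class:`NetworkDefinition` from an SBML export.

    Only documents produced by :func:`export_sbml` are supported (the
    mechanism tags live in the package annotation namespace).  Inhibition,
    activation and Hill metadata are not serialized, so the round trip
    preserves the species/reaction structure, not the modifier terms.
    """
    text = source
    p = pathlib.Path(str(source))
    if "\n" not in str(source) and p.exists():
        text = p.read_text()
    root = ET.fromstring(text)
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        raise ValueError("no <model> element found")

    doc: Dict[str, object] = {
        "species": {"dynamic": [], "constant": [], "boundary": []},
        "reactions": [],
    }
    for el in model.iter(f"{{{SBML_NS}}}species"):
        name = el.get("name", el.get("id"))
        info = el.find(f".//{{{GLY_NS}}}speciesInfo")
        role = info.get("role") if info is not None else (
            "constant" if el.get("constant") == "true" else "dynamic"
        )
        entry = {"id": name}
        if el.get("initialConcentration") is not None:
            entry["initial"] = float(el.get("initialConcentration"))
        if info is not None and info.get("measured") == "true":
            entry["measured"] = True
        doc["species"][role].append(entry)

    for el in model.iter(f"{{{SBML_NS}}}reaction"):
        name = el.get("name", el.get("id"))
        kin = el.find(f".//{{{GLY_NS}}}kinetics")
        if kin is None:
            raise ValueError(f"reaction {name}: missing kinetics annotation")
        subs = [sr.get("species") for sr in el.findall(
            f"{{{SBML_NS}}}listOfReactants/{{{SBML_NS}}}speciesReference")]
        prods = [sr.get("species") for sr in el.findall(
            f"{{{SBML_NS}}}listOfProducts/{{{SBML_NS}}}speciesReference")]
        sid_to_name = {}
        for lst in doc["species"].values():
            for entry in lst:
                sid_to_name[_sid(entry["id"])] = entry["id"]
        entry = {
            "id": name,
            "mechanism": kin.get("mechanism"),
            "substrates": [sid_to_name[s] for s in subs],
            "products": [sid_to_name[s] for s in prods],
            "kinetics_ref": kin.get("kineticsRef", name),
            "role": kin.get("role", "primary"),
        }
        if kin.get("reversiblePartner"):
            entry["reversible_partner"] = kin.get("reversiblePartner")
        doc["reactions"].append(entry)
    return load_network(doc)
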