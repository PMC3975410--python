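"""Declarative definition and validation of the NSD reaction network.

The network is described in a YAML/JSON configuration with sections
``species`` (dynamic and constant), ``reactions``, ``inhibitions``,
``activations`` and ``hill``.  Reactions are mechanism-tagged; enzymatic
mechanisms are those of :mod:`glycodyn.rates` plus the pseudo-mechanisms
``transport`` (Golgi/ER export of one NSD) and ``glycolysis_outlet`` (the
lumped phosphofructokinase sink).

The shipped default network comprises 34 dynamic sugar/nucleotide-sugar
species and 69 distinct simulated reactions: 35 primary enzymatic steps,
24 reverse/parallel enzymatic reactions, 9 transports and the glycolysis
outlet, with a mechanism census of 20 uni-uni, 7 random-order bi-bi,
14 ordered bi-bi, 17 ping-pong bi-bi and 1 ping-pong ter-ter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import yaml

from glycodyn.rates import MECHANISMS, MECHANISM_ARITY, INHIBITION_TYPES

PSEUDO_MECHANISMS = ("transport", "glycolysis_outlet")
ALL_MECHANISMS = MECHANISMS + PSEUDO_MECHANISMS

ROLES = ("primary", "reverse", "parallel", "transport", "outlet")


class NetworkLoadError(ValueError):
    """Raised when a network document cannot be turned into a valid object."""


@dataclass
class SpeciesDef:
    id: str
    name: str = ""
    role: str = "dynamic"  # dynamic | constant | boundary
    initial_concentration: Optional[float] = None  # mM; None = to-be-initialized
    measured: bool = False

    def __post_init__(self) -> None:
        if self.role not in ("dynamic", "constant", "boundary"):
            raise NetworkLoadError(f"species {self.id}: unknown role {self.role!r}")
        if self.role == "constant" and self.initial_concentration is None:
            raise NetworkLoadError(
                f"species {self.id}: constant species need a fixed concentration"
            )


@dataclass
class ReactionDef:
    id: str
    mechanism: str
    substrates: List[str]
    products: List[str]
    kinetics_ref: str
    role: str = "primary"
    reversible_partner: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mechanism not in ALL_MECHANISMS:
            raise NetworkLoadError(
                f"reaction {self.id}: unknown mechanism {self.mechanism!r}"
            )
        if self.role not in ROLES:
            raise NetworkLoadError(f"reaction {self.id}: unknown role {self.role!r}")
        if self.mechanism in MECHANISM_ARITY:
            arity = MECHANISM_ARITY[self.mechanism]
            if len(self.substrates) != arity:
                raise NetworkLoadError(
                    f"reaction {self.id}: mechanism {self.mechanism} expects "
                    f"{arity} substrate(s), got {len(self.substrates)}"
                )
        elif self.mechanism in PSEUDO_MECHANISMS and len(self.substrates) != 1:
            raise NetworkLoadError(
                f"reaction {self.id}: {self.mechanism} expects exactly one substrate"
            )


@dataclass
class InhibitionTerm:
    reaction_id: str
    inhibitor_species: str
    type: str
    K_i: float
    target_substrate: Optional[str] = None

    def __post_init__(self) -> None:
        if self.type not in INHIBITION_TYPES:
            raise NetworkLoadError(
                f"inhibition on {self.reaction_id}: unknown type {self.type!r}"
            )
        if self.K_i <= 0:
            raise NetworkLoadError(
                f"inhibition on {self.reaction_id}: K_i must be > 0"
            )


@dataclass
class ActivationTerm:
    reaction_id: str
    activator_species: str
    K_A: float

    def __post_init__(self) -> None:
        if self.K_A <= 0:
            raise NetworkLoadError(
                f"activation on {self.reaction_id}: K_A must be > 0"
            )


@dataclass
class NetworkDefinition:
    species: List[SpeciesDef]
    reactions: List[ReactionDef]
    inhibitions: List[InhibitionTerm] = field(default_factory=list)
    activations: List[ActivationTerm] = field(default_factory=list)
    hill_terms: Dict[str, Tuple[str, float]] = field(default_factory=dict)
    expected_counts: Dict[str, object] = field(default_factory=dict)

    # -- convenience views -------------------------------------------------
    @property
    def dynamic_species(self) -> List[SpeciesDef]:
        return [s for s in self.species if s.role == "dynamic"]

    @property
    def constant_species(self) -> List[SpeciesDef]:
        return [s for s in self.species if s.role == "constant"]

    @property
    def measured_species(self) -> List[SpeciesDef]:
        return [s for s in self.species if s.role == "dynamic" and s.measured]

    def reaction(self, rid: str) -> ReactionDef:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)


@dataclass
class ValidationReport:
    n_dynamic_species: int
    n_constant_species: int
    n_measured: int
    mechanism_census: Dict[str, int]
    n_primary: int
    n_reverse_parallel: int
    n_transports: int
    n_outlets: int
    n_total_reactions: int
    n_inhibitions: int
    n_activations: int
    n_hill: int
    violations: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _require(doc: dict, key: str) -> object:
    if key not in doc:
        raise NetworkLoadError(f"network document lacks section {key!r}")
    return doc[key]


def load_network(config_document) -> NetworkDefinition:
    """Build a fully linked :class:`NetworkDefinition` from a document.

    ``config_document`` may be a YAML string or an already parsed mapping
    (the ``network`` section of the package configuration).  All species
    referenced by reactions, inhibitions, activations and Hill terms must
    be declared; duplicate ids and unknown mechanism tags are load errors
    and no partial object is returned.
    """
    if isinstance(config_document, str):
        doc = yaml.safe_load(config_document)
    else:
        doc = config_document
    if not isinstance(doc, dict) or not doc:
        raise NetworkLoadError("empty or non-mapping network document")

    species: List[SpeciesDef] = []
    seen = set()
    spec_section = _require(doc, "species")
    for role_key, role in (
        ("dynamic", "dynamic"),
        ("constant", "constant"),
        ("boundary", "boundary"),
    ):
        for entry in spec_section.get(role_key, []):
            s = SpeciesDef(
                id=entry["id"],
                name=entry.get("name", entry["id"]),
                role=role,
                initial_concentration=entry.get("initial"),
                measured=bool(entry.get("measured", False)),
            )
            if s.id in seen:
                raise NetworkLoadError(f"duplicate species id {s.id!r}")
            seen.add(s.id)
            species.append(s)
    known = seen

    reactions: List[ReactionDef] = []
    rids = set()
    for entry in _require(doc, "reactions"):
        r = ReactionDef(
            id=entry["id"],
            mechanism=entry["mechanism"],
            substrates=list(entry.get("substrates", [])),
            products=list(entry.get("products", [])),
            kinetics_ref=entry.get("kinetics_ref", entry["id"]),
            role=entry.get("role", "primary"),
            reversible_partner=entry.get("reversible_partner"),
        )
        if r.id in rids:
            raise NetworkLoadError(f"duplicate reaction id {r.id!r}")
        rids.add(r.id)
        for sp in list(r.substrates) + list(r.products):
            if sp not in known:
                raise NetworkLoadError(
                    f"reaction {r.id}: references undeclared species {sp!r}"
                )
        reactions.append(r)
    for r in reactions:
        if r.reversible_partner is not None and r.reversible_partner not in rids:
            raise NetworkLoadError(
                f"reaction {r.id}: unknown reversible partner "
                f"{r.reversible_partner!r}"
            )

    inhibitions: List[InhibitionTerm] = []
    for entry in doc.get("inhibitions", []):
        term = InhibitionTerm(
            reaction_id=entry["reaction"],
            inhibitor_species=entry["inhibitor"],
            type=entry["type"],
            K_i=float(entry["K_i"]),
            target_substrate=entry.get("target"),
        )
        if term.reaction_id not in rids:
            raise NetworkLoadError(
                f"inhibition references unknown reaction {term.reaction_id!r}"
            )
        if term.inhibitor_species not in known:
            raise NetworkLoadError(
                f"inhibition on {term.reaction_id}: undeclared species "
                f"{term.inhibitor_species!r}"
            )
        inhibitions.append(term)

    activations: List[ActivationTerm] = []
    for entry in doc.get("activations", []):
        term = ActivationTerm(
            reaction_id=entry["reaction"],
            activator_species=entry["activator"],
            K_A=float(entry["K_A"]),
        )
        if term.reaction_id not in rids:
            raise NetworkLoadError(
                f"activation references unknown reaction {term.reaction_id!r}"
            )
        if term.activator_species not in known:
            raise NetworkLoadError(
                f"activation on {term.reaction_id}: undeclared species "
                f"{term.activator_species!r}"
            )
        activations.append(term)

    hill: Dict[str, Tuple[str, float]] = {}
    for rid, entry in doc.get("hill", {}).items():
        if rid not in rids:
            raise NetworkLoadError(f"Hill term references unknown reaction {rid!r}")
        sp, n = entry["species"], float(entry["n"])
        if sp not in known:
            raise NetworkLoadError(
                f"Hill term on {rid}: undeclared species {sp!r}"
            )
        if n < 1:
            raise NetworkLoadError(f"Hill term on {rid}: exponent must be >= 1")
        hill[rid] = (sp, n)

    return NetworkDefinition(
        species=species,
        reactions=reactions,
        inhibitions=inhibitions,
        activations=activations,
        hill_terms=hill,
        expected_counts=dict(doc.get("expected", {})),
    )


def validate_network(
    net: NetworkDefinition,
    expected: Optional[Dict[str, object]] = None,
) -> ValidationReport:
    """Structural census of a loaded network plus expectation checks.

    The report always carries the observed counts; violations are
    appended when counts differ from the declared expectations (either
    passed explicitly or shipped in the config's ``expected`` section) or
    when a dynamic species participates in no reaction.
    """
    census = {m: 0 for m in MECHANISMS}
    n_primary = n_revpar = n_transports = n_outlets = 0
    for r in net.reactions:
        if r.mechanism in census:
            census[r.mechanism] += 1
        if r.role == "primary":
            n_primary += 1
        elif r.role in ("reverse", "parallel"):
            n_revpar += 1
        elif r.role == "transport":
            n_transports += 1
        elif r.role == "outlet":
            n_outlets += 1

    report = ValidationReport(
        n_dynamic_species=len(net.dynamic_species),
        n_constant_species=len(net.constant_species),
        n_measured=len(net.measured_species),
        mechanism_census=census,
        n_primary=n_primary,
        n_reverse_parallel=n_revpar,
        n_transports=n_transports,
        n_outlets=n_outlets,
        n_total_reactions=len(net.reactions),
        n_inhibitions=len(net.inhibitions),
        n_activations=len(net.activations),
        n_hill=len(net.hill_terms),
    )

    used = set()
    for r in net.reactions:
        used.update(r.substrates)
        used.update(r.products)
    for s in net.dynamic_species:
        if s.id not in used:
            report.violations.append(f"orphan dynamic species {s.id!r}")

    exp = dict(net.expected_counts)
    if expected:
        exp.update(expected)
    checks = {
        "dynamic_species": report.n_dynamic_species,
        "measured_species": report.n_measured,
        "primary_steps": report.n_primary,
        "transports": report.n_transports,
        "total_reactions": report.n_total_reactions,
        "inhibition_terms": report.n_inhibitions,
        "activation_terms": report.n_activations,
        "hill_terms": report.n_hill,
    }
    for key, observed in checks.items():
        if key in exp and exp[key] != observed:
            report.violations.append(
                f"{key}: expected {exp[key]}, observed {observed}"
            )
    if "mechanism_census" in exp:
        for mech, want in exp["mechanism_census"].items():
            got = census.get(mech, 0)
            if got != want:
                report.violations.append(
                    f"mechanism {mech}: expected {want}, observed {got}"
                )
    return report
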