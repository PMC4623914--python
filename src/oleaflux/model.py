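"""Core data structures for stoichiometric (genome-scale) metabolic models.

The in-memory representation is deliberately plain: metabolites, reactions
with signed stoichiometries and flux bounds, boolean gene-protein-reaction
rules, an objective, and optional flux-coupling constraints (linear ratios
between two fluxes, used e.g. to tie non-growth maintenance ATP hydrolysis to
substrate uptake).  Units follow COBRA convention: fluxes in
mmol gDW^-1 h^-1, the biomass pseudo-reaction in h^-1.

Sign convention: for exchange reactions a negative flux is uptake and a
positive flux is secretion.  User-facing helpers take uptake magnitudes as
positive numbers and convert internally.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

DEFAULT_BOUND = 1000.0

#: Reaction categories.  "exchange" reactions connect a single species to the
#: environment, "transport" reactions move species between compartments
#: without chemical change, "pseudo" reactions (biomass, maintenance, demand)
#: have no physical stoichiometry, everything else is "enzymatic".
REACTION_KINDS = ("exchange", "transport", "enzymatic", "pseudo")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


class ModelError(ValueError):
    """Structural problem in a model or an operation on it."""


def parse_formula(formula: str) -> dict[str, float]:
    """Parse an elemental formula string into an element -> count map.

    Accepts conventional formulas (``C6H12O6``) as well as carrier
    pseudo-elements used by lumped models (single uppercase letters).
    """
    if not formula:
        return {}
    counts: dict[str, float] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ModelError(f"cannot parse formula {formula!r}")
        pos = match.end()
        element, num = match.groups()
        counts[element] = counts.get(element, 0.0) + (float(num) if num else 1.0)
    if pos != len(formula):
        raise ModelError(f"cannot parse formula {formula!r}")
    return counts


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None
    boundary: bool = False  # boundary-condition species, excluded from S

    def elements(self) -> dict[str, float]:
        return parse_formula(self.formula or "")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gene_rule: str = ""
    name: str = ""
    subsystem: str = ""
    kind: str | None = None  # one of REACTION_KINDS, or None = classify

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def genes(self) -> set[str]:
        return gene_rule_genes(self.gene_rule)


@dataclass
class FluxCoupling:
    """Linear coupling v_target = ratio * v_source, enforced in every solve."""

    target_reaction: str
    source_reaction: str
    ratio: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.ratio):
            raise ModelError("coupling ratio must be finite")
        if self.target_reaction == self.source_reaction:
            raise ModelError("cannot couple a reaction to itself")


@dataclass
class ModelSummary:
    n_reactions: int
    n_metabolites: int
    n_genes: int
    n_compartments: int
    n_exchange: int
    n_transport: int
    n_enzymatic_with_gpr: int
    n_enzymatic_without_gpr: int
    n_pseudo: int
    n_subsystems: int

    def fractions(self) -> dict[str, float]:
        total = self.n_reactions or 1
        return {
            "exchange": self.n_exchange / total,
            "transport": self.n_transport / total,
            "enzymatic_with_gpr": self.n_enzymatic_with_gpr / total,
            "enzymatic_without_gpr": self.n_enzymatic_without_gpr / total,
            "pseudo": self.n_pseudo / total,
        }

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["fractions"] = self.fractions()
        return d


_RULE_SPLIT = re.compile(r"[\s()]+")
_RULE_KEYWORDS = {"and", "or", "AND", "OR", "And", "Or", ""}


def gene_rule_genes(rule: str) -> set[str]:
    return {tok for tok in _RULE_SPLIT.split(rule) if tok not in _RULE_KEYWORDS}


class MetabolicModel:
    """A stoichiometric network with bounds, objective and couplings."""

    def __init__(
        self,
        model_id: str = "model",
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        compartments: Mapping[str, str] | None = None,
        objective: Mapping[str, float] | None = None,
        couplings: Iterable[FluxCoupling] = (),
        external_compartment: str = "e",
        name: str = "",
    ) -> None:
        self.id = model_id
        self.name = name or model_id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.compartments: dict[str, str] = dict(compartments or {})
        self.objective: dict[str, float] = dict(objective or {})
        self.couplings: list[FluxCoupling] = list(couplings)
        self.external_compartment = external_compartment
        for met in metabolites:
            self.add_metabolite(met)
        for rxn in reactions:
            self.add_reaction(rxn)

    # -- construction -----------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met
        self.compartments.setdefault(met.compartment, met.compartment)

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise ModelError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
        self.reactions[rxn.id] = rxn

    def remove_reaction(self, rxn_id: str, drop_orphans: bool = False) -> None:
        rxn = self.reactions.pop(rxn_id, None)
        if rxn is None:
            raise ModelError(f"unknown reaction {rxn_id!r}")
        self.objective.pop(rxn_id, None)
        self.couplings = [
            c
            for c in self.couplings
            if rxn_id not in (c.target_reaction, c.source_reaction)
        ]
        if drop_orphans:
            used = {m for r in self.reactions.values() for m in r.stoichiometry}
            for met_id in list(rxn.stoichiometry):
                if met_id not in used:
                    del self.metabolites[met_id]

    # -- views -------------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.genes()
        return sorted(out)

    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    def internal_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if not m.boundary]

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S with one row per non-boundary metabolite, one column per
        reaction.  Returns (S, metabolite_ids, reaction_ids)."""
        met_ids = self.internal_metabolite_ids()
        rxn_ids = self.reaction_ids()
        row = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for met_id, coef in self.reactions[rid].stoichiometry.items():
                i = row.get(met_id)
                if i is not None:
                    S[i, j] = coef
        return S, met_ids, rxn_ids

    def classify_reaction(self, rxn: Reaction) -> str:
        """Operational reaction-kind classification.

        exchange: touches exactly one non-boundary species (the rest, if any,
        being boundary species) and that species sits in the external
        compartment, or the reaction has a single participant overall.
        transport: participants span >= 2 compartments with no change in
        elemental composition.  pseudo: flagged explicitly (biomass,
        maintenance, demand).  Everything else: enzymatic.
        """
        if rxn.kind in REACTION_KINDS:
            return rxn.kind
        internal = [
            self.metabolites[m]
            for m in rxn.stoichiometry
            if not self.metabolites[m].boundary
        ]
        if len(internal) <= 1:
            return "exchange"
        comps = {m.compartment for m in internal}
        if len(comps) >= 2:
            net: dict[str, float] = {}
            known_formulas = all(m.formula for m in internal)
            if known_formulas:
                for m in internal:
                    coef = rxn.stoichiometry[m.id]
                    for el, n in m.elements().items():
                        net[el] = net.get(el, 0.0) + coef * n
                if all(abs(v) < 1e-9 for v in net.values()):
                    return "transport"
            else:
                # without formulas, fall back on id stems: a pure transport
                # moves the same species name between compartments
                stems = {m.id.rsplit("_", 1)[0] for m in internal}
                if len(stems) < len(internal):
                    return "transport"
        return "enzymatic"

    def exchange_reaction_ids(self) -> list[str]:
        return [
            rid
            for rid, rxn in self.reactions.items()
            if self.classify_reaction(rxn) == "exchange"
        ]

    # -- mutation helpers --------------------------------------------------

    def set_bounds(self, rxn_id: str, lower: float, upper: float) -> None:
        rxn = self.reactions.get(rxn_id)
        if rxn is None:
            raise ModelError(f"unknown reaction {rxn_id!r}")
        if lower > upper:
            raise ModelError(f"bounds reversed for {rxn_id}: {lower} > {upper}")
        rxn.lower_bound = float(lower)
        rxn.upper_bound = float(upper)

    def set_uptake(self, exchange_id: str, rate: float, fixed: bool = False) -> None:
        """Allow uptake through an exchange up to ``rate`` (positive number).

        With ``fixed=True`` the uptake is pinned to exactly ``rate``.
        """
        if rate < 0:
            raise ModelError("uptake rate must be a non-negative magnitude")
        rxn = self.reactions.get(exchange_id)
        if rxn is None:
            raise ModelError(f"unknown exchange reaction {exchange_id!r}")
        upper = -rate if fixed else max(rxn.upper_bound, 0.0)
        rxn.lower_bound = -rate
        rxn.upper_bound = upper

    def set_objective(self, objective: Mapping[str, float] | str) -> None:
        if isinstance(objective, str):
            objective = {objective: 1.0}
        for rid in objective:
            if rid not in self.reactions:
                raise ModelError(f"objective reaction {rid!r} not in model")
        self.objective = dict(objective)

    def add_coupling(self, coupling: FluxCoupling) -> None:
        for rid in (coupling.target_reaction, coupling.source_reaction):
            if rid not in self.reactions:
                raise ModelError(f"coupling references unknown reaction {rid!r}")
        self.couplings.append(coupling)

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    # -- validation & balance ---------------------------------------------

    def validate(self) -> None:
        for rxn in self.reactions.values():
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelError(f"reaction {rxn.id}: reversed bounds")
        for rid in self.objective:
            if rid not in self.reactions:
                raise ModelError(f"objective reaction {rid!r} missing")
        for c in self.couplings:
            if c.target_reaction not in self.reactions:
                raise ModelError(f"coupling target {c.target_reaction!r} missing")
            if c.source_reaction not in self.reactions:
                raise ModelError(f"coupling source {c.source_reaction!r} missing")

    def mass_balance(
        self, rxn_id: str, elements: Iterable[str] | None = None
    ) -> dict[str, float]:
        """Net element production of a reaction (empty dict = balanced).

        Only metabolites with formulas contribute; if any participant lacks a
        formula the check is skipped (returns {}), since balance is then
        undecidable (advisory behaviour for models with incomplete formulas).
        """
        rxn = self.reactions[rxn_id]
        mets = [self.metabolites[m] for m in rxn.stoichiometry]
        if any(m.formula is None for m in mets):
            return {}
        net: dict[str, float] = {}
        for m in mets:
            coef = rxn.stoichiometry[m.id]
            for el, n in m.elements().items():
                net[el] = net.get(el, 0.0) + coef * n
        keep = set(elements) if elements is not None else set(net)
        return {el: v for el, v in net.items() if el in keep and abs(v) > 1e-9}

    # -- serialization (JSON debug dump) ------------------------------------

    def to_json(self) -> str:
        payload = {
            "id": self.id,
            "name": self.name,
            "compartments": self.compartments,
            "external_compartment": self.external_compartment,
            "metabolites": [vars(m) for m in self.metabolites.values()],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name,
                    "stoichiometry": r.stoichiometry,
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    "gene_rule": r.gene_rule,
                    "subsystem": r.subsystem,
                    "kind": r.kind,
                }
                for r in self.reactions.values()
            ],
            "objective": self.objective,
            "couplings": [vars(c) for c in self.couplings],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MetabolicModel":
        data = json.loads(text)
        model = cls(
            model_id=data["id"],
            name=data.get("name", ""),
            compartments=data.get("compartments"),
            external_compartment=data.get("external_compartment", "e"),
        )
        for m in data["metabolites"]:
            model.add_metabolite(Metabolite(**m))
        for r in data["reactions"]:
            model.add_reaction(Reaction(**r))
        model.objective = dict(data.get("objective", {}))
        for c in data.get("couplings", []):
            model.add_coupling(FluxCoupling(**c))
        return model

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicModel {self.id}: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites>"
        )


def summarize(model: MetabolicModel) -> ModelSummary:
    """Count reactions by category, genes, compartments and subsystems."""
    n_ex = n_tr = n_enz_gpr = n_enz_nogpr = n_pseudo = 0
    for rxn in model.reactions.values():
        kind = model.classify_reaction(rxn)
        if kind == "exchange":
            n_ex += 1
        elif kind == "transport":
            n_tr += 1
        elif kind == "pseudo":
            n_pseudo += 1
        elif rxn.gene_rule.strip():
            n_enz_gpr += 1
        else:
            n_enz_nogpr += 1
    subsystems = {r.subsystem for r in model.reactions.values() if r.subsystem}
    return ModelSummary(
        n_reactions=len(model.reactions),
        n_metabolites=len(model.internal_metabolite_ids()),
        n_genes=len(model.genes),
        n_compartments=len(model.compartments),
        n_exchange=n_ex,
        n_transport=n_tr,
        n_enzymatic_with_gpr=n_enz_gpr,
        n_enzymatic_without_gpr=n_enz_nogpr,
        n_pseudo=n_pseudo,
        n_subsystems=len(subsystems),
    )
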