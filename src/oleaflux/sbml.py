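"""SBML Level 2 reading and writing in the COBRA-toolbox dialect.

Genome-scale models of the COBRA-toolbox era store flux bounds and objective
coefficients as LOCAL parameters of a dummy kinetic law (``LOWER_BOUND``,
``UPPER_BOUND``, ``OBJECTIVE_COEFFICIENT``, ``FLUX_VALUE``) and gene rules /
subsystems in the reaction notes (``GENE_ASSOCIATION: ...``,
``SUBSYSTEM: ...``).  Both that dialect and plain annotation-free L2 files
are accepted; the writer always emits the kinetic-law dialect so that a
read/write round trip is lossless.

Boundary species (``boundaryCondition="true"``) are kept on the metabolite
list but excluded from the stoichiometric matrix rows.
"""

from __future__ import annotations

import re
from pathlib import Path

import libsbml

from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, ModelError, Reaction

_NOTE_FIELD = re.compile(
    r"(GENE[ _]?ASSOCIATION|SUBSYSTEM|FORMULA|CHARGE|KIND)\s*:\s*([^<]*)"
)


class SBMLError(ModelError):
    """Raised on an unreadable or structurally invalid SBML document."""


def _notes_fields(notes: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    for key, value in _NOTE_FIELD.findall(notes or ""):
        fields[key.replace(" ", "_").upper()] = value.strip()
    return fields


def read_sbml(path: str | Path) -> MetabolicModel:
    """Read an SBML L2 file into a :class:`MetabolicModel`.

    Missing bounds default to (-1000, 1000) for reversible reactions and
    (0, 1000) for irreversible ones.
    """
    path = Path(path)
    if not path.exists():
        raise SBMLError(f"SBML file not found: {path}")
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLError(
            f"SBML parse failure in {path.name} at line "
            f"{err.getLine()}: {err.getMessage().strip()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLError(f"{path.name}: document contains no <model> element")

    compartments = {
        c.getId(): (c.getName() or c.getId())
        for c in sbml_model.getListOfCompartments()
    }
    # heuristically mark the external compartment
    external = "e"
    for cid, cname in compartments.items():
        if cid in ("e", "ext", "extracellular") or "extra" in cname.lower():
            external = cid
            break

    model = MetabolicModel(
        model_id=sbml_model.getId() or path.stem,
        name=sbml_model.getName() or "",
        compartments=compartments,
        external_compartment=external,
    )

    for sp in sbml_model.getListOfSpecies():
        notes = _notes_fields(sp.getNotesString() if sp.isSetNotes() else "")
        charge = None
        if sp.isSetCharge():
            charge = sp.getCharge()
        elif "CHARGE" in notes:
            try:
                charge = int(float(notes["CHARGE"]))
            except ValueError:
                charge = None
        model.add_metabolite(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
                formula=notes.get("FORMULA") or None,
                charge=charge,
                boundary=bool(sp.getBoundaryCondition()),
            )
        )

    objective: dict[str, float] = {}
    for rx in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for sr in rx.getListOfReactants():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for sr in rx.getListOfProducts():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()

        reversible = rx.getReversible()
        lb = -DEFAULT_BOUND if reversible else 0.0
        ub = DEFAULT_BOUND
        obj = 0.0
        kl = rx.getKineticLaw()
        if kl is not None:
            for i in range(kl.getNumParameters()):
                p = kl.getParameter(i)
                pid = p.getId().upper()
                if pid == "LOWER_BOUND":
                    lb = p.getValue()
                elif pid == "UPPER_BOUND":
                    ub = p.getValue()
                elif pid == "OBJECTIVE_COEFFICIENT":
                    obj = p.getValue()
        notes = _notes_fields(rx.getNotesString() if rx.isSetNotes() else "")
        try:
            model.add_reaction(
                Reaction(
                    id=rx.getId(),
                    name=rx.getName() or "",
                    stoichiometry=stoich,
                    lower_bound=lb,
                    upper_bound=ub,
                    gene_rule=notes.get("GENE_ASSOCIATION", ""),
                    subsystem=notes.get("SUBSYSTEM", ""),
                    kind=notes.get("KIND") or None,
                )
            )
        except ModelError as exc:
            raise SBMLError(f"{path.name}: invalid reaction {rx.getId()!r}: {exc}")
        if obj:
            objective[rx.getId()] = obj
    model.objective = objective
    model.validate()
    return model


def _set_notes(element, fields: dict[str, str]) -> None:
    lines = "".join(
        f"<p>{key}: {value}</p>" for key, value in fields.items() if value
    )
    if lines:
        element.setNotes(
            f'<body xmlns="http://www.w3.org/1999/xhtml">{lines}</body>'
        )


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write a model as SBML L2v4 with COBRA kinetic-law bounds."""
    doc = libsbml.SBMLDocument(2, 4)
    sm = doc.createModel()
    sm.setId(model.id)
    if model.name:
        sm.setName(model.name)

    for cid, cname in model.compartments.items():
        comp = sm.createCompartment()
        comp.setId(cid)
        comp.setName(cname)
        comp.setSize(1.0)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setBoundaryCondition(met.boundary)
        sp.setInitialConcentration(0.0)
        if met.charge is not None:
            sp.setCharge(int(met.charge))
        fields = {}
        if met.formula:
            fields["FORMULA"] = met.formula
        _set_notes(sp, fields)

    for rxn in model.reactions.values():
        rx = sm.createReaction()
        rx.setId(rxn.id)
        rx.setName(rxn.name or rxn.id)
        rx.setReversible(rxn.lower_bound < 0)
        rx.setFast(False)
        for met_id, coef in rxn.stoichiometry.items():
            sr = rx.createReactant() if coef < 0 else rx.createProduct()
            sr.setSpecies(met_id)
            sr.setStoichiometry(abs(float(coef)))
        _set_notes(
            rx,
            {
                "GENE_ASSOCIATION": rxn.gene_rule,
                "SUBSYSTEM": rxn.subsystem,
                "KIND": rxn.kind or "",
            },
        )
        kl = rx.createKineticLaw()
        kl.setFormula("FLUX_VALUE")
        for pid, value in (
            ("LOWER_BOUND", rxn.lower_bound),
            ("UPPER_BOUND", rxn.upper_bound),
            ("OBJECTIVE_COEFFICIENT", model.objective.get(rxn.id, 0.0)),
            ("FLUX_VALUE", 0.0),
        ):
            p = kl.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setUnits("mmol_per_gDW_per_hr")

    libsbml.writeSBMLToFile(doc, str(path))
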