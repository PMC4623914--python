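"""Declarative network edits.

Species-specific model curation (deleting invertase, closing the ethanol
exporter, adding the mannitol-cycle reactions or a cytosolic malic enzyme)
is expressed as a list of edit directives that can also be loaded from a
YAML/JSON file, so curation is reviewable data rather than code.

Supported directives (``op`` key):

- ``add_reaction``: id, stoichiometry {met: coef}, optional bounds,
  gene_rule, subsystem, kind, and ``new_metabolites`` (list of metabolite
  dicts) for species not yet in the model.
- ``remove_reaction``: id, optional drop_orphans flag.
- ``set_bounds``: id, lower, upper.
- ``set_objective``: objective {rxn: weight} or reaction id string.
- ``add_coupling``: target, source, ratio.

``apply_edits`` never mutates its input; it returns an edited copy.
Enzymatic additions are checked for elemental balance when all participant
formulas are known (exchange/transport/pseudo additions are exempt); the
check is advisory (a warning) when any formula is missing.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import yaml

from .model import FluxCoupling, MetabolicModel, Metabolite, ModelError, Reaction

BALANCE_EXEMPT_KINDS = {"exchange", "pseudo"}


class EditError(ModelError):
    """An edit directive could not be applied."""


def load_edits(path: str | Path) -> list[dict]:
    """Load a list of edit directives from a YAML (or JSON) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, Mapping) and "edits" in data:
        data = data["edits"]
    if not isinstance(data, Sequence):
        raise EditError("edit file must contain a list of directives")
    return list(data)


def _check_balance(model: MetabolicModel, rxn_id: str, elements=None) -> None:
    imbalance = model.mass_balance(rxn_id, elements=elements)
    if imbalance:
        detail = ", ".join(f"{el}: {v:+g}" for el, v in sorted(imbalance.items()))
        raise EditError(
            f"added reaction {rxn_id!r} is elementally unbalanced ({detail})"
        )


def apply_edits(
    model: MetabolicModel,
    edits: Iterable[Mapping[str, Any]],
    balance_elements: Sequence[str] | None = None,
) -> MetabolicModel:
    """Apply edit directives to a copy of ``model`` and return it.

    ``balance_elements`` restricts the elemental-balance check on added
    enzymatic reactions to a subset of elements (e.g. ``["C", "N"]`` for
    models whose H/O bookkeeping is lumped); ``None`` checks every element
    present in the participant formulas.
    """
    edited = model.copy()
    for directive in edits:
        op = directive.get("op")
        if op == "add_reaction":
            for met in directive.get("new_metabolites", []):
                if met["id"] not in edited.metabolites:
                    edited.add_metabolite(Metabolite(**met))
            rxn = Reaction(
                id=directive["id"],
                stoichiometry={k: float(v) for k, v in directive["stoichiometry"].items()},
                lower_bound=float(directive.get("lower", directive.get("lower_bound", -1000.0))),
                upper_bound=float(directive.get("upper", directive.get("upper_bound", 1000.0))),
                gene_rule=directive.get("gene_rule", ""),
                subsystem=directive.get("subsystem", ""),
                kind=directive.get("kind"),
            )
            edited.add_reaction(rxn)
            if edited.classify_reaction(rxn) not in BALANCE_EXEMPT_KINDS:
                _check_balance(edited, rxn.id, elements=balance_elements)
        elif op == "remove_reaction":
            edited.remove_reaction(
                directive["id"], drop_orphans=bool(directive.get("drop_orphans", False))
            )
        elif op == "set_bounds":
            edited.set_bounds(
                directive["id"], float(directive["lower"]), float(directive["upper"])
            )
        elif op == "set_objective":
            edited.set_objective(directive["objective"])
        elif op == "add_coupling":
            edited.add_coupling(
                FluxCoupling(
                    target_reaction=directive["target"],
                    source_reaction=directive["source"],
                    ratio=float(directive["ratio"]),
                )
            )
        else:
            raise EditError(f"unknown edit op {op!r}")
    edited.validate()
    return edited
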