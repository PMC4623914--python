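"""Biomass pseudo-reactions with variable neutral-lipid content, and the
split maintenance-energy model.

Oleaginous yeasts shift their dry-weight composition dramatically between
exponential growth (storage lipid well below 1 % of dry weight) and
nitrogen-starved lipogenesis (tens of percent).  To simulate both states
with one network, the biomass equation is parameterized by the neutral-
lipid (TAG) mass fraction f of dry weight: the storage-lipid component
delivers f gram per gram biomass and every non-lipid component is rescaled
by (1 - f) / (1 - f_ref), which reduces protein proportionally while
keeping the relative amounts of all non-lipid constituents constant.  The
total dry mass of the equation stays 1 g/gDW within 0.5 %.

Maintenance ATP is split in two: growth-associated maintenance (GAM,
mmol ATP per gram biomass formed, default 17.05) sits inside the biomass
equation; non-growth-associated maintenance (NGAM) is tied to carbon-source
uptake through a flux coupling (default 5.0 mmol ATP per mmol glucose,
2.28 per mmol glycerol), so that maintenance persists in growth-arrested,
lipid-producing states where a biomass-proportional term would vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .fba import couple_fluxes
from .model import FluxCoupling, MetabolicModel, ModelError, Reaction

F_NL_MIN = 0.004
F_NL_MAX = 0.80
MASS_TOL = 0.005  # relative tolerance on the 1 g/gDW biomass closure

#: fatty-acyl residue molecular weights (free acid, g/mol)
FATTY_ACID_MW = {
    "C16:0": 256.42,
    "C16:1": 254.41,
    "C18:0": 284.48,
    "C18:1": 282.46,
    "C18:2": 280.45,
}
#: glycerol backbone contribution to a TAG after triple esterification
TAG_BACKBONE_MW = 92.09 - 3 * 18.015

#: scaffold-style default acyl profile; supply measured phase/substrate
#: profiles to override
DEFAULT_FA_PROFILE = {"C16:0": 0.15, "C16:1": 0.10, "C18:1": 0.50, "C18:2": 0.25}


class BiomassError(ModelError):
    pass


def tag_molecular_weight(fa_profile: Mapping[str, float]) -> float:
    """MW of a lumped TAG species with the given acyl mole-fraction profile."""
    total = sum(fa_profile.values())
    if abs(total - 1.0) > 1e-6:
        raise BiomassError(f"fatty-acid profile sums to {total}, not 1")
    try:
        mean_fa = sum(FATTY_ACID_MW[k] * v for k, v in fa_profile.items())
    except KeyError as exc:
        raise BiomassError(f"unknown fatty-acid species {exc.args[0]!r}")
    # glycerol + 3 acids - 3 waters; the backbone constant already carries
    # the three lost waters
    return TAG_BACKBONE_MW + 3 * mean_fa


@dataclass
class BiomassSpec:
    """Parameterization of a biomass pseudo-reaction.

    ``base_composition`` maps metabolite ids to signed mmol per gDW at the
    reference lipid fraction (positive = consumed, negative = produced by
    the biomass reaction, e.g. the ADP released by GAM is handled
    separately).  ``molecular_weights`` must provide a g/mol value for
    every mass-bearing component; cofactor carriers are entered as 0.
    """

    f_NL: float
    base_composition: dict[str, float]
    molecular_weights: dict[str, float]
    lipid_metabolite: str
    fa_profile: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FA_PROFILE))
    GAM: float = 17.05  # mmol ATP per gDW
    reference_f: float = 0.004
    lipid_mw: float | None = None  # g/mol; default: TAG assembled from profile
    atp_id: str = "atp_c"
    adp_id: str = "adp_c"
    pi_id: str = "pi_c"
    reaction_id: str = "BIOMASS"

    def lipid_molecular_weight(self) -> float:
        if self.lipid_mw is not None:
            return self.lipid_mw
        return tag_molecular_weight(self.fa_profile)

    def validate(self) -> None:
        if not (F_NL_MIN <= self.f_NL <= F_NL_MAX):
            raise BiomassError(
                f"neutral-lipid fraction {self.f_NL} outside "
                f"[{F_NL_MIN}, {F_NL_MAX}]"
            )
        if not (0.0 <= self.reference_f < 1.0):
            raise BiomassError(f"reference lipid fraction {self.reference_f} invalid")
        total = sum(self.fa_profile.values())
        if abs(total - 1.0) > 1e-6:
            raise BiomassError(f"fatty-acid profile sums to {total}, not 1")
        if self.GAM < 0:
            raise BiomassError("GAM must be non-negative")
        for met, amount in self.base_composition.items():
            if amount > 0 and met not in self.molecular_weights:
                raise BiomassError(f"no molecular weight for component {met!r}")


@dataclass
class MaintenanceSpec:
    """Split maintenance energy: GAM inside biomass, NGAM per substrate.

    ``NGAM_ratio`` is mmol ATP hydrolyzed per mmol carbon source taken up
    (5.0 for glucose, 2.28 for glycerol in the reference parameterization).
    """

    GAM: float = 17.05
    NGAM_ratio: float = 5.0

    def __post_init__(self) -> None:
        if self.GAM < 0 or self.NGAM_ratio < 0:
            raise BiomassError("maintenance parameters must be non-negative")


def build_biomass(spec: BiomassSpec) -> Reaction:
    """Assemble the biomass pseudo-reaction for the requested lipid fraction.

    The storage-lipid coefficient delivers ``f_NL`` g/gDW; all non-lipid
    components are scaled by (1 - f_NL)/(1 - reference_f); GAM ATP
    hydrolysis is added.  The summed component mass is checked to close at
    1 g/gDW within 0.5 %.
    """
    spec.validate()
    scale = (1.0 - spec.f_NL) / (1.0 - spec.reference_f)
    stoich: dict[str, float] = {}
    mass = 0.0
    for met, amount in spec.base_composition.items():
        coef = amount * scale
        stoich[met] = stoich.get(met, 0.0) - coef
        if coef > 0:
            mass += coef * spec.molecular_weights[met] / 1000.0
    lipid_mw = spec.lipid_molecular_weight()
    lipid_coef = spec.f_NL / (lipid_mw / 1000.0)
    stoich[spec.lipid_metabolite] = stoich.get(spec.lipid_metabolite, 0.0) - lipid_coef
    mass += spec.f_NL
    if abs(mass - 1.0) > MASS_TOL:
        raise BiomassError(
            f"biomass components sum to {mass:.4f} g/gDW at f_NL={spec.f_NL}"
        )
    stoich[spec.atp_id] = stoich.get(spec.atp_id, 0.0) - spec.GAM
    stoich[spec.adp_id] = stoich.get(spec.adp_id, 0.0) + spec.GAM
    stoich[spec.pi_id] = stoich.get(spec.pi_id, 0.0) + spec.GAM
    # 9-decimal rounding keeps coefficients exactly representable in SBML
    return Reaction(
        id=spec.reaction_id,
        name=f"biomass (f_NL={spec.f_NL:g})",
        stoichiometry={k: round(v, 9) for k, v in stoich.items() if abs(v) > 1e-12},
        lower_bound=0.0,
        upper_bound=1000.0,
        kind="pseudo",
        subsystem="biomass",
    )


def biomass_component_mass(spec: BiomassSpec) -> float:
    """Total consumed mass (g per gDW) of the biomass equation."""
    rxn = build_biomass(spec)
    mass = 0.0
    for met, coef in rxn.stoichiometry.items():
        if coef < 0 and met not in (spec.atp_id,):
            mw = spec.molecular_weights.get(met)
            if met == spec.lipid_metabolite:
                mw = spec.lipid_molecular_weight()
            mass += -coef * (mw or 0.0) / 1000.0
    return mass


def with_biomass(model: MetabolicModel, spec: BiomassSpec) -> MetabolicModel:
    """Copy of ``model`` with its biomass reaction rebuilt from ``spec``."""
    out = model.copy()
    rxn = build_biomass(spec)
    if rxn.id in out.reactions:
        existing = out.reactions[rxn.id]
        existing.stoichiometry = rxn.stoichiometry
        existing.name = rxn.name
        existing.kind = "pseudo"
    else:
        out.add_reaction(rxn)
    return out


def set_maintenance(
    model: MetabolicModel,
    spec: MaintenanceSpec,
    substrate_exchange: str,
    atpase_id: str = "ATPM",
    biomass_spec: BiomassSpec | None = None,
    atp_id: str = "atp_c",
    adp_id: str = "adp_c",
    pi_id: str = "pi_c",
) -> MetabolicModel:
    """Install the split maintenance model on a copy of ``model``.

    GAM is embedded in the biomass reaction (rebuilt when ``biomass_spec``
    is given, with its GAM overridden by ``spec.GAM``); NGAM is enforced by
    coupling the ATP-hydrolysis pseudo-reaction to substrate uptake:
    v_ATPM = NGAM_ratio * |v_substrate|.  Uptake flux is negative, so the
    stored coupling ratio is -NGAM_ratio.
    """
    if substrate_exchange not in model.reactions:
        raise BiomassError(f"unknown substrate exchange {substrate_exchange!r}")
    if biomass_spec is not None:
        out = with_biomass(model, replace(biomass_spec, GAM=spec.GAM))
    else:
        out = model.copy()
    if atpase_id not in out.reactions:
        out.add_reaction(
            Reaction(
                id=atpase_id,
                name="ATP maintenance hydrolysis",
                stoichiometry={atp_id: -1.0, adp_id: 1.0, pi_id: 1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
                kind="pseudo",
                subsystem="maintenance",
            )
        )
    out.couplings = [c for c in out.couplings if c.target_reaction != atpase_id]
    if spec.NGAM_ratio > 0:
        out = couple_fluxes(
            out,
            FluxCoupling(
                target_reaction=atpase_id,
                source_reaction=substrate_exchange,
                ratio=-spec.NGAM_ratio,
            ),
        )
    else:
        out.set_bounds(atpase_id, 0.0, 0.0)
    return out
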