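"""Hand-verifiable synthetic core model of oleaginous-yeast carbon metabolism.

The generator emits a small compartmentalized network (~22 reactions) whose
FBA optima can be derived with pencil and paper, containing every structural
feature the analysis pipeline exercises on a genome-scale model:

- glucose exchange and transport, lumped glycolysis (2 ATP + 2 NADH and
  2 pyruvate per glucose),
- an oxidative-PPP lump (full oxidative cycling: 1 glucose + 12 NADP+ ->
  6 CO2 + 12 NADPH), the sole native NADPH source,
- a citrate node: citrate synthesis from 2 pyruvate (+1 NADH), ATP-coupled
  citrate export (overflow), and ATP:citrate lyase cleaving citrate to
  acetyl-CoA + oxaloacetate, with OAA decarboxylated back to pyruvate,
- fatty-acid synthesis drawing 8 acetyl-CoA + 14 NADPH + 7 ATP per C16
  acyl chain, with a lipid demand reaction as the lipogenesis objective,
- a TCA lump (full pyruvate oxidation), P/O-coupled respiration as the only
  NADH sink besides an optional glycerol-synthesis valve (which dissipates
  NADH and ATP at a carbon cost, the overflow role glycerol/polyol
  production plays in vivo),
- biomass and maintenance pseudo-reactions from the biomass builder, with
  NGAM coupled to glucose uptake,
- optional add-ons: glycerol catabolism, fructose isomerase, a sucrose
  exchange with no pathway behind it (invertase absent), the mannitol
  cycle, and an energy-independent transhydrogenase.

Cofactor pairs carry pseudo-element formulas (A = adenosine core,
R = NAD core, Q = NADP core, Z = CoA core) so that elemental balance can be
validated on C, N, P and the carrier elements; H and O bookkeeping is
elided in the lumped steps.

Stoichiometry is deterministic; a seed only permutes the order in which
reactions and metabolites are inserted, to flush out order-dependence bugs.
The manifest of expected optima is computed by exhaustive vertex
enumeration (:mod:`oleaflux.enumerate_lp`), never typed in by hand.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .biomass import BiomassSpec, MaintenanceSpec, build_biomass, set_maintenance
from .enumerate_lp import enumerate_optimum
from .model import MetabolicModel, Metabolite, ModelError, Reaction

#: elements validated on generated reactions (H/O elided in lumps)
BALANCE_ELEMENTS = ("C", "N", "P", "A", "R", "Q", "Z")

PYRUVATE_MW = 88.06
PALMITATE_MW = 256.42
#: mmol pyruvate standing in for 1 g of non-lipid biomass at the reference
#: lipid fraction (0.4 % NL)
NONLIPID_PYR = (1.0 - 0.004) * 1000.0 / PYRUVATE_MW
NONLIPID_NADPH = 4.0  # mmol NADPH per gDW non-lipid biomass
#: reducing equivalents invested in amino-acid/nucleotide synthesis per gram
#: of non-lipid biomass (reductive amination of keto-acid precursors); this
#: is what makes non-lipid biomass electron-rich relative to its pyruvate
#: stand-in
NONLIPID_NADH = 25.0


class ToyModelError(ModelError):
    pass


@dataclass
class ToyModelSpec:
    # structural options
    include_ppp: bool = True
    include_citrate_export: bool = True
    include_acl: bool = True
    include_lipid_demand: bool = True
    include_o2_chain: bool = True
    include_ngam: bool = True
    include_pyruvate_export: bool = True
    include_glycerol_valve: bool = True
    include_glycerol: bool = False
    include_fructose: bool = False
    include_sucrose: bool = False
    include_mannitol_cycle: bool = False
    include_transhydrogenase: bool = False
    # stoichiometric parameters
    po_ratio: float = 1.5  # ATP per NADH oxidized
    atp_per_glucose: float = 2.0  # glycolytic substrate-level ATP
    nadph_per_glucose_ppp: float = 12.0
    gam: float = 17.05  # mmol ATP per gDW
    ngam_ratio: float = 5.0  # mmol ATP per mmol glucose taken up
    citrate_export_atp_cost: float = 2.0
    f_nl: float = 0.004
    glucose_uptake: float = 4.0  # default uptake cap, mmol/gDW/h
    seed: int | None = None

    def validate(self) -> None:
        if self.include_lipid_demand:
            if not self.include_acl:
                raise ToyModelError(
                    "lipid demand requires ATP:citrate lyase (include_acl)"
                )
            if not (
                self.include_ppp
                or self.include_mannitol_cycle
                or self.include_transhydrogenase
            ):
                raise ToyModelError("lipid demand requires an NADPH source")
        if self.include_mannitol_cycle and not self.include_lipid_demand:
            pass  # harmless
        for val in (self.po_ratio, self.atp_per_glucose, self.nadph_per_glucose_ppp):
            if val <= 0:
                raise ToyModelError("stoichiometric parameters must be positive")


def toy_biomass_spec(f_nl: float = 0.004, gam: float = 17.05) -> BiomassSpec:
    """Biomass parameterization of the toy model (pyruvate stands in for the
    non-lipid dry mass, palmitate for the storage lipid)."""
    return BiomassSpec(
        f_NL=f_nl,
        base_composition={
            "pyr_c": NONLIPID_PYR,
            "nadph_c": NONLIPID_NADPH,
            "nadp_c": -NONLIPID_NADPH,
            "nadh_c": NONLIPID_NADH,
            "nad_c": -NONLIPID_NADH,
        },
        molecular_weights={
            "pyr_c": PYRUVATE_MW,
            "nadph_c": 0.0,
            "nadp_c": 0.0,
            "nad_c": 0.0,
            "nadh_c": 0.0,
        },
        lipid_metabolite="fa_c",
        fa_profile={"C16:0": 1.0},
        lipid_mw=PALMITATE_MW,
        GAM=gam,
        reference_f=0.004,
    )


def _metabolites() -> dict[str, Metabolite]:
    def met(mid, name, comp, formula):
        return Metabolite(id=mid, name=name, compartment=comp, formula=formula)

    return {
        "glc_e": met("glc_e", "D-glucose", "e", "C6H12O6"),
        "glc_c": met("glc_c", "D-glucose", "c", "C6H12O6"),
        "pyr_c": met("pyr_c", "pyruvate", "c", "C3H4O3"),
        "cit_c": met("cit_c", "citrate", "c", "C6H8O7"),
        "cit_e": met("cit_e", "citrate", "e", "C6H8O7"),
        "oaa_c": met("oaa_c", "oxaloacetate", "c", "C4H4O5"),
        "accoa_c": met("accoa_c", "acetyl-CoA", "c", "ZC2H3O"),
        "coa_c": met("coa_c", "coenzyme A", "c", "Z"),
        "fa_c": met("fa_c", "palmitate", "c", "C16H32O2"),
        "co2_c": met("co2_c", "CO2", "c", "CO2"),
        "co2_e": met("co2_e", "CO2", "e", "CO2"),
        "o2_c": met("o2_c", "O2", "c", "O2"),
        "o2_e": met("o2_e", "O2", "e", "O2"),
        "atp_c": met("atp_c", "ATP", "c", "AP3"),
        "adp_c": met("adp_c", "ADP", "c", "AP2"),
        "pi_c": met("pi_c", "phosphate", "c", "P"),
        "nad_c": met("nad_c", "NAD+", "c", "R"),
        "nadh_c": met("nadh_c", "NADH", "c", "RH"),
        "nadp_c": met("nadp_c", "NADP+", "c", "Q"),
        "nadph_c": met("nadph_c", "NADPH", "c", "QH"),
        "glyc_c": met("glyc_c", "glycerol", "c", "C3H8O3"),
        "glyc_e": met("glyc_e", "glycerol", "e", "C3H8O3"),
        "fru_c": met("fru_c", "D-fructose", "c", "C6H12O6"),
        "sucr_e": met("sucr_e", "sucrose", "e", "C12H22O11"),
        "mnl_c": met("mnl_c", "D-mannitol", "c", "C6H14O6"),
        "f6p_c": met("f6p_c", "fructose-6-phosphate", "c", "C6H12O6P"),
        "m1p_c": met("m1p_c", "mannitol-1-phosphate", "c", "C6H14O6P"),
    }


def build_toy_model(
    spec: ToyModelSpec | None = None, manifest: bool = True
) -> tuple[MetabolicModel, dict]:
    """Generate the toy model and its manifest.

    The manifest records the emitted reactions, the options used, and —
    when ``manifest=True`` — the expected FBA optima computed by the
    vertex-enumeration route.
    """
    spec = spec or ToyModelSpec()
    spec.validate()
    mets = _metabolites()
    used_mets: set[str] = set()
    reactions: list[Reaction] = []

    def rxn(rid, name, stoich, lb=0.0, ub=1000.0, gene="", kind=None, subsystem=""):
        reactions.append(
            Reaction(
                id=rid,
                name=name,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_rule=gene,
                kind=kind,
                subsystem=subsystem,
            )
        )
        used_mets.update(stoich)

    po = spec.po_ratio
    g_atp = spec.atp_per_glucose
    q = spec.nadph_per_glucose_ppp

    rxn("EX_glc", "glucose exchange", {"glc_e": -1.0},
        lb=-spec.glucose_uptake, ub=1000.0, kind="exchange", subsystem="exchange")
    rxn("GLCt", "glucose transport", {"glc_e": -1.0, "glc_c": 1.0},
        gene="gHXT1", kind="transport", subsystem="transport")
    rxn("GLYC", "glycolysis (lumped)",
        {"glc_c": -1.0, "adp_c": -g_atp, "pi_c": -g_atp, "nad_c": -2.0,
         "pyr_c": 2.0, "atp_c": g_atp, "nadh_c": 2.0},
        gene="gGLK1 and gPYK1", subsystem="glycolysis")
    if spec.include_ppp:
        rxn("PPP", "oxidative pentose phosphate pathway (lumped)",
            {"glc_c": -1.0, "nadp_c": -q, "co2_c": 6.0, "nadph_c": q},
            gene="gZWF1", subsystem="pentose phosphate pathway")
    rxn("CITSYN", "pyruvate to citrate (lumped)",
        {"pyr_c": -2.0, "nad_c": -1.0, "cit_c": 1.0, "nadh_c": 1.0},
        gene="gCIT1", subsystem="TCA cycle")
    if spec.include_acl:
        rxn("ACL", "ATP:citrate lyase",
            {"cit_c": -1.0, "atp_c": -1.0, "coa_c": -1.0,
             "oaa_c": 1.0, "accoa_c": 1.0, "adp_c": 1.0, "pi_c": 1.0},
            gene="gACL1 and gACL2", subsystem="lipid synthesis")
        rxn("OAADC", "oxaloacetate decarboxylation (lumped)",
            {"oaa_c": -1.0, "pyr_c": 1.0, "co2_c": 1.0},
            subsystem="anaplerosis")
    rxn("TCA", "pyruvate oxidation (lumped TCA)",
        {"pyr_c": -1.0, "nad_c": -4.0, "adp_c": -1.0, "pi_c": -1.0,
         "co2_c": 3.0, "nadh_c": 4.0, "atp_c": 1.0},
        gene="gPDA1", subsystem="TCA cycle")
    if spec.include_o2_chain:
        rxn("RESP", "respiratory chain (P/O-coupled)",
            {"nadh_c": -1.0, "o2_c": -0.5, "adp_c": -po, "pi_c": -po,
             "nad_c": 1.0, "atp_c": po},
            gene="gCOX1 and (gNDE1 or gNDI1)", subsystem="oxidative phosphorylation")
        rxn("O2t", "oxygen diffusion", {"o2_e": -1.0, "o2_c": 1.0},
            kind="transport", subsystem="transport")
        rxn("EX_o2", "oxygen exchange", {"o2_e": -1.0},
            lb=-1000.0, ub=1000.0, kind="exchange", subsystem="exchange")
    if spec.include_lipid_demand:
        rxn("FAS", "fatty-acid synthesis (lumped, C16)",
            {"accoa_c": -8.0, "atp_c": -7.0, "nadph_c": -14.0,
             "fa_c": 1.0, "coa_c": 8.0, "adp_c": 7.0, "pi_c": 7.0,
             "nadp_c": 14.0},
            gene="gFAS1 and gFAS2", subsystem="lipid synthesis")
        rxn("DM_fa", "storage lipid demand", {"fa_c": -1.0},
            kind="pseudo", subsystem="lipid synthesis")
    if spec.include_citrate_export:
        rxn("CITt", "citrate export (energized)",
            {"cit_c": -1.0, "atp_c": -spec.citrate_export_atp_cost,
             "cit_e": 1.0, "adp_c": spec.citrate_export_atp_cost,
             "pi_c": spec.citrate_export_atp_cost},
            kind="transport", subsystem="transport")
        rxn("EX_cit", "citrate exchange", {"cit_e": -1.0},
            lb=0.0, ub=1000.0, kind="exchange", subsystem="exchange")
    if spec.include_pyruvate_export:
        rxn("EX_pyr", "pyruvate exchange", {"pyr_c": -1.0},
            lb=0.0, ub=1000.0, kind="exchange", subsystem="exchange")
    rxn("CO2t", "CO2 diffusion", {"co2_c": -1.0, "co2_e": 1.0},
        kind="transport", subsystem="transport")
    rxn("EX_co2", "CO2 exchange", {"co2_e": -1.0},
        lb=0.0, ub=1000.0, kind="exchange", subsystem="exchange")
    if spec.include_glycerol_valve:
        rxn("GLYCSYN", "glycerol synthesis (lumped G3P shunt)",
            {"glc_c": -1.0, "atp_c": -2.0, "nadh_c": -2.0,
             "glyc_c": 2.0, "adp_c": 2.0, "pi_c": 2.0, "nad_c": 2.0},
            gene="gGPD1", subsystem="glycerol metabolism")
    if spec.include_glycerol_valve or spec.include_glycerol:
        rxn("GLYCt", "glycerol diffusion", {"glyc_c": -1.0, "glyc_e": 1.0},
            lb=-1000.0, ub=1000.0, kind="transport", subsystem="transport")
        rxn("EX_glyc", "glycerol exchange", {"glyc_e": -1.0},
            lb=0.0, ub=1000.0, kind="exchange", subsystem="exchange")
    if spec.include_glycerol:
        rxn("GLYCD", "glycerol catabolism (lumped)",
            {"glyc_c": -1.0, "nad_c": -2.0, "adp_c": -1.0, "pi_c": -1.0,
             "pyr_c": 1.0, "nadh_c": 2.0, "atp_c": 1.0},
            gene="gGUT1", subsystem="glycerol metabolism")
        rxn("GNG", "gluconeogenesis (lumped)",
            {"pyr_c": -2.0, "atp_c": -6.0, "nadh_c": -2.0,
             "glc_c": 1.0, "adp_c": 6.0, "pi_c": 6.0, "nad_c": 2.0},
            gene="gFBP1", subsystem="gluconeogenesis")
    if spec.include_fructose:
        rxn("EX_fru", "fructose exchange", {"fru_c": -1.0},
            lb=0.0, ub=1000.0, kind="exchange", subsystem="exchange")
        rxn("FRUISO", "glucose-fructose isomerase (lumped)",
            {"fru_c": -1.0, "glc_c": 1.0},
            lb=-1000.0, ub=1000.0, gene="gXYL", subsystem="glycolysis")
    if spec.include_sucrose:
        # exchange only: no invertase, sucrose cannot be metabolized
        rxn("EX_sucr", "sucrose exchange", {"sucr_e": -1.0},
            lb=0.0, ub=1000.0, kind="exchange", subsystem="exchange")
    if spec.include_mannitol_cycle:
        rxn("FK", "fructokinase",
            {"fru_c": -1.0, "atp_c": -1.0, "f6p_c": 1.0, "adp_c": 1.0},
            gene="gHXK1", subsystem="mannitol cycle")
        rxn("M1PDH", "mannitol-1-phosphate 5-dehydrogenase",
            {"f6p_c": -1.0, "nadh_c": -1.0, "m1p_c": 1.0, "nad_c": 1.0},
            subsystem="mannitol cycle")
        rxn("M1Pase", "mannitol-1-phosphatase",
            {"m1p_c": -1.0, "mnl_c": 1.0, "pi_c": 1.0},
            subsystem="mannitol cycle")
        rxn("MTLDH", "mannitol 2-dehydrogenase (NADP+)",
            {"mnl_c": -1.0, "nadp_c": -1.0, "fru_c": 1.0, "nadph_c": 1.0},
            lb=-1000.0, ub=1000.0, subsystem="mannitol cycle")
    if spec.include_transhydrogenase:
        rxn("THD2", "transhydrogenase (energy-independent)",
            {"nadh_c": -1.0, "nadp_c": -1.0, "nad_c": 1.0, "nadph_c": 1.0},
            subsystem="cofactor metabolism")

    bspec = toy_biomass_spec(f_nl=spec.f_nl, gam=spec.gam)
    biomass = build_biomass(bspec)
    reactions.append(biomass)
    used_mets.update(biomass.stoichiometry)

    order = list(range(len(reactions)))
    met_ids = sorted(used_mets)
    if spec.seed is not None:
        rng = np.random.default_rng(spec.seed)
        rng.shuffle(order)
        met_order = np.array(met_ids)
        rng.shuffle(met_order)
        met_ids = list(met_order)

    model = MetabolicModel(
        model_id="toy_oleaginous",
        name="synthetic oleaginous-yeast core model",
        compartments={"c": "cytosol", "e": "extracellular"},
        external_compartment="e",
    )
    for mid in met_ids:
        model.add_metabolite(mets[mid])
    for i in order:
        model.add_reaction(reactions[i])
    model.set_objective("BIOMASS")

    if spec.include_ngam and spec.ngam_ratio > 0:
        model = set_maintenance(
            model,
            MaintenanceSpec(GAM=spec.gam, NGAM_ratio=spec.ngam_ratio),
            substrate_exchange="EX_glc",
        )

    _validate_balance(model)

    info: dict = {
        "spec": asdict(spec),
        "reactions": sorted(model.reactions),
        "metabolites": sorted(model.metabolites),
        "biomass_spec": {
            "f_NL": bspec.f_NL,
            "GAM": bspec.GAM,
            "non_lipid_pyruvate_mmol": NONLIPID_PYR,
        },
        "expected": {},
    }
    if manifest:
        info["expected"] = _expected_optima(model, spec)
    return model, info


def _validate_balance(model: MetabolicModel) -> None:
    for rid, rxn in model.reactions.items():
        if model.classify_reaction(rxn) in ("exchange", "pseudo"):
            continue
        imbalance = model.mass_balance(rid, elements=BALANCE_ELEMENTS)
        if imbalance:
            raise ToyModelError(f"generated reaction {rid} unbalanced: {imbalance}")


def _expected_optima(model: MetabolicModel, spec: ToyModelSpec) -> dict:
    expected: dict = {}
    status, mu = enumerate_optimum(model, objective="BIOMASS", direction="max")
    expected["max_growth"] = {
        "status": status,
        "value": mu,
        "conditions": {"glucose_uptake_cap": spec.glucose_uptake},
    }
    if spec.include_lipid_demand:
        lipo = model.copy()
        lipo.set_bounds("BIOMASS", 0.0, 0.0)
        status, lip = enumerate_optimum(lipo, objective="DM_fa", direction="max")
        expected["max_lipid_growth_arrested"] = {
            "status": status,
            "value": lip,
            "conditions": {
                "glucose_uptake_cap": spec.glucose_uptake,
                "growth": 0.0,
            },
        }
    return expected


def toy_screen_fixture() -> tuple[MetabolicModel, dict[str, bool]]:
    """Four-substrate growth-screen fixture with one planted disagreement.

    The model grows on glucose, glycerol and fructose and cannot use
    sucrose (no invertase).  The truth table marks fructose as non-growth,
    planting exactly one false positive: the expected confusion matrix is
    TP=2, TN=1, FP=1, FN=0 (accuracy 0.75).
    """
    spec = ToyModelSpec(
        include_glycerol=True, include_fructose=True, include_sucrose=True
    )
    model, _ = build_toy_model(spec, manifest=False)
    truth = {
        "EX_glc": True,
        "EX_glyc": True,
        "EX_fru": False,  # planted disagreement: the network can grow here
        "EX_sucr": False,
    }
    return model, truth
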