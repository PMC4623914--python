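"""Lipid-production scenario analyses for oleaginous-yeast models.

These are the study designs built on top of the FBA core: growth-arrested
lipogenesis under measured uptake and citrate-excretion constraints,
fed-batch feed-rate calculation (the uptake rate that sustains a target
lipid flux without citrate overflow), TAG-content scans with rebuilt
biomass equations, oxygen robustness thresholds, NADPH-source restriction
and comparison, theoretical product yields, and substrate growth screens.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .biomass import BiomassSpec, with_biomass
from .dynamics import exchange_molecular_weight
from .fba import (
    FluxSolution,
    InfeasibleError,
    RobustnessCurve,
    robustness_scan,
    solve_fba,
)
from .model import FluxCoupling, MetabolicModel, ModelError

GROWTH_THRESHOLD = 1e-6  # h^-1; minimum growth rate counted as "growth"

#: metabolite ids recognized as cytosolic NADPH by default
DEFAULT_NADPH_IDS = ("nadph_c", "nadph")


class ScenarioError(ModelError):
    pass


# ---------------------------------------------------------------------------
# Lipogenesis phase


@dataclass
class LipogenesisConstraints:
    """Growth-arrested lipid-production phase constraints.

    ``uptake`` is the measured substrate uptake magnitude (e.g. the 0.350
    mmol gDW^-1 h^-1 of a nitrogen-starved glucose culture).  The measured
    citrate excretion can be entered either as an absolute rate
    (``citrate_rate``) or per mol substrate (``citrate_per_substrate``);
    set both to None (or the exchange to None) for no citrate constraint.
    """

    substrate_exchange: str = "EX_glc"
    uptake: float = 0.350
    growth_reaction: str = "BIOMASS"
    lipid_reaction: str = "DM_fa"
    citrate_exchange: str | None = "EX_cit"
    citrate_rate: float | None = None
    citrate_per_substrate: float | None = None

    def __post_init__(self) -> None:
        if self.uptake < 0:
            raise ScenarioError("uptake must be non-negative")
        if self.citrate_rate is not None and self.citrate_per_substrate is not None:
            raise ScenarioError(
                "give citrate as an absolute rate or a per-substrate ratio, not both"
            )


def _apply_lipogenesis(model: MetabolicModel, c: LipogenesisConstraints) -> MetabolicModel:
    probe = model.copy()
    probe.set_bounds(c.growth_reaction, 0.0, 0.0)
    probe.set_uptake(c.substrate_exchange, c.uptake, fixed=True)
    if c.citrate_exchange is not None and c.citrate_exchange in probe.reactions:
        if c.citrate_rate is not None:
            probe.set_bounds(c.citrate_exchange, c.citrate_rate, c.citrate_rate)
        elif c.citrate_per_substrate is not None:
            # v_cit = ratio * |v_substrate|; uptake flux is negative
            probe.add_coupling(
                FluxCoupling(
                    target_reaction=c.citrate_exchange,
                    source_reaction=c.substrate_exchange,
                    ratio=-c.citrate_per_substrate,
                )
            )
    return probe


def lipogenesis_fba(
    model: MetabolicModel, constraints: LipogenesisConstraints
) -> FluxSolution:
    """Maximal lipid flux in the growth-arrested, uptake-constrained state."""
    if constraints.lipid_reaction not in model.reactions:
        raise ScenarioError(
            f"lipid objective reaction {constraints.lipid_reaction!r} not in model"
        )
    probe = _apply_lipogenesis(model, constraints)
    sol = solve_fba(probe, objective=constraints.lipid_reaction, direction="max")
    if not sol.optimal:
        raise InfeasibleError(
            f"lipogenesis scenario is {sol.status} at uptake {constraints.uptake}; "
            f"check the citrate constraint"
        )
    return sol


def compute_feed_uptake(
    model: MetabolicModel,
    constraints: LipogenesisConstraints,
    target_lipid_flux: float,
) -> float:
    """Minimal substrate uptake sustaining a target lipid flux without
    citrate excretion (the fed-batch design point).

    Growth is fixed at zero, the citrate exchange is closed, the lipid flux
    is required to reach the target, and the uptake magnitude is minimized.
    """
    if target_lipid_flux < 0:
        raise ScenarioError("target lipid flux must be non-negative")
    probe = model.copy()
    probe.set_bounds(constraints.growth_reaction, 0.0, 0.0)
    if constraints.citrate_exchange is not None and constraints.citrate_exchange in probe.reactions:
        probe.set_bounds(constraints.citrate_exchange, 0.0, 0.0)
    lipid = probe.reactions[constraints.lipid_reaction]
    probe.set_bounds(constraints.lipid_reaction, target_lipid_flux, lipid.upper_bound)
    probe.set_bounds(constraints.substrate_exchange, -1000.0, 0.0)
    # uptake flux is <= 0; maximizing it minimizes the uptake magnitude
    sol = solve_fba(probe, objective=constraints.substrate_exchange, direction="max")
    if not sol.optimal:
        raise InfeasibleError(
            f"lipid flux target {target_lipid_flux} unreachable at any uptake"
        )
    return -sol.objective_value


# ---------------------------------------------------------------------------
# Fed-batch feed plan


@dataclass
class FeedPlan:
    target_uptake: float  # mmol/gDW/h
    biomass: float  # g in the reactor
    feed_concentration: float  # g/L
    substrate_mw: float  # g/mol
    pump_rate_l_per_min: float
    delivery_g_per_h: float


def feed_schedule(
    target_uptake: float,
    biomass: float,
    feed_concentration: float,
    substrate_mw: float = 180.16,
) -> FeedPlan:
    """Pump rate delivering ``target_uptake`` to ``biomass`` grams of cells.

    delivery [g/h] = uptake [mmol/gDW/h] * biomass [g] * MW [g/mol] / 1000;
    pump rate [L/min] = delivery / concentration / 60.
    """
    if biomass <= 0 or feed_concentration <= 0 or substrate_mw <= 0:
        raise ScenarioError("feed-plan inputs must be positive")
    if target_uptake < 0:
        raise ScenarioError("target uptake must be non-negative")
    delivery = target_uptake * biomass * substrate_mw / 1000.0
    pump = delivery / feed_concentration / 60.0
    return FeedPlan(
        target_uptake=target_uptake,
        biomass=biomass,
        feed_concentration=feed_concentration,
        substrate_mw=substrate_mw,
        pump_rate_l_per_min=pump,
        delivery_g_per_h=delivery,
    )


# ---------------------------------------------------------------------------
# TAG-content scans


def nadph_production_rate(
    model: MetabolicModel,
    solution: FluxSolution,
    nadph_ids: Sequence[str] = DEFAULT_NADPH_IDS,
) -> float:
    """Total NADPH production (mmol/gDW/h) in a flux solution."""
    ids = {m for m in nadph_ids if m in model.metabolites}
    total = 0.0
    for rid, rxn in model.reactions.items():
        coef = sum(rxn.stoichiometry.get(m, 0.0) for m in ids)
        if coef:
            total += max(0.0, coef * solution.fluxes.get(rid, 0.0))
    return total


def lipid_content_scan(
    model: MetabolicModel,
    biomass_spec: BiomassSpec,
    f_grid: Iterable[float],
    mode: str = "fixed_uptake",
    substrate_exchange: str = "EX_glc",
    uptake: float = 4.0,
    growth_rate: float = 0.33,
    growth_reaction: str = "BIOMASS",
    o2_exchange: str | None = "EX_o2",
    co2_exchange: str | None = "EX_co2",
    acl_reaction: str | None = "ACL",
    nadph_ids: Sequence[str] = DEFAULT_NADPH_IDS,
) -> pd.DataFrame:
    """Metabolic response to neutral-lipid content of the biomass equation.

    ``fixed_uptake``: substrate uptake capped at the measured rate, growth
    maximized.  ``fixed_growth``: growth pinned, uptake minimized.  Per
    lipid fraction f the biomass equation is rebuilt and the solution's
    growth rate / uptake, O2 uptake, CO2 output, respiratory quotient, ATP:
    citrate-lyase flux and total NADPH production rate are recorded.
    """
    if mode not in ("fixed_uptake", "fixed_growth"):
        raise ScenarioError(f"unknown scan mode {mode!r}")
    rows = []
    for f in f_grid:
        probe = with_biomass(model, replace(biomass_spec, f_NL=f))
        if mode == "fixed_uptake":
            probe.set_uptake(substrate_exchange, uptake)
            sol = solve_fba(probe, objective=growth_reaction, direction="max")
            mu = sol.objective_value if sol.optimal else float("nan")
            upt = -sol.fluxes.get(substrate_exchange, float("nan")) if sol.optimal else float("nan")
        else:
            probe.set_bounds(growth_reaction, growth_rate, growth_rate)
            probe.set_bounds(substrate_exchange, -1000.0, 0.0)
            sol = solve_fba(probe, objective=substrate_exchange, direction="max")
            mu = growth_rate if sol.optimal else float("nan")
            upt = -sol.objective_value if sol.optimal else float("nan")
        row = {"f_NL": f, "status": sol.status, "growth_rate": mu, "uptake": upt}
        if sol.optimal:
            o2 = -sol.fluxes.get(o2_exchange, float("nan")) if o2_exchange else float("nan")
            co2 = sol.fluxes.get(co2_exchange, float("nan")) if co2_exchange else float("nan")
            row["o2_uptake"] = o2
            row["co2_output"] = co2
            row["respiratory_quotient"] = co2 / o2 if o2 and o2 > 0 else float("nan")
            if acl_reaction and acl_reaction in model.reactions:
                row["acl_flux"] = sol.fluxes.get(acl_reaction, float("nan"))
            row["nadph_production"] = nadph_production_rate(probe, sol, nadph_ids)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Oxygen thresholds


def o2_thresholds(curve: RobustnessCurve, rel: float = 0.99) -> dict[str, float]:
    """Per-objective threshold: the largest scanned O2 bound at which the
    response has dropped below ``rel`` of its unconstrained (largest-bound)
    value.  Returns 0 for responses flat across the whole grid."""
    df = pd.DataFrame(curve.responses)
    out: dict[str, float] = {}
    for label, grp in df.groupby("objective"):
        grp = grp.sort_values("grid_value")
        feasible = grp[grp["status"] == "optimal"]
        if feasible.empty:
            out[label] = float("nan")
            continue
        ref = feasible["objective_value"].iloc[-1]
        below = feasible[feasible["objective_value"] < rel * ref]
        out[label] = float(below["grid_value"].max()) if not below.empty else 0.0
    return out


# ---------------------------------------------------------------------------
# NADPH sources


@dataclass
class NADPHSourceSet:
    """Named, disjoint sets of reactions counted as one NADPH source."""

    sources: dict[str, set[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for name, rxns in self.sources.items():
            for rid in rxns:
                if rid in seen:
                    raise ScenarioError(
                        f"reaction {rid!r} assigned to both {seen[rid]!r} and {name!r}"
                    )
                seen[rid] = name


def nadph_producing_reactions(
    model: MetabolicModel, nadph_ids: Sequence[str] = DEFAULT_NADPH_IDS
) -> dict[str, float]:
    """Reactions able to produce NADPH, with their net NADPH coefficient."""
    ids = {m for m in nadph_ids if m in model.metabolites}
    out: dict[str, float] = {}
    for rid, rxn in model.reactions.items():
        coef = sum(rxn.stoichiometry.get(m, 0.0) for m in ids)
        if coef > 0 and rxn.upper_bound > 0:
            out[rid] = coef
        elif coef < 0 and rxn.lower_bound < 0:
            out[rid] = coef
    return out


def restrict_nadph_source(
    model: MetabolicModel,
    source: str,
    source_sets: Mapping[str, Iterable[str]],
    nadph_ids: Sequence[str] = DEFAULT_NADPH_IDS,
) -> MetabolicModel:
    """Copy of the model in which NADPH can only be produced by the named
    source's reactions: every other NADPH-producing direction is closed."""
    if source not in source_sets:
        raise ScenarioError(f"unknown NADPH source {source!r}")
    keep = set(source_sets[source])
    missing = [rid for rid in keep if rid not in model.reactions]
    if missing:
        raise ScenarioError(
            f"NADPH source {source!r} references absent reactions {missing}"
        )
    out = model.copy()
    for rid, coef in nadph_producing_reactions(model, nadph_ids).items():
        if rid in keep:
            continue
        rxn = out.reactions[rid]
        if coef > 0:
            rxn.upper_bound = 0.0
            rxn.lower_bound = min(rxn.lower_bound, 0.0)
        else:
            rxn.lower_bound = 0.0
            rxn.upper_bound = max(rxn.upper_bound, 0.0)
    return out


def nadph_yield_comparison(
    model: MetabolicModel,
    source_sets: Mapping[str, Iterable[str]],
    constraints: LipogenesisConstraints,
    reference: str = "PPP",
    nadph_ids: Sequence[str] = DEFAULT_NADPH_IDS,
) -> pd.DataFrame:
    """Maximal lipid yield under lipogenesis constraints per NADPH source,
    reported absolutely and relative to the reference source."""
    NADPHSourceSet(sources={k: set(v) for k, v in source_sets.items()})
    rows = []
    for name in source_sets:
        restricted = restrict_nadph_source(model, name, source_sets, nadph_ids)
        try:
            sol = lipogenesis_fba(restricted, constraints)
            lipid = sol.fluxes[constraints.lipid_reaction]
            status = sol.status
        except InfeasibleError:
            lipid, status = float("nan"), "infeasible"
        rows.append(
            {
                "source": name,
                "status": status,
                "lipid_flux": lipid,
                "lipid_yield_per_substrate": lipid / constraints.uptake
                if constraints.uptake
                else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    ref_rows = df.loc[df["source"] == reference, "lipid_flux"]
    ref = float(ref_rows.iloc[0]) if not ref_rows.empty else float("nan")
    df["relative_to_reference"] = df["lipid_flux"] / ref
    return df


# ---------------------------------------------------------------------------
# Theoretical yields


@dataclass
class TheoreticalYield:
    product: str
    substrate: str
    mol_per_mol: float
    g_per_g: float | None


def theoretical_yield(
    model: MetabolicModel,
    product_reaction: str,
    substrate_exchange: str,
    growth_reaction: str | None = "BIOMASS",
    basis_uptake: float = 1.0,
    ngam_off: bool = True,
    atpase_id: str = "ATPM",
) -> TheoreticalYield:
    """Maximal stoichiometric product yield on a substrate.

    Growth is fixed at zero.  With ``ngam_off`` (default) the maintenance
    coupling is released and the ATP-hydrolysis pseudo-reaction is left
    open as a free dissipation sink, so the result is the pure carbon-
    stoichiometric bound with energy non-limiting — the conventional
    meaning of a theoretical yield.  mol/mol is product flux per substrate
    uptake; g/g additionally needs molecular weights for both species.
    """
    if basis_uptake <= 0:
        raise ScenarioError("basis uptake must be positive")
    probe = model.copy()
    if growth_reaction and growth_reaction in probe.reactions:
        probe.set_bounds(growth_reaction, 0.0, 0.0)
    if ngam_off:
        probe.couplings = [c for c in probe.couplings if c.target_reaction != atpase_id]
        if atpase_id in probe.reactions:
            probe.set_bounds(atpase_id, 0.0, 1000.0)
    probe.set_uptake(substrate_exchange, basis_uptake, fixed=True)
    sol = solve_fba(probe, objective=product_reaction, direction="max")
    if not sol.optimal:
        return TheoreticalYield(product_reaction, substrate_exchange, 0.0, None)
    mol_per_mol = sol.objective_value / basis_uptake
    g_per_g = None
    try:
        mw_p = exchange_molecular_weight(probe, product_reaction)
        mw_s = exchange_molecular_weight(probe, substrate_exchange)
        g_per_g = mol_per_mol * mw_p / mw_s
    except ModelError:
        pass
    return TheoreticalYield(product_reaction, substrate_exchange, mol_per_mol, g_per_g)


def percent_of_theoretical(observed_yield: float, max_yield: float) -> float:
    """Observed yield as a percentage of the theoretical maximum."""
    if max_yield <= 0:
        raise ScenarioError("theoretical maximum must be positive")
    if observed_yield < 0:
        raise ScenarioError("observed yield must be non-negative")
    return 100.0 * observed_yield / max_yield


# ---------------------------------------------------------------------------
# Substrate screen


@dataclass
class ScreenReport:
    records: list[dict]
    tp: int
    fp: int
    tn: int
    fn: int
    untestable: list[str] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def substrate_screen(
    model: MetabolicModel,
    truth: Mapping[str, bool],
    free_exchanges: Sequence[str] = (),
    uptake: float = 10.0,
    growth_reaction: str = "BIOMASS",
    threshold: float = GROWTH_THRESHOLD,
) -> ScreenReport:
    """Growth/no-growth prediction per sole carbon source vs published truth.

    All exchange uptakes except the free (mineral-medium) set are closed;
    each candidate substrate is opened in turn and growth is predicted when
    the optimal growth rate exceeds ``threshold``.  Substrates without an
    exchange reaction are recorded as untestable and excluded from the
    accuracy.
    """
    if not truth:
        raise ScenarioError("empty substrate list")
    base = model.copy()
    free = set(free_exchanges)
    for rid in base.exchange_reaction_ids():
        rxn = base.reactions[rid]
        if rid in free:
            rxn.lower_bound = -1000.0
        else:
            rxn.lower_bound = 0.0
    records: list[dict] = []
    untestable: list[str] = []
    tp = fp = tn = fn = 0
    for substrate, observed in truth.items():
        if substrate not in base.reactions:
            untestable.append(substrate)
            records.append(
                {"substrate": substrate, "observed": observed, "predicted": None,
                 "outcome": "untestable"}
            )
            continue
        probe = base.copy()
        probe.set_uptake(substrate, uptake)
        sol = solve_fba(probe, objective=growth_reaction, parsimonious=False)
        predicted = bool(sol.optimal and sol.objective_value > threshold)
        if predicted and observed:
            outcome = "TP"; tp += 1
        elif predicted and not observed:
            outcome = "FP"; fp += 1
        elif not predicted and not observed:
            outcome = "TN"; tn += 1
        else:
            outcome = "FN"; fn += 1
        records.append(
            {"substrate": substrate, "observed": observed, "predicted": predicted,
             "outcome": outcome,
             "growth_rate": sol.objective_value if sol.optimal else 0.0}
        )
    return ScreenReport(records=records, tp=tp, fp=fp, tn=tn, fn=fn, untestable=untestable)


# ---------------------------------------------------------------------------
# Minimal medium helper


def apply_minimal_medium(
    model: MetabolicModel,
    carbon_exchange: str,
    uptake: float,
    free_exchanges: Sequence[str] = (),
    fixed: bool = False,
) -> MetabolicModel:
    """In-silico minimal medium: close every exchange uptake except the free
    inorganic set, then open the carbon source at the given rate."""
    out = model.copy()
    free = set(free_exchanges)
    for rid in out.exchange_reaction_ids():
        rxn = out.reactions[rid]
        if rid in free:
            rxn.lower_bound = -1000.0
        elif rid != carbon_exchange:
            rxn.lower_bound = 0.0
    out.set_uptake(carbon_exchange, uptake, fixed=fixed)
    return out
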