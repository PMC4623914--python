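"""Dynamic FBA: static-optimization batch simulation.

Between successive steady-state FBA solves, biomass and extracellular
concentrations are integrated over a step dt: biomass grows exponentially
at the current optimal growth rate (X <- X * exp(mu*dt)), each tracked
extracellular concentration changes by flux * integrated-biomass * MW, and
each uptake bound for the next solve is the lesser of the kinetic cap and
what the remaining concentration can supply over one step.  This is the
classical static-optimization dFBA scheme; it converges at first order in
dt (halving dt halves the final-state error).

Uptake kinetics are a hard cap — the only kinetic input is the measured
maximal specific uptake rate; no Michaelis-Menten term is fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .fba import solve_fba
from .model import MetabolicModel, ModelError, parse_formula

ATOMIC_MASS = {
    "C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007,
    "P": 30.974, "S": 32.06, "K": 39.098, "Na": 22.99,
    "Mg": 24.305, "Fe": 55.845, "Ca": 40.078, "Cl": 35.45,
}

#: fallbacks (g/mol) when an exchanged species carries no formula
DEFAULT_MW = {"glucose": 180.16, "glycerol": 92.09}

EXHAUSTION_TOL = 1e-9


class DynamicsError(ModelError):
    pass


@dataclass
class BatchState:
    time: float  # h
    biomass: float  # g/L
    concentrations: dict[str, float]  # exchange id -> g/L

    def __post_init__(self) -> None:
        if self.biomass <= 0:
            raise DynamicsError("biomass must be positive")
        for k, v in self.concentrations.items():
            if v < -1e-12:
                raise DynamicsError(f"negative concentration for {k}")


@dataclass
class Trajectory:
    states: list[BatchState]
    terminal_reason: str  # substrate_exhausted | t_end | infeasible
    growth_rates: list[float] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for st in self.states:
            row = {"time": st.time, "biomass": st.biomass}
            row.update(st.concentrations)
            rows.append(row)
        return pd.DataFrame(rows)

    @property
    def final(self) -> BatchState:
        return self.states[-1]


def formula_mw(formula: str) -> float:
    """Molecular weight from an elemental formula; pseudo-elements weigh 0."""
    return sum(
        ATOMIC_MASS.get(el, 0.0) * n for el, n in parse_formula(formula).items()
    )


def exchange_molecular_weight(model: MetabolicModel, exchange_id: str) -> float:
    """g/mol of the species behind an exchange reaction."""
    rxn = model.reactions.get(exchange_id)
    if rxn is None:
        raise DynamicsError(f"unknown exchange {exchange_id!r}")
    mets = [
        model.metabolites[m]
        for m in rxn.stoichiometry
        if not model.metabolites[m].boundary
    ]
    if len(mets) != 1:
        raise DynamicsError(f"{exchange_id!r} is not a single-species exchange")
    met = mets[0]
    if met.formula:
        mw = formula_mw(met.formula)
        if mw > 0:
            return mw
    for key, mw in DEFAULT_MW.items():
        if key in (met.name or "").lower() or key in met.id.lower():
            return mw
    raise DynamicsError(
        f"cannot determine molecular weight for {exchange_id!r}; pass it in "
        f"molecular_weights"
    )


def simulate_batch(
    model: MetabolicModel,
    init: BatchState,
    uptake_caps: Mapping[str, float],
    dt: float = 0.1,
    t_end: float = 100.0,
    objective: Mapping[str, float] | str | None = None,
    molecular_weights: Mapping[str, float] | None = None,
    parsimonious: bool = True,
) -> Trajectory:
    """Simulate batch growth from ``init`` until substrate exhaustion or t_end.

    ``uptake_caps`` gives the maximal specific uptake rate
    (mmol gDW^-1 h^-1, positive) for each consumed exchange; every exchange
    appearing in ``init.concentrations`` is tracked (secretions included,
    with cap absent meaning no uptake allowed beyond the model's bounds).
    """
    if dt <= 0:
        raise DynamicsError("dt must be positive")
    mw = {}
    for ex in init.concentrations:
        if molecular_weights and ex in molecular_weights:
            mw[ex] = molecular_weights[ex]
        else:
            mw[ex] = exchange_molecular_weight(model, ex)

    probe = model.copy()
    states = [BatchState(init.time, init.biomass, dict(init.concentrations))]
    growth_rates: list[float] = []
    reason = "t_end"

    def exhausted(conc: Mapping[str, float]) -> bool:
        return all(conc[ex] <= EXHAUSTION_TOL for ex in uptake_caps)

    if exhausted(init.concentrations):
        return Trajectory(states=states, terminal_reason="substrate_exhausted")

    t = init.time
    while t < init.time + t_end - 1e-12:
        current = states[-1]
        X = current.biomass
        for ex, cap in uptake_caps.items():
            conc = current.concentrations.get(ex, 0.0)
            # availability limit: what the medium can supply over one step
            avail = conc / (X * mw[ex] / 1000.0 * dt)
            probe.set_uptake(ex, min(cap, max(avail, 0.0)))
        sol = solve_fba(probe, objective=objective, parsimonious=parsimonious)
        if not sol.optimal:
            reason = "infeasible"
            break
        mu = max(sol.objective_value, 0.0)
        growth_rates.append(mu)
        X_new = X * math.exp(mu * dt) if mu > 0 else X
        # integral of X over the step (exact for exponential growth)
        X_int = (X_new - X) / mu if mu > 1e-12 else X * dt
        conc_new = dict(current.concentrations)
        for ex in conc_new:
            v = sol.fluxes.get(ex, 0.0)  # mmol/gDW/h, negative = uptake
            conc_new[ex] = max(0.0, conc_new[ex] + v * X_int * mw[ex] / 1000.0)
        t = current.time + dt
        states.append(BatchState(t, X_new, conc_new))
        if exhausted(conc_new):
            reason = "substrate_exhausted"
            break
    return Trajectory(states=states, terminal_reason=reason, growth_rates=growth_rates)


@dataclass
class YieldRecord:
    substrate: str
    consumed: float  # g/L
    biomass_yield: float  # g biomass per g substrate
    product_yields: dict[str, float] = field(default_factory=dict)


def trajectory_yields(
    traj: Trajectory, substrate: str, products: Sequence[str] = ()
) -> YieldRecord:
    """Overall yields across a trajectory: Y_SX = dX / d(substrate), g/g."""
    first, last = traj.states[0], traj.states[-1]
    consumed = first.concentrations.get(substrate, 0.0) - last.concentrations.get(
        substrate, 0.0
    )
    if consumed <= EXHAUSTION_TOL:
        raise DynamicsError(f"no consumption of {substrate!r} in trajectory")
    dX = last.biomass - first.biomass
    product_yields = {
        p: (last.concentrations.get(p, 0.0) - first.concentrations.get(p, 0.0))
        / consumed
        for p in products
    }
    return YieldRecord(
        substrate=substrate,
        consumed=consumed,
        biomass_yield=dX / consumed,
        product_yields=product_yields,
    )
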