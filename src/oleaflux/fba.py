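"""Flux balance analysis and its workhorse variants.

All solves go through a single LP assembly: maximize (or minimize) c.v
subject to S.v = 0, coupling rows (v_t - ratio*v_s = 0), and flux bounds.
The LP itself is handed to HiGHS through :func:`scipy.optimize.linprog`.

Because FBA optima are typically degenerate, reported flux vectors are by
default parsimony-resolved: the objective is fixed at its optimum and the
total absolute flux sum is minimized (pFBA).  Headline objective values are
degeneracy-free; individual fluxes quoted from a solution refer to the
parsimonious optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .model import FluxCoupling, MetabolicModel, ModelError

FEASIBILITY_TOL = 1e-6  # API contract on ||S.v||_inf and bound violations
OBJECTIVE_SLACK = 1e-10  # slack when pinning the objective for pFBA / FVA


class InfeasibleError(ModelError):
    """A solve that the caller required to be optimal was not."""


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)
    parsimonious: bool = False

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class FVAResult:
    fraction_of_optimum: float
    ranges: dict[str, tuple[float, float]]

    def minimum(self, rxn_id: str) -> float:
        return self.ranges[rxn_id][0]

    def maximum(self, rxn_id: str) -> float:
        return self.ranges[rxn_id][1]


@dataclass
class RobustnessCurve:
    control_reaction: str
    grid: list[float]
    # one record per grid point per objective label
    responses: list[dict]


@dataclass
class DeletionReport:
    ratios: dict[str, float]
    essential_cutoff: float = 0.01

    def essential(self) -> list[str]:
        return sorted(g for g, r in self.ratios.items() if r < self.essential_cutoff)


# ---------------------------------------------------------------------------
# LP assembly


def _lp_arrays(model: MetabolicModel):
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    rows = [S]
    idx = {r: j for j, r in enumerate(rxn_ids)}
    for c in model.couplings:
        row = np.zeros(len(rxn_ids))
        row[idx[c.target_reaction]] = 1.0
        row[idx[c.source_reaction]] = -c.ratio
        rows.append(row[None, :])
    A_eq = np.vstack(rows) if len(rows) > 1 else S
    bounds = [
        (model.reactions[r].lower_bound, model.reactions[r].upper_bound)
        for r in rxn_ids
    ]
    return A_eq, bounds, rxn_ids, idx


def _objective_vector(model: MetabolicModel, objective, idx) -> np.ndarray:
    if objective is None:
        objective = model.objective
    if isinstance(objective, str):
        objective = {objective: 1.0}
    if not objective:
        raise ModelError("no objective specified and model has none")
    c = np.zeros(len(idx))
    for rid, w in objective.items():
        if rid not in idx:
            raise ModelError(f"objective reaction {rid!r} not in model")
        c[idx[rid]] = w
    return c


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded"}


_SOLVER_OPTIONS = {
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-10,
}


def _solve(c, A_ub, b_ub, A_eq, b_eq, bounds):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options=dict(_SOLVER_OPTIONS),
    )
    return _STATUS.get(res.status, "infeasible"), res


def solve_fba(
    model: MetabolicModel,
    objective: Mapping[str, float] | str | None = None,
    direction: str = "max",
    parsimonious: bool = True,
) -> FluxSolution:
    """Solve max/min c.v s.t. S.v = 0, couplings, bounds.

    With ``parsimonious=True`` (default) the reported flux vector addition-
    ally minimizes total absolute flux at the fixed optimal objective value.
    Infeasible and unbounded problems are reported via ``status``.
    """
    if direction not in ("max", "min"):
        raise ModelError(f"direction must be 'max' or 'min', got {direction!r}")
    A_eq, bounds, rxn_ids, idx = _lp_arrays(model)
    c = _objective_vector(model, objective, idx)
    sign = -1.0 if direction == "max" else 1.0
    b_eq = np.zeros(A_eq.shape[0])
    status, res = _solve(sign * c, None, None, A_eq, b_eq, bounds)
    if status != "optimal":
        return FluxSolution(status=status, objective_value=float("nan"))
    opt = float(c @ res.x)
    fluxes = res.x
    if parsimonious:
        fluxes = _parsimonious_fluxes(A_eq, bounds, c, opt, direction)
        if fluxes is None:  # numerically marginal; fall back to plain solution
            fluxes = res.x
    flux_map = {r: float(v) for r, v in zip(rxn_ids, fluxes)}
    return FluxSolution(
        status="optimal",
        objective_value=opt,
        fluxes=flux_map,
        parsimonious=parsimonious,
    )


def _parsimonious_fluxes(A_eq, bounds, c, opt, direction):
    """Minimize sum |v| with the objective pinned to its optimum.

    Variables are split v = p - n with p, n >= 0; the original bounds become
    inequality rows so asymmetric bounds survive the split.
    """
    m, n = A_eq.shape
    A_eq2 = np.hstack([A_eq, -A_eq])
    b_eq2 = np.zeros(m)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    eye = np.eye(n)
    split = np.hstack([eye, -eye])
    # l <= v <= u  ->  v <= u and -v <= -l
    A_ub = [split, -split]
    b_ub = [hi, -lo]
    # pin the objective: for max, c.v >= opt - slack; for min, c.v <= opt + slack
    pin = np.hstack([c, -c])
    if direction == "max":
        A_ub.append(-pin[None, :])
        b_ub.append(np.array([-(opt - OBJECTIVE_SLACK)]))
    else:
        A_ub.append(pin[None, :])
        b_ub.append(np.array([opt + OBJECTIVE_SLACK]))
    A_ub = np.vstack(A_ub)
    b_ub = np.concatenate(b_ub)
    cost = np.ones(2 * n)
    var_bounds = [(0.0, max(hi[j], 0.0) - min(lo[j], 0.0)) for j in range(n)] * 2
    status, res = _solve(cost, A_ub, b_ub, A_eq2, b_eq2, var_bounds)
    if status != "optimal":
        return None
    return res.x[:n] - res.x[n:]


def steady_state_residual(model: MetabolicModel, solution: FluxSolution) -> float:
    """||S.v||_inf of a solution, for contract checking."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    v = np.array([solution.fluxes[r] for r in rxn_ids])
    return float(np.max(np.abs(S @ v))) if len(rxn_ids) else 0.0


# ---------------------------------------------------------------------------
# FVA


def flux_variability(
    model: MetabolicModel,
    reactions: Sequence[str] | None = None,
    fraction_of_optimum: float = 1.0,
    objective: Mapping[str, float] | str | None = None,
    direction: str = "max",
) -> FVAResult:
    """Per-reaction flux range at a fixed fraction of the optimal objective.

    The objective constraint is ``c.v >= fraction * opt`` for maximization
    objectives (``<=`` for minimization).
    """
    A_eq, bounds, rxn_ids, idx = _lp_arrays(model)
    c = _objective_vector(model, objective, idx)
    base = solve_fba(model, objective=objective, direction=direction, parsimonious=False)
    if not base.optimal:
        raise InfeasibleError(
            f"model is {base.status}; cannot run FVA at fraction "
            f"{fraction_of_optimum}"
        )
    opt = base.objective_value
    if direction == "max":
        A_ub = -c[None, :]
        b_ub = np.array([-(fraction_of_optimum * opt - OBJECTIVE_SLACK)])
    else:
        A_ub = c[None, :]
        b_ub = np.array([fraction_of_optimum * opt + OBJECTIVE_SLACK])
    b_eq = np.zeros(A_eq.shape[0])
    targets = list(reactions) if reactions is not None else list(rxn_ids)
    ranges: dict[str, tuple[float, float]] = {}
    for rid in targets:
        if rid not in idx:
            raise ModelError(f"FVA target reaction {rid!r} not in model")
        e = np.zeros(len(rxn_ids))
        e[idx[rid]] = 1.0
        lo_status, lo_res = _solve(e, A_ub, b_ub, A_eq, b_eq, bounds)
        hi_status, hi_res = _solve(-e, A_ub, b_ub, A_eq, b_eq, bounds)
        if lo_status != "optimal" or hi_status != "optimal":
            raise InfeasibleError(
                f"FVA infeasible for {rid!r} at fraction {fraction_of_optimum}"
            )
        ranges[rid] = (float(lo_res.x[idx[rid]]), float(hi_res.x[idx[rid]]))
    return FVAResult(fraction_of_optimum=fraction_of_optimum, ranges=ranges)


# ---------------------------------------------------------------------------
# Robustness scan


def robustness_scan(
    model: MetabolicModel,
    control_reaction: str,
    grid: Sequence[float],
    objectives: Mapping[str, Mapping[str, float] | str],
    reporters: Sequence[str] = (),
    mode: str = "uptake",
) -> RobustnessCurve:
    """Objective response to a sweep of one reaction's bound.

    ``grid`` values are uptake magnitudes when ``mode='uptake'`` (the
    control exchange's lower bound is set to -g, secretion closed), or
    direct (lb, ub) = (g, g) pins when ``mode='fixed'``.  Infeasible grid
    points are recorded with their status; the scan continues.
    """
    grid = list(grid)
    increasing = all(b > a for a, b in zip(grid, grid[1:]))
    decreasing = all(b < a for a, b in zip(grid, grid[1:]))
    if len(grid) > 1 and not (increasing or decreasing):
        raise ModelError("robustness grid must be strictly monotone")
    if control_reaction not in model.reactions:
        raise ModelError(f"unknown control reaction {control_reaction!r}")
    responses: list[dict] = []
    for g in grid:
        probe = model.copy()
        if mode == "uptake":
            probe.set_bounds(control_reaction, -g, 0.0)
        elif mode == "fixed":
            probe.set_bounds(control_reaction, g, g)
        else:
            raise ModelError(f"unknown robustness mode {mode!r}")
        for label, obj in objectives.items():
            sol = solve_fba(probe, objective=obj, direction="max")
            rec = {
                "grid_value": float(g),
                "objective": label,
                "status": sol.status,
                "objective_value": sol.objective_value if sol.optimal else float("nan"),
            }
            for rep in reporters:
                rec[rep] = sol.fluxes.get(rep, float("nan")) if sol.optimal else float("nan")
            responses.append(rec)
    return RobustnessCurve(control_reaction=control_reaction, grid=grid, responses=responses)


# ---------------------------------------------------------------------------
# Gene deletions


class _RuleParser:
    """Recursive-descent parser/evaluator for GPR boolean rules.

    Grammar: expr := term ('or' term)*; term := factor ('and' factor)*;
    factor := gene | '(' expr ')'.  Gene ids may contain any non-space,
    non-parenthesis characters, so locus tags with dots or dashes work.
    """

    def __init__(self, rule: str):
        self.tokens = (
            rule.replace("(", " ( ").replace(")", " ) ").split()
        )
        self.pos = 0

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        self.pos += 1
        return tok

    def parse(self, present) -> bool:
        if not self.tokens:
            return True
        value = self._expr(present)
        if self._peek() is not None:
            raise ModelError(f"trailing tokens in gene rule near {self._peek()!r}")
        return value

    def _expr(self, present) -> bool:
        value = self._term(present)
        while self._peek() is not None and self._peek().lower() == "or":
            self._next()
            value = self._term(present) or value
        return value

    def _term(self, present) -> bool:
        value = self._factor(present)
        while self._peek() is not None and self._peek().lower() == "and":
            self._next()
            value = self._factor(present) and value
        return value

    def _factor(self, present) -> bool:
        tok = self._next()
        if tok is None:
            raise ModelError("unexpected end of gene rule")
        if tok == "(":
            value = self._expr(present)
            if self._next() != ")":
                raise ModelError("unbalanced parentheses in gene rule")
            return value
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelError(f"malformed gene rule near {tok!r}")
        return present(tok)


def evaluate_gene_rule(rule: str, knocked_out: Iterable[str] = ()) -> bool:
    """Evaluate a GPR rule with the given genes absent.  Empty rule = True."""
    knocked = set(knocked_out)
    return _RuleParser(rule).parse(lambda g: g not in knocked)


def single_gene_deletions(
    model: MetabolicModel,
    objective: Mapping[str, float] | str | None = None,
    essential_cutoff: float = 0.01,
) -> DeletionReport:
    """Wild-type-relative growth ratio for every single-gene knockout.

    Reactions whose rule evaluates False without the gene get bounds (0, 0).
    A gene absent from every rule has ratio 1 by construction.
    """
    wild = solve_fba(model, objective=objective, parsimonious=False)
    if not wild.optimal:
        raise InfeasibleError(f"wild-type solve is {wild.status}")
    mu_wt = wild.objective_value
    rules = {
        rid: rxn.gene_rule for rid, rxn in model.reactions.items() if rxn.gene_rule.strip()
    }
    for rid, rule in rules.items():
        try:
            evaluate_gene_rule(rule)
        except ModelError as exc:
            raise ModelError(f"reaction {rid!r}: {exc}")
    ratios: dict[str, float] = {}
    for gene in model.genes:
        blocked = [
            rid for rid, rule in rules.items() if not evaluate_gene_rule(rule, {gene})
        ]
        if not blocked:
            ratios[gene] = 1.0
            continue
        mutant = model.copy()
        for rid in blocked:
            mutant.set_bounds(rid, 0.0, 0.0)
        sol = solve_fba(mutant, objective=objective, parsimonious=False)
        mu = sol.objective_value if sol.optimal else 0.0
        ratios[gene] = float(np.clip(mu / mu_wt, 0.0, 1.0)) if mu_wt > 0 else 0.0
    return DeletionReport(ratios=ratios, essential_cutoff=essential_cutoff)


# ---------------------------------------------------------------------------
# Couplings


def couple_fluxes(model: MetabolicModel, coupling: FluxCoupling) -> MetabolicModel:
    """Return a copy of the model with v_target = ratio * v_source enforced."""
    out = model.copy()
    out.add_coupling(coupling)
    return out
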