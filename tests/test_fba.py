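"""FBA engine: solver-vs-oracle agreement, pFBA, FVA, robustness scans,
gene rules and flux couplings."""

import numpy as np
import pytest

from lp_oracle import oracle_fva, oracle_optimum
from oleaflux import (
    FluxCoupling,
    ModelError,
    ToyModelSpec,
    build_toy_model,
    couple_fluxes,
    evaluate_gene_rule,
    flux_variability,
    robustness_scan,
    single_gene_deletions,
    solve_fba,
    steady_state_residual,
)
from conftest import lean_spec


def test_closed_exchanges_give_zero_growth(toy_model):
    """No carbon in, no growth."""
    closed = toy_model.copy()
    for rid in closed.exchange_reaction_ids():
        rxn = closed.reactions[rid]
        rxn.lower_bound = 0.0
    sol = solve_fba(closed, parsimonious=False)
    assert sol.optimal
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


def test_solver_matches_oracle_on_default_toy(toy_model):
    status, expected = oracle_optimum(toy_model, "BIOMASS")
    sol = solve_fba(toy_model, parsimonious=False)
    assert status == sol.status == "optimal"
    assert sol.objective_value == pytest.approx(expected, abs=1e-8)


def test_steady_state_residual_within_contract(toy_model):
    sol = solve_fba(toy_model)
    assert steady_state_residual(toy_model, sol) <= 1e-6


def test_infeasible_reported_as_status(toy_model):
    probe = toy_model.copy()
    probe.set_uptake("EX_glc", 4.0, fixed=True)
    probe.set_bounds("EX_o2", 0.0, 0.0)  # anaerobic with forced uptake
    sol = solve_fba(probe, parsimonious=False)
    assert sol.status == "infeasible"
    assert np.isnan(sol.objective_value)


def test_objective_invariant_under_reaction_reordering():
    base, _ = build_toy_model(ToyModelSpec(seed=None), manifest=False)
    ref = solve_fba(base, parsimonious=False).objective_value
    for seed in (7, 99):
        shuffled, _ = build_toy_model(ToyModelSpec(seed=seed), manifest=False)
        val = solve_fba(shuffled, parsimonious=False).objective_value
        assert val == pytest.approx(ref, abs=1e-9)


def test_parsimonious_is_deterministic_and_idempotent(toy_model):
    a = solve_fba(toy_model, parsimonious=True)
    b = solve_fba(toy_model, parsimonious=True)
    assert a.fluxes == b.fluxes
    # total absolute flux never exceeds the plain solution's
    plain = solve_fba(toy_model, parsimonious=False)
    assert sum(map(abs, a.fluxes.values())) <= sum(map(abs, plain.fluxes.values())) + 1e-6
    assert a.objective_value == pytest.approx(plain.objective_value, abs=1e-6)


class TestFVA:
    def test_fixed_reaction_has_point_range(self, toy_model):
        probe = toy_model.copy()
        probe.set_bounds("EX_glc", -2.0, -2.0)
        res = flux_variability(probe, ["EX_glc"], fraction_of_optimum=0.5)
        lo, hi = res.ranges["EX_glc"]
        assert lo == pytest.approx(-2.0, abs=1e-9)
        assert hi == pytest.approx(-2.0, abs=1e-9)

    def test_parsimonious_flux_within_fva_range(self, toy_model):
        sol = solve_fba(toy_model, parsimonious=True)
        res = flux_variability(toy_model, fraction_of_optimum=1.0)
        for rid, (lo, hi) in res.ranges.items():
            assert lo <= hi + 1e-9
            assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6

    def test_fva_matches_enumeration_oracle(self):
        model, _ = build_toy_model(lean_spec(), manifest=False)
        targets = ["PPP", "TCA", "GLYC"]
        expected = oracle_fva(model, "BIOMASS", targets, fraction=0.9)
        got = flux_variability(model, targets, fraction_of_optimum=0.9)
        for rid in targets:
            assert got.ranges[rid][0] == pytest.approx(expected[rid][0], abs=1e-7)
            assert got.ranges[rid][1] == pytest.approx(expected[rid][1], abs=1e-7)

    def test_infeasible_fraction_raises(self, toy_model):
        probe = toy_model.copy()
        for rid in probe.exchange_reaction_ids():
            probe.reactions[rid].lower_bound = 0.0
        # optimum is 0; asking for a range on a blocked model still works,
        # but an infeasible *model* must raise with the fraction named
        probe.add_coupling(FluxCoupling("GLYC", "PPP", 1.0))
        probe.set_bounds("GLYC", 1.0, 2.0)
        probe.set_bounds("PPP", 0.0, 0.0)
        with pytest.raises(ModelError, match="0.9"):
            flux_variability(probe, ["GLYC"], fraction_of_optimum=0.9)


class TestRobustness:
    def test_single_point_grid_equals_plain_fba(self, toy_model):
        sol = solve_fba(toy_model, parsimonious=False)
        curve = robustness_scan(
            toy_model, "EX_glc", [4.0], objectives={"growth": "BIOMASS"}
        )
        assert curve.responses[0]["objective_value"] == pytest.approx(
            sol.objective_value, abs=1e-9
        )

    def test_growth_monotone_in_o2_bound(self, toy_model):
        grid = list(np.arange(0.0, 12.5, 0.5))
        curve = robustness_scan(
            toy_model, "EX_o2", grid, objectives={"growth": "BIOMASS"}
        )
        values = [r["objective_value"] for r in curve.responses]
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))

    def test_growth_curve_piecewise_linear(self, toy_model):
        """The toy growth-vs-O2 response is piecewise linear with few
        distinct slopes (breakpoints set by the P/O-coupled ATP balance)."""
        grid = list(np.arange(0.0, 10.25, 0.25))
        curve = robustness_scan(
            toy_model, "EX_o2", grid, objectives={"growth": "BIOMASS"}
        )
        values = np.array([r["objective_value"] for r in curve.responses])
        slopes = np.diff(values) / 0.25
        distinct = np.unique(np.round(slopes, 6))
        assert len(distinct) <= 4

    def test_infeasible_grid_points_recorded_not_raised(self, toy_model):
        probe = toy_model.copy()
        probe.set_uptake("EX_glc", 4.0, fixed=True)
        curve = robustness_scan(
            probe, "EX_o2", [0.0, 5.0, 10.0], objectives={"growth": "BIOMASS"}
        )
        statuses = [r["status"] for r in curve.responses]
        assert "infeasible" in statuses and "optimal" in statuses

    def test_non_monotone_grid_rejected(self, toy_model):
        with pytest.raises(ModelError):
            robustness_scan(
                toy_model, "EX_o2", [0.0, 2.0, 1.0], objectives={"g": "BIOMASS"}
            )


class TestGeneRules:
    @pytest.mark.parametrize(
        "rule,knocked,expected",
        [
            ("", {"gX"}, True),
            ("gA", {"gA"}, False),
            ("gA or gB", {"gA"}, True),
            ("gA and gB", {"gA"}, False),
            ("(gA and gB) or gC", {"gA"}, True),
            ("(gA or gB) and (gC or gD)", {"gA", "gC"}, True),
            ("(gA or gB) and (gC or gD)", {"gC", "gD"}, False),
        ],
    )
    def test_rule_evaluation(self, rule, knocked, expected):
        assert evaluate_gene_rule(rule, knocked) is expected

    def test_malformed_rule_raises(self):
        with pytest.raises(ModelError):
            evaluate_gene_rule("gA and", set())
        with pytest.raises(ModelError):
            evaluate_gene_rule("(gA or gB", set())


class TestDeletions:
    def test_deletion_screen(self, toy_model):
        report = single_gene_deletions(toy_model)
        # sole-transporter gene: no glucose uptake, no growth
        assert report.ratios["gHXT1"] == pytest.approx(0.0, abs=1e-9)
        # isoenzyme pair inside the respiration rule: either alone suffices
        assert report.ratios["gNDE1"] == pytest.approx(1.0)
        assert report.ratios["gNDI1"] == pytest.approx(1.0)
        # gene restricted to the glycerol valve: dispensable for growth
        assert report.ratios["gGPD1"] == pytest.approx(1.0)
        assert set(report.essential()) >= {"gHXT1", "gCOX1", "gPDA1"}
        assert all(0.0 <= r <= 1.0 for r in report.ratios.values())


class TestCouplings:
    def test_ngam_coupling_arithmetic_glucose(self, toy_model):
        """NGAM 5 mmol ATP per mmol glucose: at uptake 4, ATPase flux 20."""
        probe = toy_model.copy()
        probe.set_uptake("EX_glc", 4.0, fixed=True)
        sol = solve_fba(probe)
        assert -sol.fluxes["EX_glc"] == pytest.approx(4.0, abs=1e-8)
        assert sol.fluxes["ATPM"] == pytest.approx(20.0, abs=1e-6)

    def test_coupling_ratio_respected_for_glycerol_value(self):
        """Ratio 2.28 at uptake 8.78 forces ATPase flux 20.02."""
        from oleaflux import MaintenanceSpec, set_maintenance

        spec = ToyModelSpec(include_glycerol=True, include_ngam=False)
        model, _ = build_toy_model(spec, manifest=False)
        model.set_bounds("EX_glc", 0.0, 0.0)
        model = set_maintenance(
            model, MaintenanceSpec(NGAM_ratio=2.28), "EX_glyc"
        )
        model.set_uptake("EX_glyc", 8.78, fixed=True)
        sol = solve_fba(model)
        assert sol.optimal
        assert sol.fluxes["ATPM"] == pytest.approx(2.28 * 8.78, abs=1e-6)

    def test_zero_ratio_means_no_maintenance(self, toy_model):
        probe = toy_model.copy()
        probe.couplings = [
            FluxCoupling(c.target_reaction, c.source_reaction, 0.0)
            for c in probe.couplings
        ]
        probe.set_uptake("EX_glc", 4.0, fixed=True)
        sol = solve_fba(probe)
        assert sol.fluxes["ATPM"] == pytest.approx(0.0, abs=1e-9)

    def test_self_coupling_rejected(self):
        with pytest.raises(ModelError):
            FluxCoupling("ATPM", "ATPM", 1.0)
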