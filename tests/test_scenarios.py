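"""Lipid-production scenario analyses, checked against hand-derived
closed-form optima of the toy network (see conftest constants)."""

import numpy as np
import pytest

from conftest import (
    CITRATE_TERM,
    LIPID_PER_UPTAKE,
    MANNITOL_LIPID_PER_UPTAKE,
    TH_LIPID_PER_UPTAKE,
    UPTAKE_PER_LIPID,
)
from oleaflux import (
    LipogenesisConstraints,
    ModelError,
    ToyModelSpec,
    build_toy_model,
    compute_feed_uptake,
    feed_schedule,
    lipid_content_scan,
    lipogenesis_fba,
    nadph_producing_reactions,
    nadph_yield_comparison,
    o2_thresholds,
    percent_of_theoretical,
    restrict_nadph_source,
    robustness_scan,
    solve_fba,
    substrate_screen,
    theoretical_yield,
    toy_biomass_spec,
    toy_screen_fixture,
)

TOY_SOURCES = {
    "PPP": ["PPP"],
    "MANNITOL_CYCLE": ["MTLDH"],
    "TRANSHYDROGENASE": ["THD2"],
}


@pytest.fixture(scope="module")
def nadph_model():
    spec = ToyModelSpec(include_mannitol_cycle=True, include_transhydrogenase=True)
    model, _ = build_toy_model(spec, manifest=False)
    return model


class TestLipogenesis:
    def test_unconstrained_lipid_optimum_matches_hand_algebra(self, toy_model):
        """Max lipid at growth 0, uptake U: L = (84/487) U for the default
        stoichiometric parameters."""
        c = LipogenesisConstraints(uptake=0.35, citrate_exchange=None)
        sol = lipogenesis_fba(toy_model, c)
        assert sol.fluxes["DM_fa"] == pytest.approx(
            LIPID_PER_UPTAKE * 0.35, rel=1e-7
        )

    def test_citrate_constraint_lowers_lipid_proportionally(self, toy_model):
        """Forced citrate overflow at the measured per-glucose ratio: the
        optimum drops to (84 U - 87 e)/487 and the excretion is honored."""
        c = LipogenesisConstraints(uptake=0.35, citrate_per_substrate=0.55)
        sol = lipogenesis_fba(toy_model, c)
        e = 0.55 * 0.35
        assert sol.fluxes["EX_cit"] == pytest.approx(e, abs=1e-8)
        assert sol.fluxes["DM_fa"] == pytest.approx(
            LIPID_PER_UPTAKE * 0.35 - CITRATE_TERM * e, rel=1e-6
        )

    def test_absolute_citrate_rate_entry_mode(self, toy_model):
        c = LipogenesisConstraints(uptake=0.35, citrate_rate=0.1925)
        sol = lipogenesis_fba(toy_model, c)
        assert sol.fluxes["EX_cit"] == pytest.approx(0.1925, abs=1e-8)

    def test_removing_citrate_constraint_redirects_overflow(self, toy_model):
        """Without the excretion constraint all citrate goes to acetyl-CoA
        and the lipid rate rises."""
        constrained = lipogenesis_fba(
            toy_model, LipogenesisConstraints(uptake=0.35, citrate_per_substrate=0.55)
        )
        free = lipogenesis_fba(
            toy_model, LipogenesisConstraints(uptake=0.35, citrate_exchange=None)
        )
        assert free.fluxes["DM_fa"] > constrained.fluxes["DM_fa"]
        assert abs(free.fluxes.get("EX_cit", 0.0)) < 1e-8

    def test_zero_uptake_zero_lipid(self, toy_model):
        c = LipogenesisConstraints(uptake=0.0, citrate_exchange=None)
        sol = lipogenesis_fba(toy_model, c)
        assert sol.fluxes["DM_fa"] == pytest.approx(0.0, abs=1e-9)

    def test_overflow_split_consistency(self, toy_model):
        """Citrate-node bookkeeping: exported citrate plus Acl throughput
        equals total citrate synthesis per unit glucose."""
        c = LipogenesisConstraints(uptake=0.35, citrate_per_substrate=0.55)
        sol = lipogenesis_fba(toy_model, c)
        assert sol.fluxes["CITSYN"] == pytest.approx(
            sol.fluxes["EX_cit"] + sol.fluxes["ACL"], abs=1e-6
        )


class TestFeedCalculation:
    def test_min_uptake_is_inverse_of_lipid_optimum(self, toy_model):
        """Without citrate excretion the minimal uptake for a lipid target
        L is exactly (487/84) L — the fed-batch design point."""
        c = LipogenesisConstraints(uptake=0.35, citrate_per_substrate=0.55)
        lipid = lipogenesis_fba(toy_model, c).fluxes["DM_fa"]
        u = compute_feed_uptake(toy_model, c, lipid)
        assert u == pytest.approx(UPTAKE_PER_LIPID * lipid, rel=1e-7)

    def test_feed_uptake_below_measured_uptake(self, toy_model):
        c = LipogenesisConstraints(uptake=0.35, citrate_per_substrate=0.55)
        lipid = lipogenesis_fba(toy_model, c).fluxes["DM_fa"]
        assert compute_feed_uptake(toy_model, c, lipid) <= 0.35

    def test_zero_target_gives_maintenance_floor(self, toy_model):
        c = LipogenesisConstraints(uptake=0.35)
        assert compute_feed_uptake(toy_model, c, 0.0) == pytest.approx(0.0, abs=1e-8)

    def test_unreachable_target_raises(self, toy_model):
        c = LipogenesisConstraints(uptake=0.35)
        with pytest.raises(ModelError):
            compute_feed_uptake(toy_model, c, 1e6)


class TestFeedSchedule:
    def test_dimensional_identity(self):
        """A 6.55 g/L feed pumped at 69.4 uL/min delivers 27.3 mg/h."""
        delivery = 6.55 * 69.4e-6 * 60  # g/h, direct dimensional analysis
        plan = feed_schedule(target_uptake=1.0, biomass=1.0,
                             feed_concentration=6.55, substrate_mw=180.16)
        # invert: pump_rate * concentration * 60 == delivery
        assert plan.pump_rate_l_per_min * 6.55 * 60 == pytest.approx(
            plan.delivery_g_per_h, rel=1e-12
        )
        assert delivery == pytest.approx(0.0273, rel=0.01)

    def test_zero_uptake_zero_pump(self):
        plan = feed_schedule(0.0, 2.0, 6.55)
        assert plan.pump_rate_l_per_min == 0.0

    def test_doubling_concentration_halves_pump_rate(self):
        a = feed_schedule(0.5, 2.0, 6.55)
        b = feed_schedule(0.5, 2.0, 13.10)
        assert a.pump_rate_l_per_min == pytest.approx(2 * b.pump_rate_l_per_min)

    def test_invalid_inputs(self):
        with pytest.raises(ModelError):
            feed_schedule(1.0, 0.0, 6.55)
        with pytest.raises(ModelError):
            feed_schedule(-1.0, 1.0, 6.55)


class TestLipidContentScan:
    def test_fixed_uptake_scan_trends(self, toy_model):
        df = lipid_content_scan(
            toy_model, toy_biomass_spec(), [0.004, 0.2, 0.4, 0.6],
            mode="fixed_uptake", uptake=4.0,
        )
        assert (df["status"] == "optimal").all()
        mu = df["growth_rate"].to_numpy()
        assert all(b < a for a, b in zip(mu, mu[1:]))  # growth declines
        acl = df["acl_flux"].to_numpy()
        assert all(b > a for a, b in zip(acl, acl[1:]))  # Acl demand rises
        nadph = df["nadph_production"].to_numpy()
        assert all(b > a for a, b in zip(nadph, nadph[1:]))  # NADPH demand rises
        assert df["uptake"].iloc[0] == pytest.approx(4.0, abs=1e-6)

    def test_fixed_growth_scan_uptake_rises(self, toy_model):
        df = lipid_content_scan(
            toy_model, toy_biomass_spec(), [0.004, 0.3, 0.6],
            mode="fixed_growth", growth_rate=0.2,
        )
        upt = df["uptake"].to_numpy()
        assert all(b > a for a, b in zip(upt, upt[1:]))
        assert df["growth_rate"].iloc[0] == pytest.approx(0.2)

    def test_single_point_equals_plain_solve(self, toy_model):
        df = lipid_content_scan(
            toy_model, toy_biomass_spec(), [0.004], mode="fixed_uptake", uptake=4.0
        )
        sol = solve_fba(toy_model, parsimonious=False)
        assert df["growth_rate"].iloc[0] == pytest.approx(
            sol.objective_value, abs=1e-8
        )

    def test_unknown_mode_rejected(self, toy_model):
        with pytest.raises(ModelError):
            lipid_content_scan(toy_model, toy_biomass_spec(), [0.1], mode="bogus")


class TestOxygenThresholds:
    def test_growth_threshold_exceeds_lipid_threshold(self, toy_model):
        """Growth responds to O2 limitation well before the lipogenesis
        phase does (the basis of the reduced-aeration strategy)."""
        grid = list(np.arange(0.0, 10.25, 0.25))
        growth_curve = robustness_scan(
            toy_model, "EX_o2", grid, objectives={"growth": "BIOMASS"}
        )
        lipo = toy_model.copy()
        lipo.set_bounds("BIOMASS", 0.0, 0.0)
        lipo.set_uptake("EX_glc", 0.35, fixed=True)
        lipid_curve = robustness_scan(
            lipo, "EX_o2", grid, objectives={"lipid": "DM_fa"},
            reporters=["EX_pyr"],
        )
        thr_growth = o2_thresholds(growth_curve)["growth"]
        thr_lipid = o2_thresholds(lipid_curve)["lipid"]
        assert thr_growth > thr_lipid > 0

    def test_low_oxygen_causes_pyruvate_overflow(self, toy_model):
        """Below the lipid threshold, lipid output falls and pyruvate is
        excreted; at generous O2 there is no overflow."""
        lipo = toy_model.copy()
        lipo.set_bounds("BIOMASS", 0.0, 0.0)
        lipo.set_uptake("EX_glc", 0.35, fixed=True)
        curve = robustness_scan(
            lipo, "EX_o2", [0.5, 2.0], objectives={"lipid": "DM_fa"},
            reporters=["EX_pyr"],
        )
        low, high = curve.responses
        assert low["status"] == high["status"] == "optimal"
        assert low["objective_value"] < high["objective_value"]
        assert low["EX_pyr"] > 1e-6
        assert high["EX_pyr"] == pytest.approx(0.0, abs=1e-6)


class TestNADPHSources:
    def test_producers_identified(self, nadph_model):
        producers = nadph_producing_reactions(nadph_model)
        assert {"PPP", "MTLDH", "THD2"} <= set(producers)
        assert "FAS" not in producers  # consumes NADPH

    def test_source_restriction_blocks_other_producers(self, nadph_model):
        restricted = restrict_nadph_source(nadph_model, "PPP", TOY_SOURCES)
        assert restricted.reactions["THD2"].upper_bound == 0.0
        assert restricted.reactions["MTLDH"].upper_bound == 0.0
        # original untouched: restricting then discarding restores bounds
        assert nadph_model.reactions["THD2"].upper_bound > 0

    def test_mannitol_cycle_net_stoichiometry(self, nadph_model):
        """Summing the cycle reactions gives the net transhydrogenation
        NADH + NADP+ + ATP -> NAD+ + NADPH + ADP + Pi."""
        net = {}
        for rid in ("FK", "M1PDH", "M1Pase", "MTLDH"):
            for met, coef in nadph_model.reactions[rid].stoichiometry.items():
                net[met] = net.get(met, 0.0) + coef
        net = {m: c for m, c in net.items() if abs(c) > 1e-9}
        assert net == {
            "nadh_c": -1.0, "nadp_c": -1.0, "atp_c": -1.0,
            "nad_c": 1.0, "nadph_c": 1.0, "adp_c": 1.0, "pi_c": 1.0,
        }

    def test_yield_ordering_and_closed_forms(self, nadph_model):
        """Transhydrogenase >= PPP >= ATP-dependent cycles, with the exact
        toy values 7U/40, 84U/487 and 7U/47."""
        c = LipogenesisConstraints(uptake=0.35, citrate_exchange=None)
        df = nadph_yield_comparison(nadph_model, TOY_SOURCES, c).set_index("source")
        ppp = df.loc["PPP", "lipid_flux"]
        man = df.loc["MANNITOL_CYCLE", "lipid_flux"]
        th = df.loc["TRANSHYDROGENASE", "lipid_flux"]
        assert ppp == pytest.approx(LIPID_PER_UPTAKE * 0.35, rel=1e-7)
        assert man == pytest.approx(MANNITOL_LIPID_PER_UPTAKE * 0.35, rel=1e-7)
        assert th == pytest.approx(TH_LIPID_PER_UPTAKE * 0.35, rel=1e-7)
        assert th >= ppp >= man
        assert df.loc["PPP", "relative_to_reference"] == pytest.approx(1.0)

    def test_unknown_source_rejected(self, nadph_model):
        with pytest.raises(ModelError):
            restrict_nadph_source(nadph_model, "MAGIC", TOY_SOURCES)


class TestTheoreticalYield:
    def test_citrate_yield_is_one_mol_per_mol(self, toy_model):
        """The glycolysis+citrate-synthesis lump fixes the citrate ceiling
        at 1 mol per mol glucose."""
        ty = theoretical_yield(toy_model, "EX_cit", "EX_glc")
        assert ty.mol_per_mol == pytest.approx(1.0, abs=1e-8)
        assert ty.g_per_g == pytest.approx(192.12 / 180.16, rel=1e-3)

    def test_percent_of_theoretical_bounds(self, toy_model):
        ty = theoretical_yield(toy_model, "DM_fa", "EX_glc")
        assert ty.mol_per_mol > 0
        y_obs = 0.5 * ty.mol_per_mol
        assert percent_of_theoretical(y_obs, ty.mol_per_mol) == pytest.approx(50.0)
        with pytest.raises(ModelError):
            percent_of_theoretical(-0.1, 1.0)
        with pytest.raises(ModelError):
            percent_of_theoretical(0.1, 0.0)

    def test_lipogenesis_yield_below_theoretical(self, toy_model):
        """The maintenance-constrained lipogenesis yield is a genuine
        fraction of the stoichiometric ceiling."""
        ty = theoretical_yield(toy_model, "DM_fa", "EX_glc")
        pct = percent_of_theoretical(LIPID_PER_UPTAKE, ty.mol_per_mol)
        assert 0.0 < pct < 100.0


class TestSubstrateScreen:
    def test_fixture_confusion_matrix(self):
        model, truth = toy_screen_fixture()
        report = substrate_screen(model, truth, free_exchanges=["EX_o2", "EX_co2"])
        assert (report.tp, report.fp, report.tn, report.fn) == (2, 1, 1, 0)
        assert report.accuracy == pytest.approx(0.75)

    def test_truth_equal_to_predictions_gives_accuracy_one(self):
        model, truth = toy_screen_fixture()
        report = substrate_screen(model, truth, free_exchanges=["EX_o2", "EX_co2"])
        predicted = {r["substrate"]: r["predicted"] for r in report.records}
        perfect = substrate_screen(model, predicted, free_exchanges=["EX_o2", "EX_co2"])
        assert perfect.accuracy == pytest.approx(1.0)
        assert perfect.fp == perfect.fn == 0

    def test_sucrose_without_invertase_predicts_no_growth(self):
        model, _ = toy_screen_fixture()
        report = substrate_screen(
            model, {"EX_sucr": False}, free_exchanges=["EX_o2", "EX_co2"]
        )
        assert report.records[0]["predicted"] is False

    def test_missing_exchange_is_untestable(self, toy_model):
        report = substrate_screen(
            toy_model, {"EX_glc": True, "EX_xyl": True},
            free_exchanges=["EX_o2", "EX_co2"],
        )
        assert report.untestable == ["EX_xyl"]
        assert report.tp + report.fp + report.tn + report.fn == 1

    def test_empty_truth_rejected(self, toy_model):
        with pytest.raises(ModelError):
            substrate_screen(toy_model, {})
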