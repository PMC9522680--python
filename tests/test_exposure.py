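"""Scenario source terms, intake arithmetic, fold ratios, ach calibration."""

import dataclasses
import math

import pytest

from evpexposure.airmodel import SourceProfile, average_concentration, simulate_box
from evpexposure.exposure import (
    BreathingModel,
    ConstituentSpec,
    NotAvailableError,
    Scenario,
    UsageModel,
    calibrate_ach,
    fold_difference,
    fold_difference_from_rates,
    intake,
    limit_reference_intake,
    run_scenario,
    source_rate,
    transient_average,
)

CAR = Scenario("car_closed", 3.17, 25.0621, 1.0, 2, 4, "evp")
CAR_CIG = dataclasses.replace(CAR, source_kind="cigarette")


class TestSourceRate:
    def test_evp_rate_scales_with_users_and_consumption(self, registry):
        rate = source_rate(registry["nicotine"], CAR)
        assert rate == pytest.approx(2 * (902.0 / 16.0) * 4.22, rel=1e-12)

    def test_cigarette_rate_uses_sidestream(self, registry):
        assert source_rate(registry["nicotine"], CAR_CIG) == pytest.approx(11200.0)

    def test_below_mdl_constituent_emits_nothing(self, registry):
        assert source_rate(registry["acetaldehyde"], CAR) == 0.0

    def test_missing_sidestream_is_not_available(self, registry):
        with pytest.raises(NotAvailableError):
            source_rate(registry["propylene_glycol"], CAR_CIG)


class TestIntake:
    def test_default_ventilation_factor(self):
        assert BreathingModel().minute_ventilation_m3_per_h == pytest.approx(0.36)

    @pytest.mark.parametrize(
        "conc,hours,expected",
        [(500.0, 8.0, 1440.0), (0.0, 3.0, 0.0), (10.0, 1.0, 3.6)],
    )
    def test_intake_formula(self, conc, hours, expected):
        assert intake(conc, hours) == pytest.approx(expected)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            intake(-1.0, 1.0)


class TestLimitReferenceIntake:
    @pytest.mark.parametrize(
        "limit,expected",
        [
            (500.0, 1440.0),  # nicotine PEL
            (10000.0, 28800.0),  # glycerin PEL / PG guideline
            (920.0, 2650.0),  # formaldehyde (2649.6 before rounding)
            (360000.0, 1036800.0),  # acetaldehyde
            (250.0, 720.0),  # acrolein
        ],
    )
    def test_eight_hour_reference_values(self, limit, expected):
        assert limit_reference_intake(limit) == expected

    def test_unrounded_value_available(self):
        assert limit_reference_intake(920.0, rounded=False) == pytest.approx(2649.6)

    def test_missing_limit_gives_none(self):
        assert limit_reference_intake(None) is None

    def test_nonpositive_limit_rejected(self):
        with pytest.raises(ValueError):
            limit_reference_intake(0.0)


class TestRunScenario:
    def test_intake_ratio_equals_emission_factor_ratio(self, registry):
        results = {r.constituent: r for r in run_scenario(CAR, list(registry.values()))}
        fa = registry["propylene_glycol"].emission_factor
        fb = registry["nicotine"].emission_factor
        ratio = results["propylene_glycol"].intake / results["nicotine"].intake
        assert ratio == pytest.approx(fa / fb, rel=1e-9)

    def test_no_users_no_intake(self, registry):
        quiet = dataclasses.replace(CAR, n_users=0)
        for r in run_scenario(quiet, list(registry.values())):
            if r.status == "COMPUTED":
                assert r.intake == 0.0

    def test_statuses_propagate(self, registry):
        evp = {r.constituent: r for r in run_scenario(CAR, list(registry.values()))}
        assert evp["acetaldehyde"].status == "BELOW_MDL"
        assert evp["acetaldehyde"].intake == 0.0
        cig = {r.constituent: r for r in run_scenario(CAR_CIG, list(registry.values()))}
        assert cig["propylene_glycol"].status == "NA"
        assert math.isnan(cig["propylene_glycol"].intake)
        assert cig["acetaldehyde"].status == "COMPUTED"
        assert cig["acetaldehyde"].intake > 0

    def test_doubling_duration_doubles_intake_at_steady_state(self, registry):
        base = dataclasses.replace(CAR, duration=4.0)  # ach*T ~ 100 >> 1
        double = dataclasses.replace(CAR, duration=8.0)
        spec = [registry["nicotine"]]
        a = run_scenario(base, spec)[0].intake
        b = run_scenario(double, spec)[0].intake
        assert b == pytest.approx(2.0 * a, rel=0.01)

    def test_evp_intakes_orders_of_magnitude_below_limits(self, registry):
        from evpexposure.io import default_scenarios

        for scenario in default_scenarios():
            for r in run_scenario(scenario, list(registry.values())):
                if r.status == "COMPUTED" and r.limit_reference_intake:
                    assert r.intake < r.limit_reference_intake / 100.0


class TestFoldDifference:
    def test_identical_sources_give_one(self):
        assert fold_difference(5.0, 5.0) == 1.0

    def test_zero_evp_reported_as_infinite(self):
        assert fold_difference(3.0, 0.0) == math.inf

    def test_formaldehyde_rate_ratio(self, registry):
        fold = fold_difference_from_rates(registry["formaldehyde"])
        assert fold == pytest.approx(700.0 / (0.0083 * 902.0 / 16.0), rel=1e-12)
        assert round(fold, -2) == 1500.0

    def test_nicotine_rate_ratio(self, registry):
        fold = fold_difference_from_rates(registry["nicotine"])
        assert fold == pytest.approx(5600.0 / (4.22 * 902.0 / 16.0), rel=1e-12)
        assert fold >= 20.0

    def test_fold_invariant_across_scenarios(self, registry):
        from evpexposure.io import default_scenarios

        folds = set()
        for scenario in default_scenarios():
            evp = {r.constituent: r for r in run_scenario(scenario, [registry["nicotine"]])}
            cig_sc = dataclasses.replace(scenario, source_kind="cigarette")
            cig = {r.constituent: r for r in run_scenario(cig_sc, [registry["nicotine"]])}
            folds.add(
                round(fold_difference(cig["nicotine"].intake, evp["nicotine"].intake), 9)
            )
        assert len(folds) == 1


class TestCalibrateAch:
    def test_round_trip_with_forward_simulation(self):
        V, lam0, S, T = 81.0, 1.9, 700.0, 4.0
        state = simulate_box(V, lam0, SourceProfile.continuous(S), T)
        target = average_concentration(state)
        recovered = calibrate_ach(V, T, S, target)
        assert recovered == pytest.approx(lam0, rel=0.02)

    def test_steady_state_target_recovers_rate(self):
        V, lam0, S, T = 10.0, 40.0, 1000.0, 10.0  # lam0*T >> 1
        target = transient_average(S, V, lam0, T)
        assert calibrate_ach(V, T, S, target) == pytest.approx(lam0, rel=0.02)

    def test_calibrated_average_matches_target(self):
        target = 4.5625
        ach = calibrate_ach(81.0, 4.0, 713.7075, target)
        assert transient_average(713.7075, 81.0, ach, 4.0) == pytest.approx(
            target, rel=1e-6
        )

    def test_unreachable_target_rejected_with_bound(self):
        V, S, T = 10.0, 100.0, 1.0
        bound = S * T / (2.0 * V)
        with pytest.raises(ValueError, match="not achievable"):
            calibrate_ach(V, T, S, bound * 1.1)


class TestValidation:
    def test_scenario_invariants(self):
        with pytest.raises(ValueError, match="volume"):
            Scenario("x", -1.0, 1.0, 1.0, 1, 2)
        with pytest.raises(ValueError, match="n_users"):
            Scenario("x", 1.0, 1.0, 1.0, 3, 2)

    def test_below_mdl_spec_requires_zero_factor(self):
        with pytest.raises(ValueError, match="below-MDL"):
            ConstituentSpec("x", emission_factor=1.0, below_mdl=True)

    def test_usage_model_positivity(self):
        with pytest.raises(ValueError):
            UsageModel(evp_use_hours=0.0)
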