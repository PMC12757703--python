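import numpy as np
import pytest
from click.testing import CliRunner

from nicotine_pbpk.cli import main as cli_main
from nicotine_pbpk.pk_metrics import nca
from nicotine_pbpk.scenarios import (
    builtin_registry,
    ecigarette_two_sessions,
    generate_fixture_profile,
    get_scenario,
    population_range,
    resolve_dose_events,
    run_scenario,
    sensitivity_analysis,
)


class TestRegistry:
    def test_nine_scenarios(self):
        assert len(builtin_registry()) == 9

    def test_ecigarette_total_dose(self):
        spec = get_scenario("ecigarette_18mgml_10puffs")
        events = resolve_dose_events(spec)
        assert sum(e.amount for e in events) == pytest.approx(1.4, abs=1e-12)

    def test_bolus_literal_and_interpretation_stored(self):
        spec = get_scenario("iv_bolus")
        assert spec.dose["literal"] == "0.2 ug/kg/mL"
        assert spec.dose["amount_mg"] == pytest.approx(1.7)

    def test_per_kg_infusion_resolves_with_body_weight(self):
        spec = get_scenario("iv_infusion_0.5ugkgmin_30min")
        (ev,) = resolve_dose_events(spec, body_weight=70.0)
        assert ev.amount == pytest.approx(0.5 * 70 * 30 / 1000)  # 1.05 mg
        assert ev.duration == 0.5

    def test_multiple_infusion_schedule(self):
        spec = get_scenario("iv_multiple_infusion_2.5ugkgmin_30min")
        events = resolve_dose_events(spec)
        assert [e.start for e in events] == [0.0, 1.5]
        assert sum(e.amount for e in events) == pytest.approx(10.5)

    def test_two_session_ecigarette_variant(self):
        spec = ecigarette_two_sessions()
        events = resolve_dose_events(spec)
        assert sum(e.amount for e in events) == pytest.approx(2.8)

    def test_unknown_dose_kind_rejected(self):
        import dataclasses

        spec = dataclasses.replace(
            get_scenario("iv_bolus"), dose={"kind": "mystery_unit"}
        )
        with pytest.raises(ValueError, match="mystery_unit"):
            resolve_dose_events(spec)

    def test_yaml_round_trip(self, tmp_path):
        spec = get_scenario("smoking_2.4mg_10min")
        path = tmp_path / "scenario.yaml"
        spec.to_yaml(path)
        assert type(spec).from_yaml(path) == spec


class TestRunScenario:
    def test_comparison_table_covers_all_observed_parameters(self, registry_runs):
        for spec in builtin_registry():
            _, _, table = registry_runs[spec.name]
            assert set(table["parameter"]) == set(spec.observed)

    def test_determinism_bit_identical_rerun(self, registry_runs):
        spec = get_scenario("iv_infusion_0.5ugkgmin_30min")
        res_a, params_a, _ = registry_runs[spec.name]
        res_b, params_b, _ = run_scenario(spec)
        assert np.array_equal(res_a.plasma_concentration, res_b.plasma_concentration)
        assert params_a == params_b

    def test_mass_balance_on_every_scenario(self, registry_runs):
        for res, _, _ in registry_runs.values():
            assert res.mass_balance_error < 1e-4


class TestSensitivity:
    def test_doubling_total_clearance_halves_auc(self):
        result = sensitivity_analysis(
            "cl_total", [50.0, 100.0], "iv_infusion_0.5ugkgmin_30min"
        )
        auc = result.table["auc_inf"].to_numpy()
        assert auc[1] / auc[0] == pytest.approx(0.5, rel=0.02)

    def test_hematocrit_moves_calibrated_kp_monotonically(self):
        from nicotine_pbpk.compound_physiology import (
            build_reference_human,
            calibrate_partition_coefficients,
            nicotine,
        )
        import dataclasses

        kp_at = {}
        for hct in (0.30, 0.44, 0.55):
            phys = dataclasses.replace(build_reference_human(), hematocrit=hct)
            kp_at[hct] = calibrate_partition_coefficients(phys, nicotine())["muscle"]
        # larger hematocrit -> smaller plasma volume -> larger tissue Kp term
        assert kp_at[0.30] < kp_at[0.44] < kp_at[0.55]

    def test_singleton_value_single_row(self):
        result = sensitivity_analysis("cl_hepatic", [40.0])
        assert len(result.table) == 1

    @pytest.mark.parametrize(
        "param,value",
        [("fu_plasma", 1.5), ("hematocrit", 0.0), ("cl_hepatic", -1.0)],
    )
    def test_out_of_bounds_values_rejected(self, param, value):
        with pytest.raises(ValueError):
            sensitivity_analysis(param, [value])

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="parameter"):
            sensitivity_analysis("kp_lung", [1.0])


class TestPopulationRange:
    def test_zero_cv_degenerate_spread(self):
        out = population_range(
            "iv_infusion_0.5ugkgmin_30min", n=2, cv_cl=0.0, cv_kp=0.0, seed=1
        )
        for stats in out.values():
            assert stats["min"] == pytest.approx(stats["max"], rel=1e-12)
            assert stats["min"] == pytest.approx(stats["geometric_mean"], rel=1e-12)

    def test_seeded_reproducibility_and_spread_grows_with_cv(self):
        kwargs = dict(n=6, cv_kp=0.0, seed=42)
        small = population_range("iv_infusion_0.5ugkgmin_30min", cv_cl=0.1, **kwargs)
        again = population_range("iv_infusion_0.5ugkgmin_30min", cv_cl=0.1, **kwargs)
        large = population_range("iv_infusion_0.5ugkgmin_30min", cv_cl=0.4, **kwargs)
        assert small["auc_inf"] == again["auc_inf"]
        ratio = lambda s: s["auc_inf"]["max"] / s["auc_inf"]["min"]
        assert ratio(small) > 1.0
        assert ratio(large) > ratio(small)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            population_range("iv_bolus", n=1)


class TestFixtures:
    def test_noiseless_mono_is_exact(self):
        p = generate_fixture_profile("mono", {"c0": 10.0, "lambda": 0.5})
        assert p.concentrations[0] == pytest.approx(
            10.0 * np.exp(-0.5 * p.times[0]), rel=1e-12
        )

    def test_seeded_noise_reproducible(self):
        a = generate_fixture_profile("mono", noise_cv=0.2, seed=5)
        b = generate_fixture_profile("mono", noise_cv=0.2, seed=5)
        c = generate_fixture_profile("mono", noise_cv=0.2, seed=6)
        assert np.array_equal(a.concentrations, b.concentrations)
        assert not np.array_equal(a.concentrations, c.concentrations)

    def test_nca_round_trip_recovers_inputs(self):
        lam, c0 = 0.5, 10.0
        times = np.arange(0.0, 24.01, 0.25)
        p = generate_fixture_profile(
            "mono", {"c0": c0, "lambda": lam}, times=times
        )
        params = nca(p)
        assert params.lambda_z == pytest.approx(lam, abs=1e-6)
        assert params.t_half == pytest.approx(np.log(2) / lam, abs=1e-6)
        assert params.auc_inf == pytest.approx(c0 / lam, rel=1e-2)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            generate_fixture_profile("tri")


class TestCLI:
    def test_fixtures_then_nca(self, tmp_path):
        runner = CliRunner()
        fixture_csv = tmp_path / "fixture.csv"
        out_csv = tmp_path / "nca.csv"
        res = runner.invoke(
            cli_main, ["fixtures", "--kind", "mono", "--out", str(fixture_csv)]
        )
        assert res.exit_code == 0, res.output
        res = runner.invoke(
            cli_main, ["nca", str(fixture_csv), "--out", str(out_csv)]
        )
        assert res.exit_code == 0, res.output
        assert out_csv.exists()

    def test_simulate_registry_scenario(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["simulate", "iv_infusion_0.5ugkgmin_30min", "--out", str(tmp_path)],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "iv_infusion_0.5ugkgmin_30min.profile.csv").exists()
        assert (tmp_path / "iv_infusion_0.5ugkgmin_30min.log.json").exists()

    def test_sensitivity_command(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "sens.csv"
        res = runner.invoke(
            cli_main,
            ["sensitivity", "--param", "cl_total", "--values", "50",
             "--out", str(out)],
        )
        assert res.exit_code == 0, res.output
        assert out.exists()
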