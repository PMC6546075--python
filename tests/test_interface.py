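"""Tests for config serialisation, packaged fixtures, overlays and the CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from cellcycler import (
    CellModelConfig,
    ConfigurationError,
    DoseSchedule,
    DrugSpec,
    EffectCoefficients,
    PKConfig,
    RunConfig,
    TumourConfig,
    fixture_names,
    fixture_path,
    load_fixture,
    read_config,
    read_overlay,
    simulate,
    synthesize_control,
    write_config,
)
from cellcycler.cli import main as cli_main


def _full_config() -> RunConfig:
    return RunConfig(
        cell=CellModelConfig(40, 26.0, (0.3, 0.3, 0.3, 0.1)),
        tumour=TumourConfig.from_diameter(7.0, 0.3),
        drugs=(
            DrugSpec(
                name="alpha",
                pk=PKConfig("one_compartment", 2.0, 0.2, absorption_rate=1.5),
                schedule=DoseSchedule((0.0, 24.0)),
                effects=EffectCoefficients("S", 0.5, 0.1, 0.2),
            ),
            DrugSpec(
                name="beta",
                pk=PKConfig("step_infusion", infusion_levels=((0.0, 12.0, 1.5),)),
                schedule=DoseSchedule(),
                effects=EffectCoefficients("all", 0.1, 0.0, 0.0),
            ),
        ),
        horizon=100.0,
        output_step=1.0,
    )


class TestConfigRoundTrip:
    def test_write_then_read_is_identity(self, tmp_path):
        config = _full_config()
        path = tmp_path / "run.csv"
        write_config(config, path)
        assert read_config(path) == config

    def test_defaults_round_trip(self, tmp_path):
        config = RunConfig()
        path = tmp_path / "run.csv"
        write_config(config, path)
        assert read_config(path) == config

    def test_missing_required_key_is_named(self, tmp_path):
        path = tmp_path / "broken.csv"
        frame = pd.DataFrame(
            {"parameter": ["n_compartments"], "value": ["50"]}
        )
        frame.to_csv(path, index=False)
        with pytest.raises(ConfigurationError, match="doubling_time_h"):
            read_config(path)

    def test_non_numeric_value_is_named(self, tmp_path):
        path = tmp_path / "run.csv"
        write_config(RunConfig(), path)
        text = path.read_text().replace("doubling_time_h,24.0", "doubling_time_h,fast")
        path.write_text(text)
        with pytest.raises(ConfigurationError, match="doubling_time_h"):
            read_config(path)

    def test_unknown_key_warns(self, tmp_path):
        path = tmp_path / "run.csv"
        write_config(RunConfig(), path)
        with open(path, "a") as fh:
            fh.write("flux_capacitance,88\n")
        with pytest.warns(UserWarning, match="flux_capacitance"):
            read_config(path)

    def test_g2_derived_when_absent(self, tmp_path):
        path = tmp_path / "run.csv"
        write_config(RunConfig(), path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("phase_g2")]
        path.write_text("\n".join(lines) + "\n")
        config = read_config(path)
        assert config.cell.phase_fractions == pytest.approx((0.2, 0.3, 0.4, 0.1))

    def test_invalid_fractions_raise_on_read(self, tmp_path):
        path = tmp_path / "run.csv"
        write_config(RunConfig(), path)
        text = path.read_text().replace("phase_g1,0.2", "phase_g1,0.5")
        path.write_text(text)
        with pytest.raises(ConfigurationError, match="sum to 1"):
            read_config(path)


class TestFixtures:
    def test_known_names(self):
        assert fixture_names() == ("case1", "case2", "case3")
        with pytest.raises(KeyError):
            load_fixture("case9")

    def test_case1_matches_published_settings(self, case1):
        assert case1.config.cell.doubling_time == 24.0
        assert case1.config.cell.phase_fractions == (0.2, 0.3, 0.4, 0.1)
        assert case1.config.tumour.initial_diameter == 6.8
        assert case1.config.tumour.layer_thickness == 0.24
        taxol = {d.name: d for d in case1.config.drugs}["Taxol"]
        assert taxol.effects.phase_of_action == "M"
        assert taxol.effects.apoptosis_coef == 1.0
        assert taxol.pk.dose_over_v == 1.0 and taxol.pk.elimination_rate == 0.1

    def test_case2_matches_published_settings(self):
        case = load_fixture("case2")
        assert case.config.cell.doubling_time == 30.0
        assert case.config.cell.phase_fractions == (0.5, 0.25, 0.15, 0.1)
        assert case.config.tumour.initial_diameter == 6.32
        assert case.config.tumour.layer_thickness == 0.46
        gem = {d.name: d for d in case.config.drugs}["Gemcitabine"]
        assert gem.effects.phase_of_action == "S"
        assert gem.effects.damage_coef == 10.0
        assert gem.effects.apoptosis_coef == 0.8

    def test_case3_matches_published_settings(self):
        case = load_fixture("case3")
        assert case.config.cell.doubling_time == 18.0
        assert case.config.cell.phase_fractions == (0.49, 0.33, 0.09, 0.09)
        assert case.config.tumour.initial_diameter == 8.30
        assert case.config.tumour.layer_thickness == 0.50
        doc = {d.name: d for d in case.config.drugs}["Docetaxel"]
        assert doc.pk.elimination_rate == 0.0025
        assert doc.effects.phase_of_action == "M"

    def test_fixture_files_pass_validation(self):
        for name in fixture_names():
            assert fixture_path(name).exists()
            read_config(fixture_path(name))  # raises on any violation

    @pytest.mark.parametrize("name", ["case1", "case2", "case3"])
    def test_every_arm_simulates_to_horizon(self, name):
        from dataclasses import replace

        case = load_fixture(name)
        for arm in case.arms:
            spec = replace(
                case.arm_spec(arm), rtol=1e-6, atol=1e-8, output_step=8.0
            )
            traj = simulate(spec)
            assert traj.times[-1] == case.config.horizon

    def test_unknown_arm_rejected(self, case1):
        with pytest.raises(KeyError, match="unknown arm"):
            case1.arm_config("placebo")

    def test_arm_resets_other_drug_schedules(self, case1):
        config = case1.arm_config("taxol")
        by_name = {d.name: d for d in config.drugs}
        assert by_name["Taxol"].schedule.dose_times == (0.0, 168.0, 336.0)
        assert by_name["EGFRi"].schedule.dose_times == ()


class TestOverlayIO:
    def test_time_day_converted_to_hours(self, tmp_path):
        path = tmp_path / "overlay.csv"
        path.write_text("time_day,diameter\n0,6.8\n7,7.9\n")
        overlay = read_overlay(path)
        np.testing.assert_allclose(overlay.time_h, [0.0, 168.0])

    def test_volume_dialects(self, tmp_path):
        path = tmp_path / "overlay.csv"
        path.write_text("time_h,volume\n0,100\n24,200\n")
        sphere = read_overlay(path, volume_dialect="sphere")
        bare = read_overlay(path, volume_dialect="cube_root")
        np.testing.assert_allclose(sphere.diameter_mm, (6 * np.array([100, 200]) / np.pi) ** (1 / 3))
        np.testing.assert_allclose(bare.diameter_mm, np.array([100, 200]) ** (1 / 3))

    def test_undeclared_units_rejected(self, tmp_path):
        path = tmp_path / "overlay.csv"
        path.write_text("time,diameter\n0,6.8\n24,7.0\n")
        with pytest.raises(ConfigurationError, match="time_h"):
            read_overlay(path)


class TestSynthesizeControl:
    def test_zero_noise_is_exact_line(self):
        t = np.arange(0, 169, 24.0)
        overlay = synthesize_control(3.4, 0.24, 24.0, 0.0, t)
        expected = 2 * (3.4 + np.log(2) / 24.0 * 0.24 * t)
        np.testing.assert_allclose(overlay.diameter_mm, expected, rtol=1e-12)

    def test_seed_reproducibility(self):
        t = np.arange(8) * 168.0
        a = synthesize_control(3.4, 0.24, 24.0, 0.1, t, seed=42)
        b = synthesize_control(3.4, 0.24, 24.0, 0.1, t, seed=42)
        c = synthesize_control(3.4, 0.24, 24.0, 0.1, t, seed=43)
        np.testing.assert_array_equal(a.diameter_mm, b.diameter_mm)
        assert not np.array_equal(a.diameter_mm, c.diameter_mm)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            synthesize_control(3.4, 0.24, 24.0, -0.1, np.arange(3.0))


class TestCLI:
    def test_simulate_fixture_arm_writes_outputs(self, tmp_path):
        runner = CliRunner()
        prefix = tmp_path / "run"
        result = runner.invoke(
            cli_main,
            ["simulate", "--fixture", "case1", "--arm", "taxol", "--out-prefix", str(prefix)],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "run_trajectory.csv").exists()
        summary = pd.read_csv(tmp_path / "run_summary.csv")
        assert "diameter_loss_mm" in summary.columns

    def test_simulate_from_config_file(self, tmp_path):
        path = tmp_path / "run.csv"
        config = RunConfig(horizon=24.0, output_step=2.0)
        write_config(config, path)
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["simulate", "--config", str(path), "--out-prefix", str(tmp_path / "x")],
        )
        assert result.exit_code == 0, result.output
        assert "final total volume: 2" in result.output

    def test_spread_reports_sigma(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["spread", "--n", "50", "--td", "24"])
        assert result.exit_code == 0, result.output
        frame = pd.read_csv(pd.io.common.StringIO(result.output.split("wrote")[0]))
        assert frame.loc[0, "sigma_sim_h"] == pytest.approx(3.4, abs=0.35)

    def test_fit_control_recovers_generating_values(self, tmp_path):
        t = np.arange(8) * 168.0
        overlay = synthesize_control(3.4, 0.24, 24.0, 0.0, t)
        path = tmp_path / "control.csv"
        pd.DataFrame({"time_h": overlay.time_h, "diameter": overlay.diameter_mm}).to_csv(
            path, index=False
        )
        runner = CliRunner()
        result = runner.invoke(cli_main, ["fit-control", "--overlay", str(path), "--td", "24"])
        assert result.exit_code == 0, result.output
        assert "R0 estimate: 3.4000 mm" in result.output
        assert "growing layer estimate: 0.2400 mm" in result.output

    def test_fixtures_command_emits_configs(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["fixtures", "--dest", str(tmp_path)])
        assert result.exit_code == 0, result.output
        for name in fixture_names():
            assert (tmp_path / f"{name}.csv").exists()

    def test_conflicting_sources_usage_error(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["simulate"])
        assert result.exit_code == 2
        assert "exactly one of" in result.output

    def test_missing_arm_usage_error(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["simulate", "--fixture", "case1"])
        assert result.exit_code == 2

    def test_validation_error_exits_nonzero(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("parameter,value\nn_compartments,50\n")
        runner = CliRunner()
        result = runner.invoke(cli_main, ["simulate", "--config", str(path)])
        assert result.exit_code == 1
        assert "missing required" in result.output
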