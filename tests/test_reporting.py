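"""End-to-end report runs, method comparison, and the CLI surface."""

import pandas as pd
import pytest
from click.testing import CliRunner

from workrisk import RunConfig, compare_methods, run_assessment, case_study_fixture
from workrisk.cli import main
from workrisk.exposure import MeasurementRecord, write_measurements
from workrisk.gbz import WeightMode


@pytest.fixture()
def fixture_csv(tmp_path):
    path = tmp_path / "measurements.csv"
    write_measurements(case_study_fixture(), path)
    return path


class TestRunAssessment:
    def test_case_study_summary_row(self, fixture_csv, tmp_path):
        bundle = run_assessment(RunConfig(measurements=fixture_csv, out_dir=tmp_path / "out"))
        summary = pd.read_csv(bundle.paths["summary"])
        chlorine = summary[summary.agent == "Chlorine"].iloc[0]
        assert chlorine.hq_max == 67.12
        assert chlorine.gbz_level.startswith("Level 0")
        report = bundle.paths["report"].read_text()
        assert "67.12" in report

    def test_every_fixture_agent_grades_level_0(self, fixture_csv, tmp_path):
        bundle = run_assessment(RunConfig(measurements=fixture_csv, out_dir=tmp_path / "out"))
        assert all(g.g == 0.0 for g in bundle.gradings)
        assert all(g.level.rank == "0" for g in bundle.gradings)

    def test_empty_measurement_file_errors_without_outputs(self, tmp_path):
        empty = tmp_path / "empty.csv"
        empty.write_text("post_id,agent,ca_mg_m3,limit_type,et_h_per_day,ef_day_per_year\n")
        out = tmp_path / "out"
        with pytest.raises(ValueError, match="no measurement rows"):
            run_assessment(RunConfig(measurements=empty, out_dir=out))
        assert not out.exists()

    def test_unknown_agent_listed_but_run_continues(self, tmp_path):
        records = case_study_fixture() + [MeasurementRecord("px", "Unobtainium", 1.0)]
        path = tmp_path / "m.csv"
        write_measurements(records, path)
        bundle = run_assessment(RunConfig(measurements=path, out_dir=tmp_path / "out"))
        assert bundle.unresolved == ["Unobtainium"]
        assert len(bundle.results) == len(case_study_fixture())
        assert "Unobtainium" in bundle.paths["report"].read_text()

    def test_regeneration_is_byte_identical(self, fixture_csv, tmp_path):
        cfg1 = RunConfig(measurements=fixture_csv, out_dir=tmp_path / "a", seed=3)
        cfg2 = RunConfig(measurements=fixture_csv, out_dir=tmp_path / "b", seed=3)
        b1, b2 = run_assessment(cfg1), run_assessment(cfg2)
        for key in ("results", "summary", "grading", "report"):
            assert b1.paths[key].read_bytes() == b2.paths[key].read_bytes(), key

    def test_summary_numbers_match_engine_values_under_rounding(self, fixture_csv, tmp_path):
        from workrisk.epa import format_hq

        bundle = run_assessment(RunConfig(measurements=fixture_csv, out_dir=tmp_path / "out"))
        summary = pd.read_csv(bundle.paths["summary"], dtype=str)
        by_agent = {s.agent: s for s in bundle.summaries}
        for _, row in summary.iterrows():
            assert row.hq_min == format_hq(by_agent[row.agent].hq_min)
            assert row.hq_max == format_hq(by_agent[row.agent].hq_max)

    def test_refined_mode_flows_through(self, fixture_csv, tmp_path):
        bundle = run_assessment(
            RunConfig(measurements=fixture_csv, out_dir=tmp_path / "out", mode=WeightMode.REFINED)
        )
        # below-limit posts now carry W_B = B > 0, so G > 0 everywhere
        assert all(g.g > 0 for g in bundle.gradings)


class TestCompareMethods:
    def test_case_study_phosphine_discordant_toluene_concordant(self, fixture_csv, tmp_path):
        bundle = run_assessment(RunConfig(measurements=fixture_csv, out_dir=tmp_path / "out"))
        comp = bundle.comparison.set_index(["agent", "post_id"])
        assert bool(comp.loc[("Phosphine", "phosphine-min"), "discordant"])
        assert bool(comp.loc[("Phosphine", "phosphine-max"), "discordant"])
        assert not bool(comp.loc[("Toluene", "toluene-obs"), "discordant"])

    def test_empty_inputs_give_empty_table(self):
        comp = compare_methods([], [])
        assert len(comp) == 0

    def test_key_mismatch_rejected(self, registry):
        from workrisk.epa import assess_post
        from workrisk.gbz import grade_agent

        rec = MeasurementRecord("p1", "Ammonia", 7.6)
        other = MeasurementRecord("p2", "Ammonia", 7.6)
        risk = assess_post(rec, registry)
        grading = grade_agent(other, registry.get("Ammonia"))
        with pytest.raises(ValueError, match="different post × agent keys"):
            compare_methods([risk], [grading])


class TestCli:
    def test_assess_fixture_end_to_end(self, fixture_csv, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["assess", "--measurements", str(fixture_csv), "--out", str(tmp_path / "out")],
        )
        assert result.exit_code == 0, result.output
        assert "67.12" in result.output
        assert (tmp_path / "out" / "summary.csv").exists()

    def test_fixture_then_simulate_round(self, tmp_path):
        runner = CliRunner()
        fx = runner.invoke(main, ["fixture", "--out", str(tmp_path / "fx.csv")])
        assert fx.exit_code == 0, fx.output

        scenario_yaml = tmp_path / "scenario.yaml"
        scenario_yaml.write_text(
            "n_posts: 5\nagents:\n  - name: Ammonia\n    gm_ratio: 0.3\n    gsd: 2.0\nseed: 1\n"
        )
        sim = runner.invoke(
            main,
            ["simulate", "--scenario", str(scenario_yaml), "--out", str(tmp_path / "sim")],
        )
        assert sim.exit_code == 0, sim.output
        assert (tmp_path / "sim" / "measurements.csv").exists()

    def test_compare_joins_written_outputs(self, fixture_csv, tmp_path):
        runner = CliRunner()
        out = tmp_path / "out"
        assert (
            runner.invoke(
                main, ["assess", "--measurements", str(fixture_csv), "--out", str(out)]
            ).exit_code
            == 0
        )
        cmp_result = runner.invoke(
            main,
            [
                "compare",
                "--results", str(out / "results.csv"),
                "--grading", str(out / "grading.csv"),
            ],
        )
        assert cmp_result.exit_code == 0, cmp_result.output
        assert "discordant" in cmp_result.output

    def test_assess_empty_file_exits_nonzero(self, tmp_path):
        empty = tmp_path / "empty.csv"
        empty.write_text("post_id,agent,ca_mg_m3,limit_type,et_h_per_day,ef_day_per_year\n")
        result = CliRunner().invoke(
            main, ["assess", "--measurements", str(empty), "--out", str(tmp_path / "out")]
        )
        assert result.exit_code != 0
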