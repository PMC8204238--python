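import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from cdmprivacy import (
    CdmTableSet,
    ConfigurationError,
    RunConfig,
    presets,
    run_all,
    run_phi_experiment,
    run_qi_experiment,
    run_sampling_experiment,
)
from cdmprivacy.cli import main as cli_main
from cdmprivacy.reporting import build_all_scenario_datasets


@pytest.fixture(scope="module")
def report(toy_cdm, registry):
    return run_phi_experiment(toy_cdm, registry)


@pytest.fixture(scope="module")
def reports(toy_cdm, registry):
    return run_qi_experiment(toy_cdm, registry)


class TestPhiReport:
    def test_sixteen_rows_plus_average(self, report):
        assert len(report) == 17
        assert report["variable"].iloc[-1] == "average"

    def test_every_gap_nonnegative(self, report):
        data = report[report["variable"] != "average"]
        assert (data["gap_pct_unique"] >= 0).all()
        assert (data["gap_max_ec"] >= 0).all()

    def test_average_row_is_column_mean(self, report):
        data = report[report["variable"] != "average"]
        avg = report[report["variable"] == "average"].iloc[0]
        assert avg["gap_pct_unique"] == pytest.approx(data["gap_pct_unique"].mean())
        assert avg["max_ec_safe_harbor"] == pytest.approx(data["max_ec_safe_harbor"].mean())

    def test_rows_recomputable_from_counts(self, report):
        """Reports carry no orphan values: percent columns equal
        100*unique/N for every data row."""
        data = report[report["variable"] != "average"]
        recomputed = 100.0 * data["unique_limited"] / data["n_records"]
        assert np.allclose(recomputed, data["pct_unique_limited"])


class TestQiReport:
    def test_seven_rows_plus_average(self, reports):
        summary, _ = reports
        assert len(summary) == 8
        assert summary["scenario"].iloc[-1] == "average"

    def test_partial_mass_bounded(self, reports):
        summary, _ = reports
        data = summary[summary["scenario"] != "average"]
        total = data[["pct_k1_limited", "pct_k2_limited", "pct_k5_limited"]].sum(axis=1)
        assert (total <= 100.0 + 1e-9).all()

    def test_distribution_covers_k1_to_20_per_dataset_policy(self, reports):
        _, dist = reports
        counts = dist.groupby(["dataset", "policy"])["k"].apply(
            lambda s: sorted(s.tolist())
        )
        assert all(v == list(range(1, 21)) for v in counts)
        assert set(dist["policy"]) == {"limited", "safe_harbor"}
        assert dist["dataset"].nunique() == 7


class TestSamplingReport:
    def test_grid_shape_and_averages(self, toy_cdm, registry):
        datasets = build_all_scenario_datasets(toy_cdm, registry)
        grid = run_sampling_experiment(datasets, sample_sizes=(10, 40), iterations=10, seed=4)
        assert len(grid) == 2 * (7 + 1)
        for n in (10, 40):
            block = grid[(grid["n"] == n) & (grid["dataset"] != "average")]
            avg = grid[(grid["n"] == n) & (grid["dataset"] == "average")].iloc[0]
            applicable = block[block["applicable"]]
            assert avg["gap"] == pytest.approx(applicable["gap"].mean())

    def test_not_applicable_cells_marked(self, toy_cdm, registry):
        datasets = build_all_scenario_datasets(toy_cdm, registry)
        grid = run_sampling_experiment(datasets, sample_sizes=(10**6,), iterations=2, seed=4)
        data = grid[grid["dataset"] != "average"]
        assert (~data["applicable"]).all()
        assert data["gap"].isna().all()


class TestRunAll:
    def test_deterministic_rerun(self, tmp_path):
        cfg = dict(synthetic=presets()["toy"], sample_sizes=(10, 30), iterations=5, seed=8)
        run_all(RunConfig(out_dir=tmp_path / "a", **cfg))
        run_all(RunConfig(out_dir=tmp_path / "b", **cfg))
        for name in ("phi_report", "qi_report", "qi_distribution", "sampling_qi"):
            a = (tmp_path / "a" / f"{name}.csv").read_text()
            b = (tmp_path / "b" / f"{name}.csv").read_text()
            assert a == b, name

    def test_input_mode_exclusive(self, tmp_path):
        with pytest.raises(ConfigurationError):
            RunConfig(out_dir=tmp_path, synthetic=None, input_cdm=None)
        with pytest.raises(ConfigurationError):
            RunConfig(out_dir=tmp_path, synthetic=presets()["toy"], input_cdm=tmp_path)

    def test_csv_export_reproduces_full_data_columns(self, toy_cdm, registry, tmp_path):
        """Loading a CDM from a CSV export yields the same full-data report
        as the in-memory tables (the --input-cdm path used for a real
        release)."""
        toy_cdm.to_csv(tmp_path / "cdm")
        loaded = CdmTableSet.from_csv(tmp_path / "cdm")
        a = run_phi_experiment(toy_cdm, registry)
        b = run_phi_experiment(loaded, registry)
        for col in ("n_records", "pct_unique_limited", "pct_unique_safe_harbor",
                    "gap_pct_unique", "max_ec_limited", "max_ec_safe_harbor"):
            assert np.allclose(a[col].astype(float), b[col].astype(float), equal_nan=True), col


class TestCli:
    def test_report_command_renders_mapping(self):
        result = CliRunner().invoke(cli_main, ["report", "--profile", "synpuf5pct"])
        assert result.exit_code == 0
        assert "death_date" in result.output

    def test_unknown_profile_exits_2(self):
        result = CliRunner().invoke(cli_main, ["report", "--profile", "bogus"])
        assert result.exit_code == 2

    def test_generate_then_evaluate(self, tmp_path):
        runner = CliRunner()
        r1 = runner.invoke(
            cli_main,
            ["generate", "--preset", "toy", "--seed", "3", "--out", str(tmp_path / "cdm")],
        )
        assert r1.exit_code == 0, r1.output
        r2 = runner.invoke(
            cli_main,
            ["evaluate", "--input-cdm", str(tmp_path / "cdm"), "--out", str(tmp_path / "rep")],
        )
        assert r2.exit_code == 0, r2.output
        report = pd.read_csv(tmp_path / "rep" / "phi_report.csv")
        assert len(report) == 17
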