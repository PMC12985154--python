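"""Model/results orchestration, scenario transforms, table I/O, CLI."""

import json

import numpy as np
import pandas as pd
import pytest

from trialcea import (CostUtilityAnalysis, RunConfig, ScenarioSpec, SimConfig,
                      apply_dropout, build_ledger, extrapolate_one_year,
                      generate_cohort, load_trial_tables, run_pipeline,
                      run_scenario, toy_benefit_table, write_trial_tables,
                      UnitCostTable)
from trialcea.datasets import analysis_frame
from trialcea.exceptions import EstimationError, LoadError
from trialcea.impute import ImputationSpec, impute


@pytest.fixture(scope="module")
def completed_frame(pilot_dataset_module):
    stack = impute(pilot_dataset_module, ImputationSpec(m=2, seed=3))
    return stack.frames[0]


@pytest.fixture(scope="module")
def pilot_dataset_module():
    cfg = SimConfig(seed=11)
    return apply_dropout(generate_cohort(cfg), cfg)


class TestScenarioTransforms:
    def test_per_protocol_filter_keeps_adherent_patients(self, pilot_dataset_module):
        model = CostUtilityAnalysis(pilot_dataset_module, scenario="pp")
        sub = model._scenario_dataset()
        assert (sub.patients["sessions_received"] >= 9).all()
        kept = set(sub.patients["patient_id"])
        sessions = pilot_dataset_module.patients.set_index("patient_id")["sessions_received"]
        assert kept == set(sessions.index[sessions >= 9])

    def test_per_protocol_filter_that_empties_an_arm_fails(self, pilot_dataset_module):
        ds = pilot_dataset_module.copy()
        ds.patients.loc[ds.patients["arm"] == "PPT", "sessions_received"] = 5
        with pytest.raises(EstimationError):
            CostUtilityAnalysis(ds, scenario="pp")._scenario_dataset()

    def test_fee_multiplier_raises_each_ppt_patient_by_session_fee(self, completed_frame,
                                                                   benefits):
        uc = UnitCostTable()
        base = build_ledger(completed_frame, uc, benefits, fee_multiplier=1.0)
        doubled = build_ledger(completed_frame, uc, benefits, fee_multiplier=2.0)
        delta = (doubled.patient_totals("healthcare")
                 - base.patient_totals("healthcare"))
        sessions = completed_frame["sessions"]
        is_ppt = completed_frame["arm"] == "PPT"
        assert np.allclose(delta[is_ppt], 16.0 * sessions[is_ppt])
        assert np.allclose(delta[~is_ppt], 0.0)
        # societal non-medical and productivity components are untouched
        assert np.allclose(
            (doubled.patient_totals("societal") - base.patient_totals("societal")),
            delta)

    def test_employed_only_mode_zeroes_unemployed_productivity(self, completed_frame,
                                                               benefits):
        uc = UnitCostTable()
        base = build_ledger(completed_frame, uc, benefits, productivity_mode="base")
        alt = build_ledger(completed_frame, uc, benefits, productivity_mode="employed_only")
        employed = completed_frame["employed"].astype(bool)
        prod_base = base.amounts["productivity"].groupby(level=0).sum()
        prod_alt = alt.amounts["productivity"].groupby(level=0).sum()
        assert (prod_alt[~employed] == 0.0).all()
        assert np.allclose(prod_alt[employed], prod_base[employed])

    def test_one_year_extrapolation_rules(self, completed_frame, benefits):
        uc = UnitCostTable()
        ledger = build_ledger(completed_frame, uc, benefits)
        qalys, annual = extrapolate_one_year(completed_frame, ledger,
                                             followup_weeks=6.0)
        # sustained final utility is the annual QALY, one year × utility
        assert np.allclose(qalys["eq5d"], completed_frame["eq5d_w13"])
        # intervention period kept once; follow-up scaled to a weekly rate × 52.18
        iv = annual.amounts.xs("intervention", level=1)
        assert np.allclose(iv, ledger.amounts.xs("intervention", level=1))
        fu_base = ledger.amounts.xs("followup", level=1)
        fu_annual = annual.amounts.xs("followup", level=1)
        assert np.allclose(fu_annual, fu_base * (365.25 / 7) / 6.0)
        # zero follow-up spending stays zero; doubling the rate doubles it
        zero = fu_base.sum(axis=1) == 0
        assert (fu_annual.sum(axis=1)[zero] == 0).all()

    def test_fee_scenario_changes_costs_but_not_qalys(self, pilot_dataset_module):
        main = run_scenario(pilot_dataset_module, "main", m=3, B=50, seed=9)
        fee = run_scenario(pilot_dataset_module, "fee_1.5x", m=3, B=50, seed=9)
        for measure in ("eq5d", "sf6d"):
            assert (fee.qaly_results[measure].difference.estimate
                    == main.qaly_results[measure].difference.estimate)
        assert (fee.cost_summaries["healthcare"].difference.estimate
                > main.cost_summaries["healthcare"].difference.estimate)


class TestTableIO:
    def test_round_trip_write_read_identity(self, tmp_path, pilot_dataset_module):
        write_trial_tables(pilot_dataset_module, tmp_path)
        loaded = load_trial_tables(tmp_path)
        assert loaded.equals(pilot_dataset_module)

    def test_out_of_bounds_utility_is_a_load_error_citing_bounds(self, tmp_path,
                                                                 pilot_dataset_module):
        write_trial_tables(pilot_dataset_module, tmp_path)
        visits = pd.read_csv(tmp_path / "visits.csv", na_values=["NA"],
                             keep_default_na=False)
        visits.loc[0, "eq5d_utility"] = 1.7
        visits.to_csv(tmp_path / "visits.csv", index=False, na_rep="NA")
        with pytest.raises(LoadError, match=r"\[-1, 1\]"):
            load_trial_tables(tmp_path)

    def test_missing_table_file_is_a_load_error_listing_files(self, tmp_path,
                                                              pilot_dataset_module):
        write_trial_tables(pilot_dataset_module, tmp_path)
        (tmp_path / "wpai.csv").unlink()
        with pytest.raises(LoadError, match="wpai.csv"):
            load_trial_tables(tmp_path)


class TestPipeline:
    def make_config(self, tmp_path, dataset, **overrides):
        data_dir = tmp_path / "data"
        write_trial_tables(dataset, data_dir)
        kwargs = dict(data_dir=str(data_dir), out_dir=str(tmp_path / "out"),
                      scenario="main", seed=5, m=3, B=50, make_plots=False)
        kwargs.update(overrides)
        return RunConfig(**kwargs)

    def test_identical_config_and_seed_reproduce_all_outputs(self, tmp_path,
                                                             pilot_dataset_module):
        cfg = self.make_config(tmp_path, pilot_dataset_module)
        run_pipeline(cfg)
        first = {p.name: p.read_bytes()
                 for p in (tmp_path / "out").iterdir() if p.suffix != ".png"}
        run_pipeline(cfg)
        second = {p.name: p.read_bytes()
                  for p in (tmp_path / "out").iterdir() if p.suffix != ".png"}
        assert first == second

    def test_outputs_carry_the_seed_in_the_manifest(self, tmp_path,
                                                    pilot_dataset_module):
        cfg = self.make_config(tmp_path, pilot_dataset_module, seed=77)
        run_pipeline(cfg)
        manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert manifest["seed"] == 77
        assert manifest["cloud_size"] == 3 * 50
        summary = pd.read_csv(tmp_path / "out" / "summary.csv")
        assert len(summary) == 4  # two perspectives × two measures

    def test_pipeline_writes_plots_when_asked(self, tmp_path, pilot_dataset_module):
        cfg = self.make_config(tmp_path, pilot_dataset_module, m=2, B=20,
                               make_plots=True)
        run_pipeline(cfg)
        pngs = list((tmp_path / "out").glob("*.png"))
        assert len(pngs) == 8  # CE plane + CEAC per perspective × measure


class TestCLI:
    def test_simulate_run_report_round_trip(self, tmp_path):
        from click.testing import CliRunner
        from trialcea.cli import main
        import yaml

        runner = CliRunner()
        data_dir = tmp_path / "sim"
        r = runner.invoke(main, ["simulate", "--out", str(data_dir), "--seed", "4"])
        assert r.exit_code == 0, r.output
        assert (data_dir / "patients.csv").exists()

        run_cfg = {"data_dir": str(data_dir), "out_dir": str(tmp_path / "out"),
                   "scenario": "main", "seed": 1, "m": 2, "B": 25,
                   "make_plots": False}
        cfg_path = tmp_path / "run.yaml"
        cfg_path.write_text(yaml.safe_dump(run_cfg))
        r = runner.invoke(main, ["run", "--config", str(cfg_path)])
        assert r.exit_code == 0, r.output
        assert "societal" in r.output

        r = runner.invoke(main, ["report", "--results", str(tmp_path / "out"),
                                 "--format", "md"])
        assert r.exit_code == 0, r.output
        assert r.output.startswith("| scenario |")
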