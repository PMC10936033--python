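import numpy as np
import pandas as pd
import pytest

from twamap.cohort import (
    apply_eligibility,
    ckd_epi_2009,
    egfr_stratum,
    run_pipeline,
    vasopressor_dose_total,
)
from twamap.config import PipelineConfig
from twamap.types import MapSeries, OperationRecord, UnknownDrugError


def op(op_id, pid, cpb=(3600.0, 10800.0), invalid=None, start=0.0, end=14400.0):
    cpb_start, cpb_stop = cpb if cpb else (None, None)
    return OperationRecord(
        op_id=op_id,
        patient_id=pid,
        surgery_type="CABG",
        emergency=False,
        surgery_start=start,
        surgery_end=end,
        cpb_start=cpb_start,
        cpb_stop=cpb_stop,
        invalid_reason=invalid,
    )


def dense_series(op_id, end=14400.0, value=70.0, step=60.0):
    t = np.arange(0.0, end + step, step)
    return MapSeries(op_id, t, np.full(t.size, value))


class TestEligibility:
    def test_valid_op_kept(self):
        ops = [op("a", "p1")]
        vitals = {"a": dense_series("a")}
        eligible, report = apply_eligibility(ops, vitals)
        assert [o.op_id for o in eligible] == ["a"]
        assert report.n_eligible == 1

    def test_engineered_failures_counted(self):
        ops = [
            op("a", "p1"),
            op("b", "p2", cpb=None),                      # no_cpb
            op("c", "p3", invalid="invalid_cpb_window"),  # flagged upstream
            op("d", "p4"),                                # no vitals at all
            op("e", "p5"),                                # sparse vitals
            op("f", "p1", start=1e6),                     # reoperation
        ] + [op(f"g{i}", f"q{i}") for i in range(4)]
        vitals = {o.op_id: dense_series(o.op_id) for o in ops if o.op_id not in ("d", "e")}
        vitals["e"] = dense_series("e", step=600.0)  # 10-min gaps
        eligible, report = apply_eligibility(ops, vitals)
        assert report.n_input == 10
        assert report.n_eligible == 5
        assert report.exclusions == {
            "no_cpb": 1,
            "invalid_cpb_window": 1,
            "no_map_data": 1,
            "insufficient_resolution": 1,
            "reoperation": 1,
        }

    def test_attrition_conservation(self):
        ops = [op("a", "p1"), op("b", "p2", cpb=None)]
        _, report = apply_eligibility(ops, {"a": dense_series("a")})
        assert report.n_input == report.n_eligible + sum(report.exclusions.values())

    def test_order_invariance(self):
        ops = [op("a", "p1"), op("b", "p2", cpb=None), op("c", "p3")]
        vitals = {"a": dense_series("a"), "c": dense_series("c")}
        e1, _ = apply_eligibility(ops, vitals)
        e2, _ = apply_eligibility(list(reversed(ops)), vitals)
        assert [o.op_id for o in e1] == [o.op_id for o in e2]


class TestVasopressorDose:
    def test_weighted_sum(self):
        assert vasopressor_dose_total({"norepinephrine": 10, "epinephrine": 5}) == 15.0

    def test_empty(self):
        assert vasopressor_dose_total({}) == 0.0

    def test_unknown_drug_named_in_error(self):
        with pytest.raises(UnknownDrugError, match="drugX"):
            vasopressor_dose_total({"norepinephrine": 1, "drugX": 2})

    def test_custom_weights(self):
        assert vasopressor_dose_total({"milrinone": 2.0}, {"milrinone": 0.5}) == 1.0


class TestEgfrHelper:
    def test_normal_function(self):
        # healthy 40-year-old male, scr 0.9 -> well above 90
        assert ckd_epi_2009(0.9, 40, female=False) > 90

    def test_reduced_function(self):
        assert ckd_epi_2009(2.5, 80, female=True) < 30

    def test_strata_cutpoints(self):
        assert egfr_stratum(95) == "G1"
        assert egfr_stratum(90) == "G1"
        assert egfr_stratum(75) == "G2"
        assert egfr_stratum(50) == "G3a"
        assert egfr_stratum(40) == "G3b"
        assert egfr_stratum(20) == "G4"
        assert egfr_stratum(10) == "G5"


class TestPipeline:
    def test_engineered_attrition_matches_construction(self, sim_cohort_small, sim_tables_dir):
        d = sim_tables_dir
        cohort, report = run_pipeline(
            d / "vitals.csv", d / "operations.csv", d / "labs.csv", d / "patients.csv"
        )
        att = report["attrition"]
        assert att["exclusions"]["no_cpb"] == 2
        assert att["exclusions"]["invalid_cpb_window"] == 1
        assert att["exclusions"]["insufficient_resolution"] == 2
        assert att["exclusions"]["no_baseline"] == 1
        assert att["exclusions"]["reoperation"] == 1
        assert att["n_eligible"] == 60
        assert att["n_input"] == att["n_eligible"] + sum(att["exclusions"].values())
        assert len(cohort) == 60

    def test_cohort_columns_present_and_nonconstant(self, sim_tables_dir):
        d = sim_tables_dir
        cohort, _ = run_pipeline(
            d / "vitals.csv", d / "operations.csv", d / "labs.csv", d / "patients.csv"
        )
        cfg = PipelineConfig()
        for col in cfg.covariates:
            assert col in cohort.columns, col
            assert cohort[col].nunique() > 1, f"{col} is constant"
        for col in ("twa65_cpb", "twa75_cpb", "twa65_postcpb", "twa75_postcpb",
                    "aki", "aki_stage", "crrt", "cpb_time"):
            assert col in cohort.columns

    def test_threshold_monotonicity_rowwise(self, sim_tables_dir):
        d = sim_tables_dir
        cohort, _ = run_pipeline(
            d / "vitals.csv", d / "operations.csv", d / "labs.csv", d / "patients.csv"
        )
        assert (cohort["twa65_cpb"] <= cohort["twa75_cpb"] + 1e-9).all()
        assert (cohort["twa65_postcpb"] <= cohort["twa75_postcpb"] + 1e-9).all()

    def test_exposures_nonnegative_cpb_positive(self, sim_tables_dir):
        d = sim_tables_dir
        cohort, _ = run_pipeline(
            d / "vitals.csv", d / "operations.csv", d / "labs.csv", d / "patients.csv"
        )
        assert (cohort["twa65_cpb"] >= 0).all()
        assert (cohort["cpb_time"] > 0).all()

    def test_adjudication_matches_generated_truth(self, sim_cohort_small, sim_tables_dir):
        d = sim_tables_dir
        cohort, _ = run_pipeline(
            d / "vitals.csv", d / "operations.csv", d / "labs.csv", d / "patients.csv"
        )
        truth = sim_cohort_small.analysis_table
        m = cohort.merge(truth, on="patient_id", suffixes=("", "_true"))
        assert len(m) == 60
        assert (m["aki"] == m["aki_true"]).all()
        assert (m["aki_stage"] == m["aki_stage_true"]).all()
        assert (m["crrt"] == m["crrt_true"]).all()

    def test_missing_weight_complete_case(self, tmp_path):
        from twamap.simulate import SimConfig, simulate_cohort

        sim = simulate_cohort(SimConfig(n_patients=20, seed=3))
        sim.patients.loc[sim.patients.index[0], "weight"] = np.nan
        sim.write_csv(tmp_path)
        cohort, report = run_pipeline(
            tmp_path / "vitals.csv", tmp_path / "operations.csv",
            tmp_path / "labs.csv", tmp_path / "patients.csv",
        )
        assert len(cohort) == 19
        assert report["attrition"]["exclusions"]["missing_covariates"] == 1

    def test_missing_weight_imputed(self, tmp_path):
        from twamap.simulate import SimConfig, simulate_cohort

        sim = simulate_cohort(SimConfig(n_patients=20, seed=3))
        sim.patients.loc[sim.patients.index[0], "weight"] = np.nan
        sim.write_csv(tmp_path)
        cfg = PipelineConfig(missing_policy="impute")
        cohort, report = run_pipeline(
            tmp_path / "vitals.csv", tmp_path / "operations.csv",
            tmp_path / "labs.csv", tmp_path / "patients.csv", cfg,
        )
        assert len(cohort) == 20
        assert not cohort["weight"].isna().any()

    def test_build_deterministic(self, sim_tables_dir):
        d = sim_tables_dir
        c1, _ = run_pipeline(
            d / "vitals.csv", d / "operations.csv", d / "labs.csv", d / "patients.csv"
        )
        c2, _ = run_pipeline(
            d / "vitals.csv", d / "operations.csv", d / "labs.csv", d / "patients.csv"
        )
        pd.testing.assert_frame_equal(c1, c2)
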