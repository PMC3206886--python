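import json

import numpy as np
import pandas as pd
import pytest

from funconn import (CohortConfig, ConnectomeStudy, PipelineConfig,
                     RoiTimeSeries)
from funconn.config import ConfigurationError
from funconn.io import (load_cohort, read_matrix, read_nuisance,
                        read_subject_table, read_timeseries, write_cohort,
                        write_matrix, write_nuisance, write_subject_table,
                        write_timeseries)


@pytest.fixture(scope="module")
def cohort_dir(tmp_path_factory, small_cohort):
    path = tmp_path_factory.mktemp("cohort")
    write_cohort(small_cohort, path)
    return small_cohort, path


SMALL_PIPELINE = dict(sparsity_low=0.15, sparsity_high=0.17,
                      analysis_sparsity=0.15, n_random=5, seed=3)


class TestRoundTrips:
    def test_subject_table(self, cohort_dir, tmp_path):
        cohort, _ = cohort_dir
        path = tmp_path / "subjects.csv"
        write_subject_table(path, cohort.subjects)
        back = read_subject_table(path)
        assert back == cohort.subjects

    def test_timeseries(self, cohort_dir, tmp_path):
        cohort, _ = cohort_dir
        ts = cohort.timeseries["sub-001"]
        path = tmp_path / "ts.tsv"
        write_timeseries(path, ts)
        back = read_timeseries(path)
        assert back.region_labels == ts.region_labels
        assert back.tr_seconds == ts.tr_seconds
        np.testing.assert_allclose(back.data, ts.data, rtol=1e-6)

    def test_nuisance(self, cohort_dir, tmp_path):
        cohort, _ = cohort_dir
        nuis = cohort.nuisance["sub-001"]
        path = tmp_path / "nuis.tsv"
        write_nuisance(path, nuis)
        back = read_nuisance(path)
        np.testing.assert_allclose(back.motion, nuis.motion, rtol=1e-6)
        np.testing.assert_allclose(back.wm_signal, nuis.wm_signal, rtol=1e-6)

    def test_matrix(self, tmp_path):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(5, 5))
        path = tmp_path / "m.tsv"
        write_matrix(path, m, list("abcde"), stage="test")
        back, labels = read_matrix(path)
        np.testing.assert_allclose(back, m, rtol=1e-6)
        assert labels == tuple("abcde")

    def test_cohort_directory(self, cohort_dir):
        cohort, path = cohort_dir
        subjects, timeseries, nuisance = load_cohort(path)
        assert subjects == cohort.subjects
        assert set(timeseries) == set(nuisance) == {s.subject_id
                                                    for s in subjects}

    def test_output_files_carry_provenance_header(self, cohort_dir):
        _, path = cohort_dir
        first = (path / "subjects.csv").read_text().splitlines()[0]
        assert first.startswith("# funconn v")
        assert "stage=" in first and "config=" in first


class TestSubjectTableValidation:
    def test_mixed_case_values_normalized(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("subject_id,sex,group,age\n"
                        "s1,F,HC,30\n"
                        "s2,male,Patient,41\n")
        recs = read_subject_table(path)
        assert recs[0].sex == "female" and recs[0].group == "control"
        assert recs[1].sex == "male" and recs[1].group == "patient"

    def test_duplicate_subject_id_rejected(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("subject_id,sex,group,age\ns1,F,HC,30\ns1,M,HC,32\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_subject_table(path)

    def test_missing_required_column_rejected(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("subject_id,sex,age\ns1,F,30\n")
        with pytest.raises(ValueError, match="group"):
            read_subject_table(path)

    def test_unknown_category_names_subject(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("subject_id,sex,group,age\ns9,unknown,HC,30\n")
        with pytest.raises(ValueError, match="s9"):
            read_subject_table(path)


class TestPipelineConfig:
    def test_inverted_sparsity_range_rejected(self):
        with pytest.raises(ConfigurationError):
            PipelineConfig(sparsity_low=0.30, sparsity_high=0.10)

    def test_unknown_keys_rejected(self):
        with pytest.raises(ConfigurationError):
            PipelineConfig.from_dict({"sparsity_lo": 0.15})

    def test_default_sweep_grid(self):
        cfg = PipelineConfig()
        assert len(cfg.sparsities) == 11
        assert cfg.sparsities[0] == 0.15
        assert cfg.sparsities[-1] == 0.25


@pytest.fixture(scope="module")
def results(cohort_dir):
    _, path = cohort_dir
    study = ConnectomeStudy.from_directory(
        path, PipelineConfig(**SMALL_PIPELINE))
    return study.fit()


class TestConnectomeStudy:
    def test_fit_produces_all_tables(self, results):
        assert len(results.global_metrics) == 12
        assert set(results.global_metrics.columns) >= {
            "C", "L", "gamma", "lambda", "sigma"}
        assert results.betweenness.shape == (12, 45)
        assert len(results.metric_anova) == 5
        assert len(results.nodal_anova) == 45
        assert set(results.robustness) == {"female", "male"}
        assert not results.partial_corr.empty

    def test_sweep_covers_grid_for_every_subject(self, results):
        counts = results.sweep_metrics.groupby("subject_id").size()
        assert (counts == 3).all()       # 0.15, 0.16, 0.17

    def test_summary_mentions_key_quantities(self, results):
        text = results.summary()
        assert "sigma" in text
        assert "ANOVA" in text
        assert "partial corr" in text

    def test_save_writes_results_and_manifest(self, results, tmp_path):
        out = tmp_path / "results"
        results.save(out)
        names = {p.name for p in out.iterdir()}
        assert {"qc.csv", "global_metrics.csv", "metric_anova.csv",
                "nodal_anova.csv", "manifest.json"} <= names
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["n_subjects"] == 12
        assert manifest["config"]["analysis_sparsity"] == 0.15

    def test_refit_is_deterministic(self, cohort_dir, results):
        _, path = cohort_dir
        study = ConnectomeStudy.from_directory(
            path, PipelineConfig(**SMALL_PIPELINE))
        again = study.fit()
        pd.testing.assert_frame_equal(results.global_metrics,
                                      again.global_metrics)
        pd.testing.assert_frame_equal(results.nodal_anova, again.nodal_anova)

    def test_simulate_constructor_round_trip(self):
        study = ConnectomeStudy.simulate(
            CohortConfig(n_females_per_group=2, n_males_per_group=2,
                         n_regions=20, n_timepoints=60, seed=9))
        assert len(study.subjects) == 8
        assert study.timeseries[study.subjects[0].subject_id].n_regions == 20

    def test_excessive_motion_excludes_subject(self, cohort_dir):
        cohort, _ = cohort_dir
        nuisance = dict(cohort.nuisance)
        bad_id = cohort.subjects[0].subject_id
        bad = nuisance[bad_id]
        motion = bad.motion.copy()
        motion[0, 50] = 2.5
        from funconn import NuisanceSet
        nuisance[bad_id] = NuisanceSet(motion, bad.wm_signal, bad.csf_signal)
        study = ConnectomeStudy(cohort.subjects, cohort.timeseries, nuisance,
                                PipelineConfig(**SMALL_PIPELINE))
        res = study.fit()
        assert res.excluded_subjects == [bad_id]
        assert bad_id not in res.global_metrics["subject_id"].values


class TestCli:
    def test_simulate_then_qc(self, tmp_path):
        from click.testing import CliRunner

        from funconn.cli import main

        runner = CliRunner()
        cohort_dir = tmp_path / "cohort"
        cfg = tmp_path / "cfg.json"
        cfg.write_text(json.dumps({
            "n_females_per_group": 2, "n_males_per_group": 2,
            "n_regions": 20, "n_timepoints": 60}))
        r = runner.invoke(main, ["simulate", "--out", str(cohort_dir),
                                 "--seed", "1", "--config", str(cfg)])
        assert r.exit_code == 0, r.output
        assert (cohort_dir / "subjects.csv").exists()

        qc_out = tmp_path / "qc.csv"
        r = runner.invoke(main, ["qc", "--in", str(cohort_dir),
                                 "--out", str(qc_out)])
        assert r.exit_code == 0, r.output
        qc = pd.read_csv(qc_out)
        assert len(qc) == 8 and qc["passed"].all()

    def test_build_writes_matrices(self, tmp_path):
        from click.testing import CliRunner

        from funconn.cli import main

        runner = CliRunner()
        cohort_dir = tmp_path / "cohort"
        cfg = tmp_path / "cfg.json"
        cfg.write_text(json.dumps({
            "n_females_per_group": 1, "n_males_per_group": 1,
            "n_regions": 20, "n_timepoints": 60}))
        runner.invoke(main, ["simulate", "--out", str(cohort_dir),
                             "--seed", "2", "--config", str(cfg)])
        out = tmp_path / "matrices"
        r = runner.invoke(main, ["build", "--in", str(cohort_dir),
                                 "--out", str(out), "--sparsity", "20%"])
        assert r.exit_code == 0, r.output
        adj, labels = read_matrix(out / "sub-001_adjacency.tsv")
        assert adj.shape == (20, 20)
        assert adj.sum() / 2 == round(0.20 * 190)
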