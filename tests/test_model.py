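"""End-to-end model fitting, reporting, determinism and the CLI."""

import dataclasses
import json

import numpy as np
import pytest
import yaml

from connectocentric import (
    AnalysisConfig,
    CohortSpec,
    ConnectomeCentralityModel,
    cohens_d,
    generate_cohort,
    permutation_two_sample,
    split_node,
)


class TestConfig:
    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            AnalysisConfig.from_mapping({"densty_low": 10})

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text(yaml.safe_dump({"density_low": 25, "seed": 3}))
        cfg = AnalysisConfig.from_yaml(path)
        assert cfg.density_low == 25 and cfg.seed == 3

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            AnalysisConfig(metrics=("clustering",))
        with pytest.raises(ValueError):
            AnalysisConfig(density_low=50, density_high=20)
        with pytest.raises(ValueError):
            AnalysisConfig(family_alpha=1.5)


class TestFit:
    def test_primary_tests_and_alpha(self, small_model):
        res = small_model.fit(sections=("primary",))
        assert len(res.primary) == 4  # 2 nodes x 2 metrics
        assert all(r.alpha == pytest.approx(0.0125) for r in res.primary)
        effect = res.primary_result("lh_piriform", "degree")
        assert effect.cohens_d > 0.5  # planted d = 1.0
        assert effect.n_a == 12 and effect.n_b == 8

    def test_subject_conservation(self, small_model):
        res = small_model.fit(sections=("primary",))
        d = res.diagnostics
        assert (
            d["n_drug_resistant"]
            + d["n_drug_responsive"]
            + d["n_excluded_missing_resistance"]
            == d["n_subjects_total"]
        )
        assert d["n_excluded_missing_resistance"] == 2

    def test_reported_p_reproducible_from_logged_seed(self, small_model):
        res = small_model.fit(sections=("primary",))
        r = res.primary_result("lh_piriform", "degree")
        cent = small_model.centralities()["degree"]["lh_piriform"].to_numpy()
        resistant = np.array(
            [c.drug_resistant is True for c in small_model.clinical]
        )
        responsive = np.array(
            [c.drug_resistant is False for c in small_model.clinical]
        )
        redo = permutation_two_sample(
            cent[resistant], cent[responsive],
            n_permutations=small_model.config.n_permutations, seed=r.seed,
        )
        assert redo.p_value == r.p_value
        assert redo.t_statistic == pytest.approx(r.t_statistic)

    def test_correlations_cover_duration_and_age(self, small_model):
        res = small_model.fit(sections=("correlations",))
        covs = {(c.node, c.metric, c.covariate) for c in res.correlations}
        assert ("lh_piriform", "degree", "duration_years") in covs
        assert ("lh_piriform", "degree", "age_at_mri") in covs
        assert len(res.correlations) == 8
        dur = next(
            c for c in res.correlations
            if c.node == "lh_piriform" and c.metric == "degree"
            and c.covariate == "duration_years"
        )
        assert dur.n == 19  # 20 labeled minus 1 missing duration

    def test_regression_adjusts_for_covariates(self, small_model):
        res = small_model.fit(sections=("regression",))
        base = res.regressions["resistance_duration"]
        assert "drug_resistant" in base.terms and "duration_years" in base.terms
        assert base.n_dropped == 1  # missing duration
        full = res.regressions["full_covariates"]
        assert set(base.terms) < set(full.terms)
        assert full.df_resid == full.n_used - len(full.terms)

    def test_exploratory_tables(self, small_model):
        res = small_model.fit(sections=("exploratory",))
        frame = res.exploratory["degree"]
        assert len(frame) == 30
        assert np.all(frame["p_fdr"] >= frame["p_raw"] - 1e-12)
        assert (frame["m_comparisons"] == 30).all()
        # planted node (d = 1.0) should rank among the strongest effects;
        # at n = 12 vs 8 a null node occasionally tops it by chance
        assert "lh_piriform" in set(res.top_nodes("degree").index[:3])

    def test_end_to_end_determinism(self, tmp_path, small_cohort):
        cfg = AnalysisConfig(n_permutations=500, seed=4)
        reports = []
        for d in ("r1", "r2"):
            res = ConnectomeCentralityModel.from_cohort(small_cohort, cfg).fit()
            res.save(tmp_path / d)
            reports.append((tmp_path / d / "report.json").read_bytes())
        assert reports[0] == reports[1]
        saved = json.loads(reports[0])
        assert set(saved) == {
            "primary", "correlations", "regressions", "exploratory",
            "exploratory_duration", "surgery", "surgery_note", "diagnostics",
        }

    def test_summary_mentions_key_sections(self, small_model):
        res = small_model.fit()
        text = res.summary()
        assert "Primary tests" in text
        assert "lh_piriform" in text
        assert "Spearman" in text

    def test_small_cohort_uses_exhaustive_mode(self):
        spec = CohortSpec(
            n_nodes=15, n_group_a=2, n_group_b=2, n_unlabeled=0,
            degree_effect_d=0.0, seed=5, n_missing_duration=0,
        )
        cohort = generate_cohort(spec)
        cfg = AnalysisConfig(metrics=("degree",), n_permutations=1000, seed=1)
        res = ConnectomeCentralityModel.from_cohort(cohort, cfg).fit(
            sections=("primary",)
        )
        assert res.diagnostics["small_sample_exhaustive"]
        assert all(r.exhaustive for r in res.primary)

    def test_surgery_not_evaluable_without_both_outcomes(self, small_cohort):
        clinical = [
            dataclasses.replace(r, ilae_class=3 if r.operated else None)
            for r in small_cohort.clinical
        ]
        cfg = AnalysisConfig(n_permutations=200, seed=2, metrics=("degree",))
        model = ConnectomeCentralityModel(
            small_cohort.connectomes, clinical, cfg
        )
        res = model.fit(sections=("surgery",))
        assert res.surgery == []
        assert "not evaluable" in res.surgery_note

    def test_surgery_alpha_and_direction(self):
        # strong outcome coupling: seizure-free subjects have lower centrality
        spec = CohortSpec(
            n_nodes=30, n_group_a=14, n_group_b=10, n_unlabeled=4,
            degree_effect_d=1.2, operated_fraction=0.9, outcome_slope=3.0,
            seed=3,
        )
        cohort = generate_cohort(spec)
        cfg = AnalysisConfig(metrics=("degree",), n_permutations=500, seed=8)
        res = ConnectomeCentralityModel.from_cohort(cohort, cfg).fit(
            sections=("surgery",)
        )
        if res.surgery:  # both outcome groups populated for this seed
            r = res.surgery[0]
            assert r.alpha == pytest.approx(0.005)
            assert r.cohens_d < 0

    def test_mismatched_clinical_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="no clinical record"):
            ConnectomeCentralityModel(
                small_cohort.connectomes, small_cohort.clinical[:-1]
            )

    def test_unknown_primary_node_rejected(self, small_cohort):
        cfg = AnalysisConfig(primary_nodes=("nonexistent",))
        with pytest.raises(ValueError, match="primary nodes"):
            ConnectomeCentralityModel.from_cohort(small_cohort, cfg)


class TestNodeSplitRobustness:
    def test_planted_effect_survives_node_split(self, small_cohort):
        """A finer parcellation of the effect node keeps the effect visible."""
        effect = small_cohort.truth["effect_node"]
        halves = ("piriform_rostral", "piriform_caudal")
        connectomes = [
            split_node(c, effect, halves) for c in small_cohort.connectomes
        ]
        cfg = AnalysisConfig(
            metrics=("degree",), primary_nodes=halves, n_permutations=500,
            seed=6,
        )
        model = ConnectomeCentralityModel(
            connectomes, small_cohort.clinical, cfg
        )
        cent = model.centralities()["degree"]
        resistant = np.array([r.drug_resistant is True for r in model.clinical])
        responsive = np.array(
            [r.drug_resistant is False for r in model.clinical]
        )
        ds = {
            node: cohens_d(cent[node][resistant], cent[node][responsive])
            for node in model.labels
        }
        ranked = sorted(ds, key=ds.get, reverse=True)
        assert set(halves) & set(ranked[:3])


class TestCLI:
    def test_synth_run_metrics_workflow(self, tmp_path):
        from click.testing import CliRunner

        from connectocentric.cli import main

        runner = CliRunner()
        spec = {
            "n_nodes": 20, "n_group_a": 8, "n_group_b": 6, "n_unlabeled": 1,
            "degree_effect_d": 0.8, "seed": 9,
        }
        spec_path = tmp_path / "spec.yaml"
        spec_path.write_text(yaml.safe_dump(spec))
        out = tmp_path / "cohort"
        r = runner.invoke(main, ["synth", "--spec", str(spec_path), "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert (out / "clinical.csv").exists()
        assert (out / "truth.json").exists()

        cfg_path = tmp_path / "config.yaml"
        cfg_path.write_text(
            yaml.safe_dump({"n_permutations": 200, "metrics": ["degree"]})
        )
        report_dir = tmp_path / "report"
        r = runner.invoke(
            main,
            [
                "run", "--config", str(cfg_path), "--matrices", str(out),
                "--clinical", str(out / "clinical.csv"), "--seed", "3",
                "--out", str(report_dir),
            ],
        )
        assert r.exit_code == 0, r.output
        assert (report_dir / "report.json").exists()
        assert (report_dir / "primary.csv").exists()

        r = runner.invoke(
            main,
            [
                "metrics",
                "--subject", str(out / "sub-000_matrix.tsv"),
                "--waytotals", str(out / "sub-000_waytotals.tsv"),
            ],
        )
        assert r.exit_code == 0, r.output
        assert r.output.startswith("node,integrated_degree")
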