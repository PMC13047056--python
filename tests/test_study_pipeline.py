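"""Study orchestration: table layout, robustness comparisons, subgroup

construction, and end-to-end determinism."""

import json

import pytest

from paneldml.design_prep import PrepConfig
from paneldml.dml_core import DMLConfig
from paneldml.study_pipeline import (
    ReportTable,
    StudyConfig,
    run_benchmark,
    run_full_study,
    run_heterogeneity,
    run_robustness,
    stars,
)
from paneldml.synthetic_panel import DGPConfig, generate_panel


def _study_cfg(**dgp_over):
    dgp_kw = dict(n_cities=40, n_years=8, theta_true=0.15, nonlinear_nuisance=False,
                  fe_sd_city=0.0, adoption_waves=((2009, 0.12), (2010, 0.12), (2011, 0.12)),
                  confounder_dim=5, mediator_paths={"EEQ": (0.3, 0.5)},
                  mediator_noise_sd={"EEQ": 0.5}, seed=42)
    dgp_kw.update(dgp_over)
    dgp = DGPConfig(**dgp_kw)
    return StudyConfig(
        dgp=dgp,
        prep=PrepConfig(fe_city=False),
        dml=DMLConfig(learner="linear", seed=7),
        mediators=("EEQ",),
        subgroup_vars=("region", "batch"),
        fold_presets=(4,),
        n_boot=30,
        seed=7,
    )


def test_stars_convention():
    assert stars(3.0) == "***"
    assert stars(2.0) == "**"
    assert stars(1.7) == "*"
    assert stars(1.0) == ""


class TestBenchmark:
    def test_four_column_ladder_layout(self):
        cfg = _study_cfg()
        panel = generate_panel(cfg.dgp)
        table = run_benchmark(panel, cfg)
        df = table.to_dataframe()
        assert df.shape[1] == 4
        assert list(df.loc["fe_year"]) == [False, False, True, True]
        assert list(df.loc["fe_city"]) == [False, False, False, True]
        assert list(df.loc["squares"]) == [False, True, True, True]
        assert (df.loc["n"] == len(panel.df)).all()

    def test_markdown_rendering_traces_results(self):
        cfg = _study_cfg()
        panel = generate_panel(cfg.dgp)
        table = run_benchmark(panel, cfg)
        md = table.to_markdown()
        assert md.startswith("### benchmark")
        assert f"{table.columns[0]['result'].theta_hat:.4f}" in md


class TestRobustness:
    def test_irrelevant_policy_dummies_barely_move_theta(self):
        cfg = _study_cfg()
        panel = generate_panel(cfg.dgp)
        out = run_robustness(panel, cfg)
        by_label = {c["variant"]: c for c in out["comparison"]}
        assert abs(by_label["policy dummies"]["theta_shift_in_benchmark_se"]) < 1.0

    def test_all_variants_reported_with_comparison(self):
        cfg = _study_cfg()
        panel = generate_panel(cfg.dgp)
        out = run_robustness(panel, cfg)
        labels = [c["label"] for c in out["table"].columns]
        assert labels[0] == "benchmark"
        assert any("winsor" in lb for lb in labels)
        assert any("PLIV" in lb for lb in labels)
        assert any("folds" in lb for lb in labels)
        assert len(out["comparison"]) == len(labels) - 1


class TestHeterogeneity:
    def test_subgroup_tables_report_own_n(self):
        cfg = _study_cfg()
        panel = generate_panel(cfg.dgp)
        tables = run_heterogeneity(panel, cfg)
        df = panel.df
        for col in tables["region"].columns:
            lv = col["label"]
            assert col["result"].n_obs == int((df["region"] == lv).sum())

    def test_batch_groups_exclude_other_waves(self):
        cfg = _study_cfg()
        panel = generate_panel(cfg.dgp)
        tables = run_heterogeneity(panel, cfg)
        df = panel.df
        never = int((df["batch"] == "none").sum())
        for col in tables["batch"].columns:
            own = int((df["batch"] == col["label"]).sum())
            assert col["result"].n_obs == own + never

    def test_regional_effect_contrast_detected(self):
        """A large west-only effect shows up in the west column and not the

        east column for most replications."""
        west_sig, east_sig = 0, 0
        reps = 12
        for s in range(reps):
            cfg = _study_cfg(theta_by_region={"west": 0.30, "east": 0.0, "central": 0.0, "northeast": 0.0},
                             theta_true=0.0, mediator_paths={}, mediator_noise_sd={}, seed=900 + s)
            cfg = StudyConfig(dgp=cfg.dgp.with_(n_cities=80), prep=cfg.prep, dml=cfg.dml,
                              subgroup_vars=("region",), seed=7)
            tables = run_heterogeneity(generate_panel(cfg.dgp), cfg)
            cols = {c["label"]: c["result"] for c in tables["region"].columns}
            if "west" in cols:
                west_sig += abs(cols["west"].t_stat) > 1.96
            if "east" in cols:
                east_sig += abs(cols["east"].t_stat) > 1.96
        assert west_sig >= 0.8 * reps
        assert east_sig <= 0.4 * reps


class TestFullStudy:
    def test_end_to_end_bundle_and_modularity(self, tmp_path):
        cfg = _study_cfg()
        bundle = run_full_study(cfg, out_dir=tmp_path / "run")
        assert not bundle["partial"]
        assert set(bundle["stages"]) == {"index", "benchmark", "robustness", "mediation", "heterogeneity"}
        assert (tmp_path / "run" / "manifest.json").exists()
        assert (tmp_path / "run" / "tables" / "benchmark.md").exists()
        # dropping the mediator list skips only the mediation stage
        cfg2 = _study_cfg()
        cfg2.mediators = ()
        bundle2 = run_full_study(cfg2, out_dir=tmp_path / "run2")
        assert "mediation" not in bundle2["stages"]
        assert "benchmark" in bundle2["stages"]

    def test_reported_cells_trace_to_stored_results(self, tmp_path):
        cfg = _study_cfg()
        bundle = run_full_study(cfg, out_dir=tmp_path / "run")
        stored = json.loads((tmp_path / "run" / "results" / "study.json").read_text())
        assert stored["benchmark"] == bundle["benchmark"]
        for col in stored["benchmark"]["columns"]:
            assert col["t_stat"] == pytest.approx(col["theta_hat"] / col["se"])

    def test_yaml_roundtrip(self, tmp_path):
        yml = tmp_path / "study.yaml"
        yml.write_text(
            "seed: 3\n"
            "dgp:\n  n_cities: 30\n  n_years: 6\n  adoption_waves: [[2009, 0.2]]\n"
            "  mediator_paths: {EEQ: [0.2, 0.4]}\n  mediator_noise_sd: {EEQ: 0.5}\n"
            "dml:\n  learner: linear\n"
            "prep:\n  fe_city: false\n"
            "mediators: [EEQ]\n"
        )
        cfg = StudyConfig.from_yaml(yml)
        assert cfg.dgp.n_cities == 30
        assert cfg.dgp.mediator_paths["EEQ"] == (0.2, 0.4)
        assert cfg.dml.seed == 3  # global seed flows into the estimator
        assert cfg.config_hash() == StudyConfig.from_yaml(yml).config_hash()
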