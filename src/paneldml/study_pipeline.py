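"""End-to-end simulated-study orchestration.

Runs the full evaluation ladder on one panel: the four-column benchmark
(controls; + squares; + year FE; + city FE), the robustness suite
(winsorization presets, province-by-trend fixed effects, contemporaneous
policy dummies, the historical-instrument PLIV fit, fold-count and learner
swaps), mediation per mediator, and subgroup heterogeneity.  Everything is
driven by one config (YAML-able) and a global seed; outputs are
machine-readable JSON plus markdown tables, and a manifest with the config
hash so a re-run is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from paneldml.design_prep import PrepConfig, interpolate_missing, winsorize
from paneldml.dml_core import DMLConfig, DMLResult, dml_plr
from paneldml.dml_pliv import IVConfig, dml_pliv
from paneldml.index_entropy import IndicatorSpec, composite_index
from paneldml.mediation import bootstrap_indirect
from paneldml.synthetic_panel import DGPConfig, INDICATOR_DIRECTIONS, PanelDataset, generate_indicator_table, generate_panel, true_effects

__all__ = ["StudyConfig", "ReportTable", "run_benchmark", "run_robustness", "run_heterogeneity", "run_full_study", "stars"]


def stars(t_stat: float) -> str:
    """Two-sided normal significance stars at the 10/5/1% levels."""
    p = 2.0 * norm.sf(abs(t_stat))
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


@dataclass
class ReportTable:
    """A named set of fitted columns; every cell traces to a DMLResult."""

    name: str
    columns: list[dict] = field(default_factory=list)  # {label, result, meta}

    def add(self, label: str, result: DMLResult, **meta) -> None:
        self.columns.append({"label": label, "result": result, "meta": meta})

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "columns": [
                {"label": c["label"], "meta": c["meta"], **c["result"].to_dict()}
                for c in self.columns
            ],
        }

    def to_dataframe(self) -> pd.DataFrame:
        rows = {}
        for c in self.columns:
            r = c["result"]
            rows[c["label"]] = {
                "coef": r.theta_hat,
                "se": r.se,
                "t": r.t_stat,
                "stars": stars(r.t_stat),
                "n": r.n_obs,
                **c["meta"],
            }
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        df = self.to_dataframe()
        labels = list(df.columns)
        lines = [f"### {self.name}", ""]
        lines.append("| | " + " | ".join(labels) + " |")
        lines.append("|---" * (len(labels) + 1) + "|")

        def fmt(v):
            if isinstance(v, float):
                return f"{v:.4f}"
            return str(v)

        for idx in df.index:
            lines.append("| " + str(idx) + " | " + " | ".join(fmt(df.loc[idx, c]) for c in labels) + " |")
        lines.append("")
        return "\n".join(lines)


@dataclass
class StudyConfig:
    """One config for the whole simulated study."""

    dgp: DGPConfig = field(default_factory=DGPConfig)
    prep: PrepConfig = field(default_factory=PrepConfig)
    dml: DMLConfig = field(default_factory=DMLConfig)
    iv_instrument_col: str = "instrument_base"
    mediators: tuple[str, ...] = ("EEQ", "ISL", "HWS")
    subgroup_vars: tuple[str, ...] = ("region", "size", "regulation", "batch")
    winsor_presets: tuple[tuple[float, float], ...] = ((0.01, 0.99), (0.05, 0.95))
    fold_presets: tuple[int, ...] = (4, 8)
    swap_learner: str = "gradient_boosting"
    policy_dummy_cols: tuple[str, ...] = ("policy_broadband", "policy_bigdata", "policy_innovation")
    n_boot: int = 1000
    boot_learner: str = "linear"
    run_index_construction: bool = True
    out_dir: str = "scratch/study_out"
    seed: int = 1

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        kw: dict = {}
        if "dgp" in d:
            g = dict(d.pop("dgp"))
            if "adoption_waves" in g:
                g["adoption_waves"] = tuple((int(y), float(f)) for y, f in g["adoption_waves"])
            if "mediator_paths" in g:
                g["mediator_paths"] = {k: tuple(v) for k, v in g["mediator_paths"].items()}
            kw["dgp"] = DGPConfig(**g)
        if "prep" in d:
            p = dict(d.pop("prep"))
            for key in ("winsor_bounds",):
                if p.get(key) is not None:
                    p[key] = tuple(p[key])
            for key in ("policy_dummies", "exclude_from_winsor"):
                if key in p:
                    p[key] = tuple(p[key])
            kw["prep"] = PrepConfig(**p)
        if "dml" in d:
            kw["dml"] = DMLConfig(**d.pop("dml"))
        for key in ("mediators", "subgroup_vars", "fold_presets", "policy_dummy_cols"):
            if key in d:
                d[key] = tuple(d[key])
        if "winsor_presets" in d:
            d["winsor_presets"] = tuple(tuple(b) for b in d["winsor_presets"])
        kw.update(d)
        cfg = cls(**kw)
        # the global seed flows into the estimator config unless it set its own
        if cfg.dml.seed == 0:
            cfg.dml = cfg.dml.with_(seed=cfg.seed)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_canonical_json(self) -> str:
        def enc(o):
            if hasattr(o, "__dataclass_fields__"):
                return {k: getattr(o, k) for k in o.__dataclass_fields__}
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, (tuple, set)):
                return list(o)
            raise TypeError(f"cannot encode {type(o)}")
        return json.dumps(self, default=enc, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_json().encode()).hexdigest()


# the four-column specification ladder
_BENCHMARK_SPECS = [
    ("(1) controls", dict(add_squares=False, fe_year=False, fe_city=False)),
    ("(2) + squares", dict(add_squares=True, fe_year=False, fe_city=False)),
    ("(3) + year FE", dict(add_squares=True, fe_year=True, fe_city=False)),
    ("(4) + city FE", dict(add_squares=True, fe_year=True, fe_city=True)),
]


def run_benchmark(panel: PanelDataset, cfg: StudyConfig) -> ReportTable:
    """The specification ladder: successively add control squares, year fixed

    effects and city fixed effects, each column a full cross-fitted PLR fit."""
    table = ReportTable("benchmark")
    for label, flags in _BENCHMARK_SPECS:
        prep = cfg.prep.with_(**flags)
        res = dml_plr(panel, "PHL", "SCC", prep, cfg.dml)
        table.add(label, res, squares=flags["add_squares"], fe_year=flags["fe_year"], fe_city=flags["fe_city"])
    return table


def run_robustness(panel: PanelDataset, cfg: StudyConfig, benchmark: DMLResult | None = None) -> dict:
    """Robustness suite around the full-specification benchmark fit.

    Returns the report table plus a per-variant sign/significance comparison
    against the benchmark column.
    """
    if benchmark is None:
        benchmark = dml_plr(panel, "PHL", "SCC", cfg.prep, cfg.dml)
    table = ReportTable("robustness")
    table.add("benchmark", benchmark)

    for lo, hi in cfg.winsor_presets:
        pw = winsorize(panel, (lo, hi), exclude=cfg.prep.exclude_from_winsor)
        table.add(f"winsor {lo:g}/{hi:g}", dml_plr(pw, "PHL", "SCC", cfg.prep, cfg.dml), winsor=[lo, hi])

    table.add("province x trend", dml_plr(panel, "PHL", "SCC", cfg.prep.with_(province_trend=True), cfg.dml),
              province_trend=True)

    policy_cols = tuple(c for c in cfg.policy_dummy_cols if c in panel.df.columns)
    if policy_cols:
        table.add("policy dummies", dml_plr(panel, "PHL", "SCC", cfg.prep.with_(policy_dummies=policy_cols), cfg.dml),
                  policy_dummies=list(policy_cols))

    if cfg.iv_instrument_col in panel.df.columns:
        iv = IVConfig(instrument_base_col=cfg.iv_instrument_col, dml=cfg.dml)
        table.add("PLIV (historical IV)", dml_pliv(panel, "PHL", "SCC", iv, cfg.prep), instrument=cfg.iv_instrument_col)

    for k in cfg.fold_presets:
        table.add(f"{k} folds", dml_plr(panel, "PHL", "SCC", cfg.prep, cfg.dml.with_(n_folds=k)), n_folds=k)

    table.add(f"learner: {cfg.swap_learner}",
              dml_plr(panel, "PHL", "SCC", cfg.prep, cfg.dml.with_(learner=cfg.swap_learner, learner_params={})),
              learner=cfg.swap_learner)

    bench_sign = np.sign(benchmark.theta_hat)
    bench_sig = abs(benchmark.t_stat) > 1.96
    comparison = []
    for c in table.columns[1:]:
        r = c["result"]
        comparison.append({
            "variant": c["label"],
            "same_sign": bool(np.sign(r.theta_hat) == bench_sign),
            "same_significance_5pct": bool((abs(r.t_stat) > 1.96) == bench_sig),
            "theta_shift_in_benchmark_se": float((r.theta_hat - benchmark.theta_hat) / benchmark.se),
        })
    return {"table": table, "comparison": comparison}


def run_heterogeneity(panel: PanelDataset, cfg: StudyConfig) -> dict[str, ReportTable]:
    """Per-subgroup PLR fits.

    For the pilot-batch analysis each batch's adopters are compared against
    never-treated cities only, so other waves never contaminate the control
    group.  Subgroups too small to cross-fit are skipped with a warning.
    """
    out: dict[str, ReportTable] = {}
    df = panel.df
    for var in cfg.subgroup_vars:
        if var not in df.columns:
            warnings.warn(f"subgroup variable {var!r} not in panel; skipped")
            continue
        table = ReportTable(f"heterogeneity_{var}")
        levels = [lv for lv in pd.unique(df[var]) if not (var == "batch" and lv == "none")]
        for lv in sorted(map(str, levels)):
            if var == "batch":
                mask = (df[var].astype(str) == lv) | (df[var].astype(str) == "none")
            else:
                mask = df[var].astype(str) == lv
            sub = df[mask]
            if len(sub) < 2 * cfg.dml.n_folds or sub["SCC"].nunique() < 2 or sub["city_id"].nunique() < cfg.dml.n_folds:
                warnings.warn(f"subgroup {var}={lv}: too little data, skipped")
                continue
            sub_panel = PanelDataset(sub.reset_index(drop=True), list(panel.control_cols), list(panel.mediator_cols))
            res = dml_plr(sub_panel, "PHL", "SCC", cfg.prep, cfg.dml)
            table.add(str(lv), res, subgroup=f"{var}={lv}")
        out[var] = table
    return out


def run_full_study(cfg: StudyConfig, out_dir: str | Path | None = None) -> dict:
    """Generate the panel, construct the index, and run every stage.

    Writes ``results/*.json``, ``tables/*.md`` and ``manifest.json`` under
    ``out_dir``; the returned bundle mirrors the files.  Output content is a
    pure function of the config (runtimes go to the log, not the bundle).
    """
    out_path = Path(out_dir if out_dir is not None else cfg.out_dir)
    (out_path / "results").mkdir(parents=True, exist_ok=True)
    (out_path / "tables").mkdir(parents=True, exist_ok=True)

    bundle: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stages": [], "partial": False}
    panel = generate_panel(cfg.dgp)
    bundle["truth"] = true_effects(cfg.dgp)
    bundle["n_obs"] = len(panel.df)

    def _stage(name, fn):
        try:
            value = fn()
            bundle["stages"].append(name)
            return value
        except Exception as exc:  # record and continue: bundle marked partial
            warnings.warn(f"stage {name} failed: {exc}")
            bundle["partial"] = True
            bundle.setdefault("errors", {})[name] = str(exc)
            return None

    if cfg.run_index_construction:
        def _index():
            tbl = generate_indicator_table(cfg.dgp)
            specs = [IndicatorSpec(n, d) for n, d in INDICATOR_DIRECTIONS.items()]
            res = composite_index(tbl, specs)
            return {
                "weights": dict(zip(res.names, map(float, res.weights))),
                "entropies": dict(zip(res.names, map(float, res.entropies))),
                "index_mean": float(res.index.mean()),
                "index_min": float(res.index.min()),
                "index_max": float(res.index.max()),
                "index_skewness": float(pd.Series(res.index).skew()),
            }
        bundle["index"] = _stage("index", _index)

    panel = interpolate_missing(panel)
    if cfg.prep.winsor_bounds is not None:
        panel = winsorize(panel, cfg.prep.winsor_bounds, cfg.prep.exclude_from_winsor)

    bench_table = _stage("benchmark", lambda: run_benchmark(panel, cfg))
    tables: dict[str, ReportTable] = {}
    if bench_table is not None:
        tables["benchmark"] = bench_table
        bundle["benchmark"] = bench_table.to_dict()
        bench_res = bench_table.columns[-1]["result"]
    else:
        bench_res = None

    rob = _stage("robustness", lambda: run_robustness(panel, cfg, benchmark=bench_res))
    if rob is not None:
        tables["robustness"] = rob["table"]
        bundle["robustness"] = {"table": rob["table"].to_dict(), "comparison": rob["comparison"]}

    if cfg.mediators:
        # one estimator for the whole mediation stage (points and bootstrap),
        # so the CI always brackets the reported indirect effect
        med_cfg = cfg.dml.with_(learner=cfg.boot_learner, learner_params={})
        def _mediation():
            out = {}
            for m in cfg.mediators:
                res = bootstrap_indirect(panel, m, cfg.prep, med_cfg, n_boot=cfg.n_boot)
                out[m] = res.to_dict()
            return out
        med = _stage("mediation", _mediation)
        if med is not None:
            bundle["mediation"] = med

    het = _stage("heterogeneity", lambda: run_heterogeneity(panel, cfg))
    if het is not None:
        for var, t in het.items():
            tables[f"heterogeneity_{var}"] = t
        bundle["heterogeneity"] = {var: t.to_dict() for var, t in het.items()}

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "dml_seed": cfg.dml.seed,
        "dgp_seed": cfg.dgp.seed,
        "stages": bundle["stages"],
        "partial": bundle["partial"],
        "n_obs": bundle["n_obs"],
    }
    for name, content in [("study", bundle), ("manifest", manifest)]:
        with open(out_path / ("manifest.json" if name == "manifest" else f"results/{name}.json"), "w") as fh:
            json.dump(content, fh, indent=2, sort_keys=True)
    for name, t in tables.items():
        (out_path / "tables" / f"{name}.md").write_text(t.to_markdown())
    return bundle
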