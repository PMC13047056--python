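"""Generator contracts: balance, absorbing treatment, wave sizes, determinism,

ground-truth arithmetic, and the confound-free null case."""

import numpy as np
import pandas as pd
import pytest

from paneldml.index_entropy import IndicatorSpec, composite_index
from paneldml.synthetic_panel import (
    DGPConfig,
    INDICATOR_DIRECTIONS,
    generate_indicator_table,
    generate_panel,
    true_effects,
)
from tests.conftest import ols_fit


def test_panel_bookkeeping_at_study_scale():
    cfg = DGPConfig(seed=5)
    panel = generate_panel(cfg)
    assert len(panel.df) == 270 * 14
    # absorbing treatment within every city
    mono = panel.df.sort_values(["city_id", "year"]).groupby("city_id")["SCC"].diff().dropna()
    assert (mono >= 0).all()
    # treated city-year share close to the study's 0.171
    assert panel.df["SCC"].mean() == pytest.approx(0.171, abs=0.005)


def test_wave_sizes_follow_floor_rule():
    cfg = DGPConfig(n_cities=53, n_years=10, start_year=2007,
                    adoption_waves=((2010, 0.10), (2012, 0.25)),
                    mediator_paths={}, mediator_noise_sd={}, seed=2)
    panel = generate_panel(cfg)
    per_batch = panel.df.drop_duplicates("city_id")["batch"].value_counts()
    assert per_batch.get("1", 0) == int(np.floor(0.10 * 53))
    assert per_batch.get("2", 0) == int(np.floor(0.25 * 53))
    assert per_batch.get("none", 0) == 53 - 5 - 13


def test_same_seed_bitwise_identical():
    cfg = DGPConfig(n_cities=30, n_years=6, adoption_waves=((2009, 0.2),), seed=77)
    p1, p2 = generate_panel(cfg), generate_panel(cfg)
    pd.testing.assert_frame_equal(p1.df, p2.df, check_exact=True)


def test_null_effect_without_confounding():
    """theta=0 and no confounding: treated/untreated outcome gap ~ 0."""
    diffs = []
    for s in range(30):
        cfg = DGPConfig(n_cities=60, n_years=8, theta_true=0.0, confounding_strength=0.0,
                        instrument_strength=0.0, nonlinear_nuisance=False, fe_sd_city=0.0,
                        adoption_waves=((2009, 0.2),), confounder_dim=4,
                        mediator_paths={}, mediator_noise_sd={}, seed=100 + s)
        df = generate_panel(cfg).df
        diffs.append(df.loc[df.SCC == 1, "PHL"].mean() - df.loc[df.SCC == 0, "PHL"].mean())
    mc_se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
    assert abs(np.mean(diffs)) < 3 * mc_se + 1e-12


def test_ols_recovers_theta_on_linear_dgp():
    """Closed-form OLS oracle on a linear, no-FE panel recovers theta."""
    cfg = DGPConfig(n_cities=120, n_years=10, theta_true=0.5, nonlinear_nuisance=False,
                    fe_sd_city=0.0, fe_sd_year=0.0, adoption_waves=((2010, 0.15), (2012, 0.15)),
                    confounder_dim=5, mediator_paths={}, mediator_noise_sd={}, seed=9)
    df = generate_panel(cfg).df
    X = df[[f"X{j}" for j in range(1, 6)]].to_numpy()
    Z = np.column_stack([np.ones(len(df)), df["SCC"].to_numpy(), X])
    beta, se = ols_fit(df["PHL"].to_numpy(), Z)
    assert abs(beta[1] - 0.5) < 3 * se[1]


def test_pretreatment_trends_parallel_without_confounding():
    """With no confounding or endogeneity, eventual adopters and never-adopters

    have equal pre-treatment outcome trends in expectation."""
    gaps = []
    for s in range(200):
        cfg = DGPConfig(n_cities=40, n_years=8, confounding_strength=0.0, instrument_strength=0.0,
                        endogeneity_rho=0.0, adoption_waves=((2011, 0.3),), confounder_dim=4,
                        nonlinear_nuisance=False, mediator_paths={}, mediator_noise_sd={}, seed=500 + s)
        df = generate_panel(cfg).df
        pre = df[df.year < 2011]
        adopter = pre.merge(df.groupby("city_id")["SCC"].max().rename("ever"), on="city_id")

        def slope(sub):
            return np.polyfit(sub["year"], sub["PHL"], 1)[0]

        gaps.append(slope(adopter[adopter.ever == 1]) - slope(adopter[adopter.ever == 0]))
    mc_se = np.std(gaps, ddof=1) / np.sqrt(len(gaps))
    assert abs(np.mean(gaps)) < 3 * mc_se


def test_true_effects_arithmetic():
    cfg = DGPConfig(theta_true=0.15, mediator_paths={"A": (0.2, 0.5), "B": (0.1, 0.3)},
                    mediator_noise_sd={})
    eff = true_effects(cfg)
    assert eff["indirect"]["A"] == pytest.approx(0.10)
    assert eff["indirect"]["B"] == pytest.approx(0.03)
    assert eff["total"] == pytest.approx(0.15 + 0.13)
    zero = true_effects(cfg.with_(mediator_paths={"A": (0.0, 0.5), "B": (0.2, 0.0)}))
    assert all(v == 0 for v in zero["indirect"].values())


def test_config_validation_refusals():
    with pytest.raises(ValueError, match="degenerate"):
        generate_panel(DGPConfig(n_cities=3, n_years=2, confounder_dim=10,
                                 adoption_waves=(), mediator_paths={}, mediator_noise_sd={}))
    with pytest.raises(ValueError, match="sum"):
        DGPConfig(adoption_waves=((2010, 0.7), (2012, 0.7))).validate()
    with pytest.raises(ValueError, match="outside"):
        DGPConfig(adoption_waves=((1990, 0.1),)).validate()


def test_indicator_table_contract():
    cfg = DGPConfig(n_cities=30, n_years=6, adoption_waves=((2009, 0.2),),
                    mediator_paths={}, mediator_noise_sd={}, seed=4)
    tbl = generate_indicator_table(cfg)
    assert list(INDICATOR_DIRECTIONS) == [c for c in tbl.columns if c not in ("city_id", "year")]
    assert INDICATOR_DIRECTIONS["infection_incidence"] == "negative"
    assert (tbl[list(INDICATOR_DIRECTIONS)] > 0).all().all()


def test_noiseless_indicators_make_index_monotone_in_latent():
    """At zero indicator noise the entropy index is a monotone transform of

    the latent health factor (rank correlation 1 with the panel outcome)."""
    cfg = DGPConfig(n_cities=30, n_years=6, adoption_waves=((2009, 0.2),),
                    mediator_paths={}, mediator_noise_sd={}, indicator_noise_sd=0.0, seed=4)
    tbl = generate_indicator_table(cfg)
    panel = generate_panel(cfg)
    specs = [IndicatorSpec(n, d) for n, d in INDICATOR_DIRECTIONS.items()]
    res = composite_index(tbl, specs)
    rho = pd.Series(res.index).corr(panel.df["PHL"], method="spearman")
    assert rho == pytest.approx(1.0, abs=1e-12)
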