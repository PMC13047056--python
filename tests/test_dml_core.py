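"""PLR estimator: moment arithmetic, cross-fitting bookkeeping, determinism,

orthogonality diagnostics, and oracle equivalences."""

import numpy as np
import pytest

from paneldml.design_prep import build_design
from paneldml.dml_core import (
    DMLConfig,
    ResidualSet,
    crossfit_nuisances,
    dml_plr,
    estimate_theta,
    plr_from_arrays,
)
from paneldml.synthetic_panel import DGPConfig, generate_panel
from tests.conftest import ols_fit


class TestEstimateTheta:
    def test_hand_evaluated_ratio(self):
        res = ResidualSet(vhat=np.array([1.0, -1.0, 0.0]), ytilde=np.array([2.0, 0.0, 1.0]))
        assert estimate_theta(res, np.array([1.0, 0.0, 0.0])) == 2.0

    def test_proportional_case_exact(self):
        v = np.array([0.5, -1.0, 2.0, -1.5])
        res = ResidualSet(vhat=v, ytilde=3.25 * v)
        assert estimate_theta(res, v) == pytest.approx(3.25, abs=1e-14)

    def test_orthogonal_numerator_gives_zero(self):
        res = ResidualSet(vhat=np.array([1.0, -1.0]), ytilde=np.array([2.0, 2.0]))
        assert estimate_theta(res, np.array([2.0, 1.0])) == pytest.approx(0.0)

    def test_no_residual_variation_refused(self):
        res = ResidualSet(vhat=np.zeros(3), ytilde=np.ones(3))
        with pytest.raises(ValueError, match="unidentified"):
            estimate_theta(res, np.array([1.0, 0.0, 1.0]))


class TestCrossfit:
    def test_partition_bookkeeping(self):
        rng = np.random.default_rng(0)
        y, d, X = rng.normal(size=100), rng.integers(0, 2, 100).astype(float), rng.normal(size=(100, 3))
        fit = crossfit_nuisances(y, d, X, DMLConfig(n_folds=5, learner="linear", seed=3))
        sizes = np.bincount(fit.fold_id, minlength=5)
        assert (sizes == 20).all()
        assert ((fit.mhat >= 0) & (fit.mhat <= 1)).all()  # propensity clipped

    def test_determinism(self):
        rng = np.random.default_rng(1)
        y, d, X = rng.normal(size=60), rng.normal(size=60), rng.normal(size=(60, 2))
        cfg = DMLConfig(learner="linear", seed=9)
        f1, f2 = crossfit_nuisances(y, d, X, cfg), crossfit_nuisances(y, d, X, cfg)
        np.testing.assert_array_equal(f1.fold_id, f2.fold_id)
        np.testing.assert_array_equal(f1.ghat, f2.ghat)

    def test_realizable_linear_function_recovered(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 4))
        y = 1.5 + X @ np.array([1.0, -2.0, 0.5, 0.0])
        d = rng.integers(0, 2, 200).astype(float)  # independent of X
        fit = crossfit_nuisances(y, d, X, DMLConfig(learner="linear", seed=0))
        assert np.max(np.abs(fit.ghat - y)) < 1e-5
        assert np.abs(fit.mhat.mean() - d.mean()) < 0.1

    def test_constant_treatment_fold_falls_back_to_mean(self):
        rng = np.random.default_rng(3)
        y, X = rng.normal(size=30), rng.normal(size=(30, 2))
        d = np.zeros(30)
        d[0] = 1.0  # some training splits see no treated unit
        with pytest.warns(UserWarning, match="constant treatment"):
            crossfit_nuisances(y, d, X, DMLConfig(n_folds=5, learner="linear", seed=1))


class TestPLR:
    def test_outcome_translation_invariance_linear_learner(self, small_panel, lean_prep):
        cfg = DMLConfig(learner="linear", seed=5)
        r0 = dml_plr(small_panel, "PHL", "SCC", lean_prep, cfg)
        shifted = small_panel.copy()
        shifted.df["PHL"] = shifted.df["PHL"] + 100.0
        r1 = dml_plr(shifted, "PHL", "SCC", lean_prep, cfg)
        assert r1.theta_hat == pytest.approx(r0.theta_hat, abs=1e-8)

    def test_constant_treatment_refused(self, small_panel, lean_prep):
        panel = small_panel.copy()
        panel.df["SCC"] = 0.0
        with pytest.raises(ValueError, match="constant"):
            dml_plr(panel, "PHL", "SCC", lean_prep, DMLConfig(learner="linear"))

    def test_orthogonality_diagnostics_at_large_n(self, lean_prep):
        cfg = DGPConfig(n_cities=125, n_years=8, nonlinear_nuisance=False, fe_sd_city=0.0,
                        confounding_strength=0.5,
                        adoption_waves=((2009, 0.15), (2011, 0.15)), confounder_dim=5,
                        mediator_paths={}, mediator_noise_sd={}, seed=31)
        panel = generate_panel(cfg)
        res = dml_plr(panel, "PHL", "SCC", lean_prep, DMLConfig(learner="linear", seed=2))
        assert abs(res.diagnostics["mean_vhat"]) < 0.05
        assert abs(res.diagnostics["corr_vhat_mhat"]) < 0.05

    def test_fwl_oracle_equivalence_linear_dgp(self, lean_prep):
        """Cross-fitted DML with the linear learner agrees with exact OLS

        partialling (Frisch-Waugh-Lovell) on a linear DGP."""
        cfg = DGPConfig(n_cities=200, n_years=10, theta_true=0.5, nonlinear_nuisance=False,
                        fe_sd_city=0.0, adoption_waves=((2010, 0.15), (2012, 0.15)),
                        confounder_dim=5, mediator_paths={}, mediator_noise_sd={}, seed=17)
        panel = generate_panel(cfg)
        X = build_design(panel, lean_prep).values
        y, d = panel.df["PHL"].to_numpy(), panel.df["SCC"].to_numpy()
        res = plr_from_arrays(y, d, X, panel.df["city_id"].to_numpy(), DMLConfig(learner="linear", seed=1))
        beta, _ = ols_fit(y, np.column_stack([np.ones(len(y)), d, X]))
        assert abs(res.theta_hat - beta[1]) <= 0.01

    def test_repeats_aggregate_by_median(self, small_panel, lean_prep):
        cfg = DMLConfig(learner="linear", seed=5, n_repeats=3)
        res = dml_plr(small_panel, "PHL", "SCC", lean_prep, cfg)
        assert len(res.thetas) == 3
        assert res.theta_hat == pytest.approx(float(np.median(res.thetas)))
        lo, hi = res.ci95
        assert lo == pytest.approx(res.theta_hat - 1.96 * res.se)
        assert hi == pytest.approx(res.theta_hat + 1.96 * res.se)
        assert res.t_stat == pytest.approx(res.theta_hat / res.se)

    def test_cluster_folds_keep_cities_together(self, small_panel, lean_prep):
        cfg = DMLConfig(learner="linear", seed=5, cluster_folds=True)
        design = build_design(small_panel, lean_prep)
        fit = crossfit_nuisances(
            small_panel.df["PHL"].to_numpy(), small_panel.df["SCC"].to_numpy(),
            design.values, cfg, groups=small_panel.df["city_id"].to_numpy(),
        )
        per_city = {}
        for cid, fold in zip(small_panel.df["city_id"], fit.fold_id):
            per_city.setdefault(cid, set()).add(fold)
        assert all(len(folds) == 1 for folds in per_city.values())
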