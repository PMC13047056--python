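"""Cross-fitted partial-linear double machine learning (DML).

Model: Y = theta * D + g(X) + U with E[U | D, X] = 0, plus the auxiliary
treatment equation D = m(X) + V with E[V | X] = 0.  Both conditional
expectations are learned by pluggable ML regressors under K-fold
cross-fitting (each observation predicted by models trained on the other
folds), and theta is estimated from the Neyman-orthogonal moment that uses
the treatment residual V-hat as an instrument for D:

    theta_hat = (sum V_it * D_it)^(-1) * sum V_it * (Y_it - g_hat(X_it)).

Inference uses the influence-function sandwich for the PLR score
psi = V * (Ytilde - theta * D), clustered at the panel unit (city) level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor

from paneldml.design_prep import PrepConfig, build_design
from paneldml.synthetic_panel import PanelDataset

__all__ = [
    "DMLConfig",
    "NuisanceFit",
    "ResidualSet",
    "DMLResult",
    "make_learner",
    "crossfit_nuisances",
    "estimate_theta",
    "dml_plr",
    "plr_from_arrays",
    "naive_ols",
]


@dataclass(frozen=True)
class DMLConfig:
    """Estimator settings.

    ``n_folds=5`` corresponds to a 1:4 holdout:training split; 4 and 8 give
    the 1:3 and 1:7 variants.  ``cluster_col`` names the panel unit used both
    for clustered standard errors and (optionally, ``cluster_folds``) for
    assigning whole units to folds.
    """

    n_folds: int = 5
    learner: str = "random_forest"
    learner_params: dict = field(default_factory=dict)
    n_repeats: int = 1
    seed: int = 0
    cluster_col: str = "city_id"
    cluster_folds: bool = False

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.learner not in ("random_forest", "gradient_boosting", "linear"):
            raise ValueError(f"unknown learner {self.learner!r}")

    def with_(self, **kwargs) -> "DMLConfig":
        return replace(self, **kwargs)


class LinearLearner:
    """Least-squares regressor on an intercept-augmented design.

    Solves ridge-stabilized normal equations (tiny penalty, excluding the
    intercept) so collinear dummy blocks do not blow up.  Fast enough for
    tight Monte-Carlo and bootstrap loops.
    """

    def __init__(self, ridge: float = 1e-8):
        self.ridge = ridge
        self.coef_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearLearner":
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        Xa = np.empty((n, p + 1))
        Xa[:, 0] = 1.0
        Xa[:, 1:] = X
        G = Xa.T @ Xa
        scale = max(np.trace(G) / (p + 1), 1.0)
        G[np.arange(1, p + 1), np.arange(1, p + 1)] += self.ridge * scale
        self.coef_ = np.linalg.solve(G, Xa.T @ y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.coef_[0] + X @ self.coef_[1:]


def make_learner(name: str, params: dict, random_state: int):
    """Instantiate a nuisance regressor.

    The binary treatment is modeled with the same regressor family as the
    outcome (a regression forest's conditional mean is the propensity); the
    prediction is clipped to [0, 1] downstream.
    """
    params = dict(params)
    if name == "linear":
        return LinearLearner(**params)
    if name == "random_forest":
        defaults = dict(n_estimators=500, min_samples_leaf=5, max_features="sqrt", n_jobs=1)
        defaults.update(params)
        return RandomForestRegressor(random_state=random_state, **defaults)
    if name == "gradient_boosting":
        defaults = dict(max_iter=200)
        defaults.update(params)
        return HistGradientBoostingRegressor(random_state=random_state, **defaults)
    raise ValueError(f"unknown learner {name!r}")


@dataclass
class NuisanceFit:
    """Out-of-fold nuisance predictions under the cross-fitting contract:

    every prediction comes from models trained on folds that exclude the
    predicted observation."""

    ghat: np.ndarray
    mhat: np.ndarray
    fold_id: np.ndarray

    def r2(self, y: np.ndarray, d: np.ndarray) -> tuple[float, float]:
        """Out-of-fold R^2 of the outcome and treatment nuisances."""
        def _r2(t, p):
            ss = np.var(t)
            return float(1.0 - np.mean((t - p) ** 2) / ss) if ss > 0 else float("nan")
        return _r2(y, self.ghat), _r2(d, self.mhat)


@dataclass
class ResidualSet:
    vhat: np.ndarray    # D - m_hat(X)
    ytilde: np.ndarray  # Y - g_hat(X)


@dataclass
class DMLResult:
    theta_hat: float
    se: float
    t_stat: float
    ci95: tuple[float, float]
    n_obs: int
    thetas: list[float]
    diagnostics: dict

    @property
    def p_value(self) -> float:
        from scipy.stats import norm
        return float(2.0 * norm.sf(abs(self.t_stat)))

    def to_dict(self) -> dict:
        return {
            "theta_hat": self.theta_hat,
            "se": self.se,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
            "ci95": list(self.ci95),
            "n_obs": self.n_obs,
            "thetas": list(self.thetas),
            "diagnostics": {k: v for k, v in self.diagnostics.items()},
        }


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator, groups: np.ndarray | None) -> np.ndarray:
    """Seeded-permutation, contiguous-block fold assignment.

    With ``groups`` given, whole units are assigned to folds so no unit
    straddles a training/holdout boundary.
    """
    fold_id = np.empty(n, dtype=np.int64)
    if groups is None:
        perm = rng.permutation(n)
        for k, block in enumerate(np.array_split(perm, n_folds)):
            fold_id[block] = k
    else:
        uniq = np.unique(groups)
        perm = rng.permutation(len(uniq))
        g2f = {}
        for k, block in enumerate(np.array_split(perm, n_folds)):
            for gi in block:
                g2f[uniq[gi]] = k
        fold_id[:] = [g2f[g] for g in groups]
    return fold_id


def _seed_for(base_seed: int, *path: int) -> int:
    """Deterministic 31-bit child seed for a (repeat, fold, task) path."""
    return int(np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, *path]).generate_state(1)[0] & 0x7FFFFFFF)


def crossfit_nuisances(
    y: np.ndarray,
    d: np.ndarray,
    X: np.ndarray,
    cfg: DMLConfig,
    groups: np.ndarray | None = None,
    repeat: int = 0,
) -> NuisanceFit:
    """K-fold cross-fitted out-of-fold predictions of E[Y|X] and E[D|X].

    A training fold with constant treatment falls back to mean prediction
    for the held-out fold (with a warning) rather than failing.
    """
    y = np.asarray(y, dtype=float)
    d = np.asarray(d, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    if n < 2 * cfg.n_folds:
        raise ValueError(f"need at least {2 * cfg.n_folds} observations for {cfg.n_folds}-fold cross-fitting")
    if np.isnan(X).any() or np.isnan(y).any() or np.isnan(d).any():
        raise ValueError("missing values in estimator inputs")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 7, repeat]))
    fold_id = _fold_indices(n, cfg.n_folds, rng, groups if cfg.cluster_folds else None)

    binary_d = set(np.unique(d)) <= {0.0, 1.0}
    ghat = np.empty(n)
    mhat = np.empty(n)
    for k in range(cfg.n_folds):
        test = fold_id == k
        train = ~test
        if test.sum() == 0:
            continue
        g_model = make_learner(cfg.learner, cfg.learner_params, _seed_for(cfg.seed, repeat, k, 0))
        g_model.fit(X[train], y[train])
        ghat[test] = g_model.predict(X[test])
        if np.ptp(d[train]) == 0:
            warnings.warn(f"fold {k}: constant treatment in training data, using mean prediction")
            mhat[test] = d[train].mean()
        else:
            m_model = make_learner(cfg.learner, cfg.learner_params, _seed_for(cfg.seed, repeat, k, 1))
            m_model.fit(X[train], d[train])
            mhat[test] = m_model.predict(X[test])
    if binary_d:
        mhat = np.clip(mhat, 0.0, 1.0)
    return NuisanceFit(ghat=ghat, mhat=mhat, fold_id=fold_id)


def estimate_theta(res: ResidualSet, d: np.ndarray) -> float:
    """The orthogonalized estimate: ratio of sum(V*(Y - g_hat)) to sum(V*D),

    i.e. the treatment residual used as an instrument for the treatment."""
    d = np.asarray(d, dtype=float)
    denom = float(res.vhat @ d)
    if abs(denom) < 1e-12 * max(1, len(d)):
        raise ValueError("no residual treatment variation: sum(V*D) ~ 0, theta unidentified")
    return float(res.vhat @ res.ytilde) / denom


def _clustered_variance(psi: np.ndarray, J: float, clusters: np.ndarray) -> float:
    codes, _ = pd.factorize(clusters)
    cluster_sums = np.bincount(codes, weights=psi)
    return float((cluster_sums**2).sum() / J**2)


def plr_from_arrays(
    y: np.ndarray,
    d: np.ndarray,
    X: np.ndarray,
    clusters: np.ndarray,
    cfg: DMLConfig,
) -> DMLResult:
    """Full PLR fit on raw arrays (the hot path for Monte-Carlo loops).

    Repeats cross-fitting ``cfg.n_repeats`` times with fresh fold splits and
    aggregates by the median theta and median of the per-repeat variances.
    """
    y = np.asarray(y, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.ptp(d) == 0:
        raise ValueError("treatment column is constant: effect unidentified")
    thetas, variances, diags = [], [], []
    for r in range(cfg.n_repeats):
        fit = crossfit_nuisances(y, d, X, cfg, groups=clusters, repeat=r)
        res = ResidualSet(vhat=d - fit.mhat, ytilde=y - fit.ghat)
        theta_r = estimate_theta(res, d)
        psi = res.vhat * (res.ytilde - theta_r * d)
        J = float(res.vhat @ d)
        var_r = _clustered_variance(psi, J, clusters)
        r2g, r2m = fit.r2(y, d)
        sd_v, sd_m = res.vhat.std(), fit.mhat.std()
        corr_vm = float(np.corrcoef(res.vhat, fit.mhat)[0, 1]) if sd_v > 0 and sd_m > 0 else 0.0
        diags.append({
            "oof_r2_outcome": r2g,
            "oof_r2_treatment": r2m,
            "mean_vhat": float(res.vhat.mean()),
            "corr_vhat_mhat": corr_vm,
        })
        thetas.append(theta_r)
        variances.append(var_r)
    theta = float(np.median(thetas))
    se = float(np.sqrt(np.median(variances)))
    diag = {k: float(np.median([d_[k] for d_ in diags])) for k in diags[0]}
    return DMLResult(
        theta_hat=theta,
        se=se,
        t_stat=theta / se,
        ci95=(theta - 1.96 * se, theta + 1.96 * se),
        n_obs=len(y),
        thetas=[float(t) for t in thetas],
        diagnostics=diag,
    )


def dml_plr(
    panel: PanelDataset,
    outcome_col: str,
    treatment_col: str,
    design_cfg: PrepConfig,
    cfg: DMLConfig,
) -> DMLResult:
    """Estimate the partial-linear treatment effect on a prepared panel.

    Orchestrates design construction, cross-fitted nuisances, residual
    orthogonalization and the moment estimate, with city-clustered
    influence-function standard errors.
    """
    design = build_design(panel, design_cfg)
    df = panel.df
    y = df[outcome_col].to_numpy(dtype=float)
    d = df[treatment_col].to_numpy(dtype=float)
    clusters = df[cfg.cluster_col].to_numpy()
    return plr_from_arrays(y, d, design.values, clusters, cfg)


def naive_ols(y: np.ndarray, d: np.ndarray, X: np.ndarray) -> float:
    """Benchmark comparator: plain OLS coefficient on D given [1, D, X].

    This is the 'traditional' linear regression the orthogonalized estimator
    is meant to improve upon when the true nuisance is nonlinear.
    """
    n = len(y)
    Z = np.column_stack([np.ones(n), d, X])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return float(beta[1])
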