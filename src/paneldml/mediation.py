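"""Mechanism (mediation) analysis inside the orthogonalized framework.

Path a: the policy's effect on a mediator, estimated by the same
partial-linear DML as the main fit with the mediator as outcome.  Path b:
the mediator's effect on the outcome holding the policy fixed, from a joint
moment fit that keeps the main estimator's residual-as-instrument
convention (all of outcome, treatment and mediator residualized on X by
cross-fitted learners), so the total effect decomposes exactly into
direct + a*b.
The indirect effect is the product a*b; its uncertainty comes from a
city-block bootstrap (whole cities resampled with replacement, nuisances
re-fit per replicate) with a percentile confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from paneldml.design_prep import PrepConfig, build_design
from paneldml.dml_core import DMLConfig, DMLResult, _clustered_variance, _seed_for, crossfit_nuisances, make_learner, plr_from_arrays
from paneldml.synthetic_panel import PanelDataset

__all__ = ["MediationResult", "path_a", "path_b", "bootstrap_indirect"]

import pandas as pd


@dataclass
class MediationResult:
    mediator: str
    a_hat: float
    a_se: float
    b_hat: float
    b_se: float
    theta_direct: float
    theta_direct_se: float
    indirect: float            # a_hat * b_hat, exactly
    boot_ci95: tuple[float, float]
    n_boot: int
    boot_seed: int
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {
            "mediator": self.mediator,
            "a_hat": self.a_hat, "a_se": self.a_se,
            "b_hat": self.b_hat, "b_se": self.b_se,
            "theta_direct": self.theta_direct, "theta_direct_se": self.theta_direct_se,
            "indirect": self.indirect,
            "boot_ci95": list(self.boot_ci95),
            "n_boot": self.n_boot, "boot_seed": self.boot_seed, "n_failed": self.n_failed,
        }


def _residualize_three(y, d, m, X, clusters, cfg: DMLConfig, repeat: int = 0):
    """Cross-fit E[Y|X], E[D|X], E[M|X]; the mediator uses the same fold

    partition as the outcome/treatment pair."""
    fit = crossfit_nuisances(y, d, X, cfg, groups=clusters, repeat=repeat)
    mtilde = np.empty_like(m)
    for k in range(cfg.n_folds):
        test = fit.fold_id == k
        train = ~test
        if test.sum() == 0:
            continue
        mm = make_learner(cfg.learner, cfg.learner_params, _seed_for(cfg.seed, repeat, k, 3))
        mm.fit(X[train], m[train])
        mtilde[test] = m[test] - mm.predict(X[test])
    return y - fit.ghat, d - fit.mhat, mtilde


def _joint_b_fit(ytilde, d, dtilde, mtilde, clusters):
    """Joint two-residual fit of the direct effect and the mediator slope.

    Solves the orthogonalized moment system with instruments (dtilde, mtilde)
    for the regressors (d, mtilde):

        dtilde' (ytilde - theta_direct * d - b * mtilde) = 0
        mtilde' (ytilde - theta_direct * d - b * mtilde) = 0

    i.e. the same treatment-residual-as-instrument convention as the main
    estimator, so theta_total = theta_direct + a*b holds exactly.  Clustered
    IV sandwich SEs.  Returns (theta_direct, b, se_direct, se_b).
    """
    sd_d, sd_m = dtilde.std(), mtilde.std()
    if sd_d <= 0 or sd_m <= 0:
        raise ValueError("degenerate residuals in joint b-path regression")
    r = float(np.corrcoef(dtilde, mtilde)[0, 1])
    if abs(r) > 0.999:
        raise ValueError(f"treatment and mediator residuals collinear (corr={r:.4f})")
    Z = np.column_stack([dtilde, mtilde])
    R = np.column_stack([d, mtilde])
    J = Z.T @ R
    beta = np.linalg.solve(J, Z.T @ ytilde)
    e = ytilde - R @ beta
    codes, _ = pd.factorize(clusters)
    sums = np.column_stack([np.bincount(codes, weights=Z[:, j] * e) for j in range(2)])
    omega = sums.T @ sums
    Jinv = np.linalg.inv(J)
    V = Jinv @ omega @ Jinv.T
    return float(beta[0]), float(beta[1]), float(np.sqrt(V[0, 0])), float(np.sqrt(V[1, 1]))


def _paths_from_arrays(y, d, m, X, clusters, cfg: DMLConfig):
    """(a_hat, a_se, theta_direct, b_hat, se_t, se_b) from one cross-fit pass.

    The a-path SE uses the same clustered influence-function sandwich as the
    main PLR fit, on the residuals already in hand."""
    ytilde, dtilde, mtilde = _residualize_three(y, d, m, X, clusters, cfg)
    denom = float(dtilde @ d)
    if abs(denom) < 1e-12 * max(1, len(d)):
        raise ValueError("no residual treatment variation")
    a_hat = float(dtilde @ mtilde) / denom
    psi_a = dtilde * (mtilde - a_hat * d)
    a_se = float(np.sqrt(_clustered_variance(psi_a, denom, clusters)))
    theta_direct, b_hat, se_t, se_b = _joint_b_fit(ytilde, d, dtilde, mtilde, clusters)
    return a_hat, a_se, theta_direct, b_hat, se_t, se_b, (ytilde, dtilde, mtilde)


def path_a(panel: PanelDataset, mediator_col: str, design_cfg: PrepConfig, cfg: DMLConfig) -> DMLResult:
    """Treatment -> mediator path: partial-linear DML with the mediator as outcome."""
    design = build_design(panel, design_cfg)
    df = panel.df
    return plr_from_arrays(
        df[mediator_col].to_numpy(dtype=float),
        df["SCC"].to_numpy(dtype=float),
        design.values,
        df[cfg.cluster_col].to_numpy(),
        cfg,
    )


def path_b(panel: PanelDataset, mediator_col: str, design_cfg: PrepConfig, cfg: DMLConfig,
           outcome_col: str = "PHL", treatment_col: str = "SCC"):
    """Mediator -> outcome path controlling the treatment.

    Returns a dict with ``b_hat``/``b_se`` (the mediator coefficient) and
    ``theta_direct``/``theta_direct_se`` (the treatment coefficient in the
    same joint residual regression).
    """
    design = build_design(panel, design_cfg)
    df = panel.df
    y = df[outcome_col].to_numpy(dtype=float)
    d = df[treatment_col].to_numpy(dtype=float)
    m = df[mediator_col].to_numpy(dtype=float)
    clusters = df[cfg.cluster_col].to_numpy()
    ytilde, dtilde, mtilde = _residualize_three(y, d, m, design.values, clusters, cfg)
    theta_direct, b_hat, se_t, se_b = _joint_b_fit(ytilde, d, dtilde, mtilde, clusters)
    return {"b_hat": b_hat, "b_se": se_b, "theta_direct": theta_direct, "theta_direct_se": se_t,
            "n_obs": len(y)}


def bootstrap_indirect(
    panel: PanelDataset,
    mediator_col: str,
    design_cfg: PrepConfig,
    cfg: DMLConfig,
    n_boot: int = 1000,
    boot_cfg: DMLConfig | None = None,
    outcome_col: str = "PHL",
    treatment_col: str = "SCC",
) -> MediationResult:
    """Indirect effect a*b with a city-block bootstrap percentile CI.

    Cities are resampled with replacement; nuisance learners are re-fit on
    every replicate (``boot_cfg`` may specify a cheaper learner, e.g. a
    reduced-size forest, for the replicates).  Aborts if more than 20% of
    replicates fail.
    """
    design = build_design(panel, design_cfg)
    df = panel.df
    y = df[outcome_col].to_numpy(dtype=float)
    d = df[treatment_col].to_numpy(dtype=float)
    m = df[mediator_col].to_numpy(dtype=float)
    X = design.values
    clusters = df[cfg.cluster_col].to_numpy()

    a_hat, a_se, theta_direct, b_hat, se_t, se_b = _paths_from_arrays(y, d, m, X, clusters, cfg)[:6]

    bcfg = boot_cfg if boot_cfg is not None else cfg
    city_rows: dict = {}
    for i, c in enumerate(clusters):
        city_rows.setdefault(c, []).append(i)
    city_ids = list(city_rows)
    row_blocks = [np.asarray(city_rows[c], dtype=np.int64) for c in city_ids]
    n_cities = len(city_ids)

    rng = np.random.default_rng(np.random.SeedSequence([bcfg.seed & 0x7FFFFFFF, 404]))
    draws = []
    n_failed = 0
    for rep in range(n_boot):
        pick = rng.integers(0, n_cities, size=n_cities)
        rows = np.concatenate([row_blocks[p] for p in pick])
        pseudo = np.concatenate([np.full(len(row_blocks[p]), j) for j, p in enumerate(pick)])
        rep_cfg = bcfg.with_(seed=_seed_for(bcfg.seed, 11, rep))
        try:
            out = _paths_from_arrays(y[rows], d[rows], m[rows], X[rows], pseudo, rep_cfg)
            a_r, b_r = out[0], out[3]
            draws.append(a_r * b_r)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
        if n_failed > 0.2 * n_boot:
            raise ValueError(f"bootstrap unstable: {n_failed} of {rep + 1} replicates failed")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return MediationResult(
        mediator=mediator_col,
        a_hat=a_hat, a_se=a_se,
        b_hat=b_hat, b_se=se_b,
        theta_direct=theta_direct, theta_direct_se=se_t,
        indirect=a_hat * b_hat,
        boot_ci95=(float(lo), float(hi)),
        n_boot=n_boot,
        boot_seed=int(bcfg.seed),
        n_failed=n_failed,
    )
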