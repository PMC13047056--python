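"""Synthetic staggered-adoption city-year panels with known causal structure.

The generator emulates the observational setting the estimators are built
for: a balanced panel of cities observed over ~14 years, a binary policy
(e.g. a smart-city pilot) switching on in waves and staying on, adoption
propensity loading on city-level confounders and on a historical instrument,
an outcome index driven by the policy, nonlinear nuisance functions of
high-dimensional controls, mediators on tunable a/b paths, and two-way fixed
effects.  Every causal parameter is a config field, so downstream estimators
have an exact ground-truth surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DGPConfig",
    "PanelDataset",
    "generate_panel",
    "generate_indicator_table",
    "true_effects",
    "INDICATOR_DIRECTIONS",
]

#: The five raw outcome indicators and their direction: three capacity-side
#: inputs (fiscal health spending per capita, hospital beds and doctors per
#: 10k residents) plus two performance-side outcomes (survival rate, and
#: infectious-disease incidence, which is a loss indicator).
INDICATOR_DIRECTIONS: dict[str, str] = {
    "health_spend_pc": "positive",
    "beds_per_10k": "positive",
    "doctors_per_10k": "positive",
    "survival_rate": "positive",
    "infection_incidence": "negative",
}

REGIONS = ("east", "central", "west", "northeast")
#: Approximate shares of provinces per macro region.
_REGION_SHARES = (0.36, 0.27, 0.23, 0.14)

_POLICY_DUMMY_COLS = ("policy_broadband", "policy_bigdata", "policy_innovation")


@dataclass(frozen=True)
class DGPConfig:
    """Ground-truth parameters of the synthetic panel.

    Defaults describe the reference study scenario: 270 cities x 14 years
    starting 2007, three adoption waves of 10% of cities each in 2012-2014
    (treated city-year share 0.171), a direct policy effect of 0.12 on the
    index scale and three mediators whose (a, b) paths contribute a further
    0.023, for a total effect of 0.143.
    """

    n_cities: int = 270
    n_years: int = 14
    start_year: int = 2007
    theta_true: float = 0.12
    adoption_waves: tuple[tuple[int, float], ...] = ((2012, 0.10), (2013, 0.10), (2014, 0.10))
    confounder_dim: int = 10
    confounding_strength: float = 1.0
    nonlinear_nuisance: bool = True
    mediator_paths: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"EEQ": (0.028, 0.143), "ISL": (0.205, 0.054), "HWS": (0.773, 0.010)}
    )
    mediator_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"EEQ": 0.10, "ISL": 1.0, "HWS": 3.0}
    )
    endogeneity_rho: float = 0.0
    instrument_strength: float = 1.0
    fe_sd_city: float = 0.04
    fe_sd_year: float = 0.02
    noise_sd: float = 0.08
    outcome_mean: float = 0.164
    index_scale: bool = False
    theta_by_region: Mapping[str, float] | None = None
    indicator_noise_sd: float = 1.0
    seed: int = 20070

    def validate(self) -> None:
        if self.n_cities < 1 or self.n_years < 1:
            raise ValueError("n_cities and n_years must be positive")
        if self.confounder_dim < 1:
            raise ValueError("confounder_dim must be positive")
        if self.n_cities * self.n_years < 2 * self.confounder_dim:
            raise ValueError(
                f"degenerate design: {self.n_cities * self.n_years} records for "
                f"{self.confounder_dim} confounders (need >= 2x)"
            )
        frac = sum(f for _, f in self.adoption_waves)
        if frac > 1.0 + 1e-12:
            raise ValueError(f"adoption fractions sum to {frac:.3f} > 1")
        for year, f in self.adoption_waves:
            if not (self.start_year <= year < self.start_year + self.n_years):
                raise ValueError(f"wave year {year} outside panel range")
            if f < 0:
                raise ValueError("adoption fractions must be >= 0")
        if not (-1.0 <= self.endogeneity_rho <= 1.0):
            raise ValueError("endogeneity_rho must lie in [-1, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for v in (self.theta_true, self.endogeneity_rho, self.confounding_strength, self.instrument_strength):
            if not math.isfinite(v):
                raise ValueError("config parameters must be finite")
        for a, b in self.mediator_paths.values():
            if not (math.isfinite(a) and math.isfinite(b)):
                raise ValueError("mediator paths must be finite")

    def with_(self, **kwargs) -> "DGPConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class PanelDataset:
    """A balanced long-format city-year panel.

    ``df`` carries one row per (city_id, year) with the outcome ``PHL``,
    absorbing treatment ``SCC``, named controls, mediators, subgroup labels
    (region / size / regulation / batch), ``province_id`` and the city-level
    ``instrument_base``.
    """

    df: pd.DataFrame
    control_cols: list[str]
    mediator_cols: list[str]
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        df = self.df
        dup = df.duplicated(subset=["city_id", "year"])
        if dup.any():
            raise ValueError("panel is not balanced: duplicate (city, year) rows")
        counts = df.groupby("city_id")["year"].nunique()
        if counts.nunique() != 1:
            raise ValueError("panel is not balanced: unequal year counts per city")
        scc = df.sort_values(["city_id", "year"]).groupby("city_id")["SCC"]
        if (scc.diff().dropna() < 0).any():
            raise ValueError("treatment is not an absorbing state")
        if not np.isfinite(df["PHL"].to_numpy()).all():
            raise ValueError("outcome contains non-finite values")

    @property
    def n_cities(self) -> int:
        return self.df["city_id"].nunique()

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.df["year"].unique())

    def copy(self) -> "PanelDataset":
        return PanelDataset(self.df.copy(), list(self.control_cols), list(self.mediator_cols), dict(self.meta))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PanelDataset":
        df = pd.read_csv(path)
        controls = [c for c in df.columns if c.startswith("X")]
        mediators = [c for c in ("EEQ", "ISL", "HWS") if c in df.columns]
        return cls(df, controls, mediators)


def _assign_labels(rng: np.random.Generator, n_cities: int) -> tuple[np.ndarray, np.ndarray]:
    """Assign province ids (contiguous blocks) and region labels by province."""
    n_prov = max(4, int(round(n_cities / 9)))
    block = int(np.ceil(n_cities / n_prov))
    province = np.arange(n_cities) // block
    n_prov = int(province.max()) + 1
    # split provinces into four macro regions with roughly the stated shares
    cuts = np.cumsum(np.array(_REGION_SHARES) * n_prov).round().astype(int)
    cuts[-1] = n_prov
    prov_region = np.empty(n_prov, dtype=object)
    lo = 0
    for region, hi in zip(REGIONS, cuts):
        prov_region[lo:hi] = region
        lo = max(lo, hi)
    prov_region[prov_region == None] = REGIONS[0]  # noqa: E711 - degenerate tiny panels
    return province, prov_region[province]


def _nuisance_g(X: np.ndarray, nonlinear: bool) -> np.ndarray:
    """Raw (unscaled) outcome nuisance: linear base plus a fixed nonlinear menu

    of squares, pairwise products of the first three confounders, and one
    threshold term. The caller rescales to the target variance.
    """
    k = X.shape[1]
    beta = 1.0 / np.sqrt(np.arange(1, k + 1))
    g = X @ (beta / np.linalg.norm(beta))
    if nonlinear:
        sq = ((X**2 - 1.0) @ (beta / np.linalg.norm(beta))) / np.sqrt(2.0)
        m = min(3, k)
        prod = np.zeros(len(X))
        npair = 0
        for i in range(m):
            for j in range(i + 1, m):
                prod += X[:, i] * X[:, j]
                npair += 1
        if npair:
            prod /= np.sqrt(npair)
        thresh = (X[:, 0] > 0.5).astype(float) - 0.3085  # centered indicator
        g = 0.7 * g + 1.4 * sq + 1.0 * prod + 1.0 * thresh
    return g


def generate_panel(cfg: DGPConfig) -> PanelDataset:
    """Generate a balanced staggered-adoption panel from ``cfg``.

    Deterministic in ``cfg.seed``.  Adoption: each city gets a latent score
    ``confounding_strength * s(mu_i) + instrument_strength * z_i + q_i`` with
    ``q_i ~ N(0,1)``; cities are ranked by score and the top
    ``floor(fraction * n_cities)`` of each wave adopt at that wave's year
    (earliest wave first), the remainder never adopt.  Outcome:
    ``theta * SCC + g(X) + sum_m b_m M_m + alpha_i + gamma_t + e_it`` with
    ``e`` correlated with the adoption shock ``q_i`` when
    ``endogeneity_rho != 0``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, T, k = cfg.n_cities, cfg.n_years, cfg.confounder_dim
    years = np.arange(cfg.start_year, cfg.start_year + T)

    province, region = _assign_labels(rng, n)
    size = np.where(rng.random(n) < 0.35, "large", "medium_small")
    regulation = np.where(rng.random(n) < 0.45, "high", "low")

    # confounders: persistent city component + transitory component
    mu = rng.normal(size=(n, k))
    X = mu[:, None, :] + 0.6 * rng.normal(size=(n, T, k))

    # instrument base: positive, right-skewed historical endowment
    z_raw = rng.gamma(shape=2.0, scale=1.0, size=n)
    z_std = (z_raw - z_raw.mean()) / (z_raw.std() + 1e-12)

    # adoption propensity loads on the same leading confounders the nonlinear
    # nuisance menu is built from, so omitting the nonlinear terms biases a
    # naive linear regression
    w = np.zeros(k)
    w[: min(3, k)] = 1.0
    w /= np.linalg.norm(w)
    q = rng.normal(size=n)  # adoption shock, reused in the outcome error under rho != 0
    score = cfg.confounding_strength * (mu @ w) + cfg.instrument_strength * z_std + q

    # wave assignment: rank cities by score, earliest wave takes the top block
    order = np.argsort(-score, kind="stable")
    adopt_year = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    batch = np.full(n, "none", dtype=object)
    waves = sorted(cfg.adoption_waves, key=lambda wf: wf[0])
    pos = 0
    for b, (year, fracn) in enumerate(waves, start=1):
        m = int(np.floor(fracn * n))
        sel = order[pos:pos + m]
        adopt_year[sel] = year
        batch[sel] = str(b)
        pos += m
    D = (years[None, :] >= adopt_year[:, None]).astype(float)  # absorbing by construction

    # nuisance, scaled so Var(g) matches Var(noise)
    Xf = X.reshape(n * T, k)
    g = _nuisance_g(Xf, cfg.nonlinear_nuisance)
    g = g * (cfg.noise_sd / (g.std() + 1e-12))

    alpha = rng.normal(scale=cfg.fe_sd_city, size=n) if cfg.fe_sd_city > 0 else np.zeros(n)
    trend = np.linspace(-1.0, 1.0, T)
    gamma = cfg.fe_sd_year * (0.8 * rng.normal(size=T) + 0.6 * trend) if cfg.fe_sd_year > 0 else np.zeros(T)

    rho = cfg.endogeneity_rho
    eps = rng.normal(size=(n, T))
    e = cfg.noise_sd * (rho * q[:, None] + np.sqrt(max(0.0, 1.0 - rho**2)) * eps)

    mediators: dict[str, np.ndarray] = {}
    med_noise = dict(cfg.mediator_noise_sd)
    med_contrib = np.zeros(n * T)
    for idx, (name, (a, b)) in enumerate(cfg.mediator_paths.items()):
        u = np.roll(w, idx + 1)
        h = 0.3 * (Xf @ u)
        sd_m = float(med_noise.get(name, 1.0))
        M = a * D.reshape(-1) + h + sd_m * rng.normal(size=n * T)
        mediators[name] = M
        med_contrib = med_contrib + b * M

    if cfg.theta_by_region is not None:
        theta_vec = np.array([cfg.theta_by_region.get(r, cfg.theta_true) for r in region])
    else:
        theta_vec = np.full(n, cfg.theta_true)

    y = (
        cfg.outcome_mean
        + theta_vec[:, None] * D
        + g.reshape(n, T)
        + med_contrib.reshape(n, T)
        + alpha[:, None]
        + gamma[None, :]
        + e
    )

    meta: dict = {"adopt_year": adopt_year.copy(), "clip_fraction": 0.0}
    if cfg.index_scale:
        base = rng.gamma(shape=2.0, scale=0.03, size=n) - 0.06  # skewed, mean-zero city quality
        y = y + base[:, None]
        clipped = (y < 0) | (y > 1)
        meta["clip_fraction"] = float(clipped.mean())
        y = np.clip(y, 0.0, 1.0)

    # irrelevant contemporaneous policies: staggered absorbing dummies that never
    # enter the outcome equation (robustness fodder)
    policy = {}
    for j, col in enumerate(_POLICY_DUMMY_COLS):
        py = cfg.start_year + 3 + 2 * j
        adopters = rng.random(n) < 0.25
        p_adopt = np.where(adopters, py, np.iinfo(np.int64).max)
        policy[col] = (years[None, :] >= p_adopt[:, None]).astype(float).reshape(-1)

    control_cols = [f"X{j + 1}" for j in range(k)]
    df = pd.DataFrame({
        "city_id": np.repeat(np.arange(n), T),
        "province_id": np.repeat(province, T),
        "year": np.tile(years, n),
        "PHL": y.reshape(-1),
        "SCC": D.reshape(-1),
    })
    for j, c in enumerate(control_cols):
        df[c] = Xf[:, j]
    for name, M in mediators.items():
        df[name] = M
    for col, v in policy.items():
        df[col] = v
    df["region"] = np.repeat(region, T)
    df["size"] = np.repeat(size, T)
    df["regulation"] = np.repeat(regulation, T)
    df["batch"] = np.repeat(batch, T)
    df["instrument_base"] = np.repeat(z_raw, T)

    panel = PanelDataset(df, control_cols, list(cfg.mediator_paths.keys()), meta)
    panel.validate()
    return panel


def true_effects(cfg: DGPConfig) -> dict:
    """Ground-truth effect summary implied by ``cfg``: the direct effect,

    each mediator's indirect effect ``a*b``, and the total effect.
    """
    cfg.validate()
    indirect = {name: a * b for name, (a, b) in cfg.mediator_paths.items()}
    return {
        "theta": cfg.theta_true,
        "indirect": indirect,
        "total": cfg.theta_true + sum(indirect.values()),
    }


def generate_indicator_table(cfg: DGPConfig) -> pd.DataFrame:
    """Raw five-indicator table per city-year for entropy-index construction.

    All five indicators are affine in a shared latent health factor (the
    panel outcome rescaled to [0, 1]) plus indicator noise scaled by
    ``cfg.indicator_noise_sd``; infectious-disease incidence is the single
    negative-direction (loss) indicator.  At zero indicator noise the
    entropy-weight index is an exactly monotone transform of the latent
    factor.
    """
    panel = generate_panel(cfg)
    y = panel.df["PHL"].to_numpy()
    lat = (y - y.min()) / (y.max() - y.min() + 1e-300)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 91]))
    s = cfg.indicator_noise_sd
    nrow = len(lat)

    def noise(scale):
        return s * scale * rng.normal(size=nrow)

    table = pd.DataFrame({
        "city_id": panel.df["city_id"],
        "year": panel.df["year"],
        "health_spend_pc": np.maximum(1.0, 100.0 + 800.0 * lat + noise(40.0)),
        "beds_per_10k": np.maximum(0.5, 20.0 + 50.0 * lat + noise(4.0)),
        "doctors_per_10k": np.maximum(0.5, 15.0 + 35.0 * lat + noise(3.0)),
        "survival_rate": np.clip(0.985 + 0.012 * lat + noise(0.001), 0.0, 1.0),
        "infection_incidence": np.maximum(0.1, 60.0 - 45.0 * lat + noise(5.0)),
    })
    return table
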