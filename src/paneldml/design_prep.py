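"""Panel preparation: interpolation, winsorization, and the high-dimensional

design matrix (control levels and squares, year/city dummy blocks, policy
dummies, province-specific linear trends).  Fixed effects are passed to the
nuisance learners as one-hot features inside X rather than demeaned away, so
tree learners see the raw treatment column.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from paneldml.synthetic_panel import PanelDataset

__all__ = ["PrepConfig", "DesignMatrix", "interpolate_missing", "winsorize", "build_design"]


@dataclass(frozen=True)
class PrepConfig:
    winsor_bounds: tuple[float, float] | None = None
    interpolate_missing: bool = False
    add_squares: bool = True
    fe_year: bool = True
    fe_city: bool = True
    province_trend: bool = False
    policy_dummies: tuple[str, ...] = ()
    exclude_from_winsor: tuple[str, ...] = ("SCC",)

    def __post_init__(self):
        if self.winsor_bounds is not None:
            lo, hi = self.winsor_bounds
            if not (0.0 < lo < hi < 1.0):
                raise ValueError(f"winsor bounds must satisfy 0 < lo < hi < 1, got {self.winsor_bounds}")

    def with_(self, **kwargs) -> "PrepConfig":
        return replace(self, **kwargs)


@dataclass
class DesignMatrix:
    """Nuisance-learner feature matrix aligned to the panel rows.

    ``roles`` maps each column name to one of: control, square, year_fe,
    city_fe, province_trend, policy.
    """

    X: pd.DataFrame
    roles: dict[str, str]

    @property
    def values(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)

    def columns_with_role(self, role: str) -> list[str]:
        return [c for c, r in self.roles.items() if r == role]


def interpolate_missing(panel: PanelDataset) -> PanelDataset:
    """Fill gaps in continuous columns by within-city linear interpolation

    over years; leading/trailing gaps take the nearest observed value.  A
    city with a column entirely missing cannot be filled and is refused.
    """
    df = panel.df
    num_cols = [c for c in panel.control_cols + panel.mediator_cols + ["PHL"] if c in df.columns]
    if not df[num_cols].isna().any().any():
        return panel  # complete panel: returned unchanged
    out = df.sort_values(["city_id", "year"]).copy()
    for col in num_cols:
        if not out[col].isna().any():
            continue
        all_missing = out.groupby("city_id")[col].transform(lambda s: s.isna().all())
        if all_missing.any():
            city = out.loc[all_missing, "city_id"].iloc[0]
            raise ValueError(f"column {col!r} entirely missing for city {city}: cannot interpolate")
        filled = out.groupby("city_id", group_keys=False)[col].apply(
            lambda s: s.interpolate(method="linear", limit_direction="both")
        )
        out[col] = filled
    out = out.loc[df.index]  # restore original row order
    return PanelDataset(out, list(panel.control_cols), list(panel.mediator_cols), dict(panel.meta))


def winsorize(
    panel: PanelDataset,
    bounds: tuple[float, float],
    exclude: Sequence[str] = ("SCC",),
) -> PanelDataset:
    """Clip each continuous column at its pooled empirical quantiles.

    The treatment column and any listed exclusions are never touched, and
    binary columns are left as-is.
    """
    lo, hi = bounds
    if not (0.0 < lo < hi < 1.0):
        raise ValueError(f"invalid winsor bounds {bounds}")
    df = panel.df.copy()
    candidates = [c for c in panel.control_cols + panel.mediator_cols + ["PHL"] if c in df.columns]
    exclude = set(exclude) | {"SCC"}
    for col in candidates:
        if col in exclude:
            continue
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"cannot winsorize non-numeric column {col!r}")
        x = df[col].to_numpy(dtype=float)
        if set(np.unique(x)) <= {0.0, 1.0}:
            continue  # binary indicator
        # nearest-order-statistic quantiles: bounds are observed values, so
        # clipping is idempotent and never leaves the observed range
        qlo = np.quantile(x, lo, method="nearest")
        qhi = np.quantile(x, hi, method="nearest")
        df[col] = np.clip(x, qlo, qhi)
    return PanelDataset(df, list(panel.control_cols), list(panel.mediator_cols), dict(panel.meta))


def build_design(panel: PanelDataset, cfg: PrepConfig) -> DesignMatrix:
    """Assemble the nuisance design: control levels (+ squares), one-hot year

    and city dummies (reference level dropped), per-province linear trends,
    and verbatim policy dummies.
    """
    df = panel.df
    cols: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}

    for c in panel.control_cols:
        cols[c] = df[c].to_numpy(dtype=float)
        roles[c] = "control"
    if cfg.add_squares:
        for c in panel.control_cols:
            name = f"{c}_sq"
            cols[name] = df[c].to_numpy(dtype=float) ** 2
            roles[name] = "square"

    if cfg.fe_year:
        years = np.sort(df["year"].unique())
        for y in years[1:]:  # drop reference level
            name = f"year_{y}"
            cols[name] = (df["year"].to_numpy() == y).astype(float)
            roles[name] = "year_fe"
    if cfg.fe_city:
        cities = np.sort(df["city_id"].unique())
        if len(cities) < 2:
            raise ValueError("city fixed effects require at least 2 cities")
        for cty in cities[1:]:
            name = f"city_{cty}"
            cols[name] = (df["city_id"].to_numpy() == cty).astype(float)
            roles[name] = "city_fe"
    if cfg.province_trend:
        start = int(df["year"].min())
        t = (df["year"].to_numpy() - start).astype(float)
        for p in np.sort(df["province_id"].unique()):
            name = f"provtrend_{p}"
            cols[name] = t * (df["province_id"].to_numpy() == p)
            roles[name] = "province_trend"
    for c in cfg.policy_dummies:
        if c not in df.columns:
            raise ValueError(f"policy dummy column {c!r} not in panel")
        cols[c] = df[c].to_numpy(dtype=float)
        roles[c] = "policy"

    X = pd.DataFrame(cols, index=df.index)
    if X.isna().any().any():
        raise ValueError("design matrix contains missing values; run interpolation first")
    return DesignMatrix(X, roles)
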