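"""Entropy-weight composite index for direction-tagged indicators.

Weights are objective: each indicator's weight is proportional to its
information divergence 1 - e_j, where e_j is the Shannon entropy of the
indicator's normalized share distribution across observations.  Indicators
that barely discriminate between observations (entropy near 1) get little
weight; a constant column gets weight exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["IndicatorSpec", "CompositeIndexResult", "normalize_indicators", "entropy_weights", "composite_index"]

#: continuity fix inside the share distribution, avoids ln 0
EPS = 1e-12


@dataclass(frozen=True)
class IndicatorSpec:
    name: str
    direction: str  # "positive" (benefit) or "negative" (loss)

    def __post_init__(self):
        if self.direction not in ("positive", "negative"):
            raise ValueError(f"direction must be 'positive' or 'negative', got {self.direction!r}")


@dataclass
class CompositeIndexResult:
    weights: np.ndarray          # per indicator, >= 0, sums to 1
    normalized: np.ndarray       # rows x indicators, in [0, 1]
    index: np.ndarray            # per row, in [0, 1]
    entropies: np.ndarray        # per indicator, in [0, 1]
    names: list[str]

    def weight_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.names, name="weight")


def _check_specs(table: pd.DataFrame, specs: Sequence[IndicatorSpec]) -> list[IndicatorSpec]:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("indicator names must be unique")
    missing = [n for n in names if n not in table.columns]
    if missing:
        raise ValueError(f"indicator columns missing from table: {missing}")
    return list(specs)


def normalize_indicators(table: pd.DataFrame, specs: Sequence[IndicatorSpec]) -> np.ndarray:
    """Min-max normalize each indicator column to [0, 1], reversing negative-

    direction (loss) indicators so that larger is always better.  A constant
    column is mapped to all zeros and flagged downstream via zero entropy
    weight rather than raising.
    """
    specs = _check_specs(table, specs)
    if len(table) < 2:
        raise ValueError("need at least 2 rows to normalize")
    out = np.empty((len(table), len(specs)))
    for j, s in enumerate(specs):
        x = table[s.name].to_numpy(dtype=float)
        if not np.isfinite(x).all():
            raise ValueError(f"non-finite values in indicator {s.name!r}")
        lo, hi = x.min(), x.max()
        if hi - lo <= 0:
            out[:, j] = 0.0  # constant column: no discriminating information
            continue
        z = (x - lo) / (hi - lo)
        out[:, j] = z if s.direction == "positive" else 1.0 - z
    return out


def entropy_weights(normalized: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Entropy weights from a normalized matrix.

    p_ij = (z_ij + eps) / sum_i (z_ij + eps);  e_j = -(1/ln n) sum_i p_ij ln p_ij;
    w_j = (1 - e_j) / sum_j (1 - e_j).  Constant (all-equal) columns receive
    weight 0; if every column is constant there is nothing to weight.
    """
    z = np.asarray(normalized, dtype=float)
    if z.ndim != 2 or z.shape[0] < 2:
        raise ValueError("normalized must be a matrix with >= 2 rows")
    if z.min() < -1e-9 or z.max() > 1 + 1e-9:
        raise ValueError("normalized entries must lie in [0, 1]")
    n, m = z.shape
    const = (z.max(axis=0) - z.min(axis=0)) <= 0
    p = (z + EPS) / (z + EPS).sum(axis=0, keepdims=True)
    e = -(p * np.log(p)).sum(axis=0) / np.log(n)
    e = np.clip(e, 0.0, 1.0)
    d = 1.0 - e
    d[const] = 0.0
    total = d.sum()
    if total <= 0:
        raise ValueError("all indicator columns are constant: no information to weight")
    return d / total, e


def composite_index(table: pd.DataFrame, specs: Sequence[IndicatorSpec]) -> CompositeIndexResult:
    """Chain normalization -> entropy weights -> weighted sum; keeps every

    intermediate for audit.  The index is the weight-convex combination of
    normalized indicator values, hence lies in [0, 1].
    """
    z = normalize_indicators(table, specs)
    w, e = entropy_weights(z)
    idx = z @ w
    return CompositeIndexResult(weights=w, normalized=z, index=idx, entropies=e, names=[s.name for s in specs])


def equal_weight_index(table: pd.DataFrame, specs: Sequence[IndicatorSpec]) -> np.ndarray:
    """Debug mode: equal-weight average of the normalized indicators."""
    z = normalize_indicators(table, specs)
    return z.mean(axis=1)
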