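"""Indicator normalization ahead of network modelling.

The subjective indicators are right-skewed; a square-root transform is
applied to the peak indicator (mSA) and a cube-root transform to the area
indicator (iSA), after which each participant's values are centred and
scaled to unit unbiased standard deviation so that a single Gaussian node can
describe the pooled sample.  The SCR indicators are scaled per participant
but *not* centred: the compound-Poisson model requires the exact zeros
(manoeuvres without any response) to stay at zero.

A useful analytic consequence of per-participant z-scoring: with P
participants of n values each, the pooled unbiased SD is exactly
sqrt(P*(n-1)/(P*n-1)) regardless of the data — 0.98506 for 20 x 32.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TransformParams",
    "power_transform",
    "standardize_by_participant",
    "skewness",
    "normality_check",
    "apply_transforms",
]


@dataclass(frozen=True)
class TransformParams:
    """Exponents and scaling flags of the normalization pipeline."""

    sa_exponents: dict = field(default_factory=lambda: {"msa": 0.5, "isa": 1.0 / 3.0})
    center_sa: bool = True
    center_scr: bool = False

    def __post_init__(self) -> None:
        for name, e in self.sa_exponents.items():
            if not (0 < e <= 1):
                raise ValueError(f"exponent for {name} must be in (0, 1], got {e}")
        if self.center_scr:
            raise ValueError("centering SCR indicators would destroy the zero mass")


def power_transform(values, exponent: float):
    """Elementwise x**exponent for nonnegative x; fixes 0 and 1."""
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("power transform requires nonnegative values")
    return values ** exponent


def standardize_by_participant(values, participant_ids, center: bool = True):
    """Per-participant z-scoring (center=True) or pure scaling (center=False).

    Scaling always uses the unbiased (n-1) standard deviation.  With
    ``center=False`` exact zeros are preserved exactly (multiplicative map).
    """
    values = np.asarray(values, dtype=float)
    ids = np.asarray(participant_ids)
    out = np.empty_like(values)
    for pid in np.unique(ids):
        sel = ids == pid
        v = values[sel]
        if len(v) < 2:
            raise ValueError(f"participant {pid!r} has fewer than 2 values")
        sd = float(np.std(v, ddof=1))
        if sd == 0.0:
            raise ValueError(f"participant {pid!r} has zero within-participant variance")
        out[sel] = (v - v.mean()) / sd if center else v / sd
    return out


def skewness(values) -> float:
    """Adjusted Fisher-Pearson sample skewness (the bias-corrected g1)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("skewness requires at least 3 values")
    return float(stats.skew(values, bias=False))


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value (3 <= n <= 5000)."""
    values = np.asarray(values, dtype=float)
    if not (3 <= len(values) <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def apply_transforms(
    indicators: pd.DataFrame,
    params: TransformParams | None = None,
) -> pd.DataFrame:
    """Add transformed columns ``*_t`` to an indicator table.

    Subjective indicators: power transform, then per-participant centring and
    scaling.  SCR indicators: per-participant scaling only.
    """
    params = params or TransformParams()
    df = indicators.copy()
    ids = df["participant_id"].to_numpy()
    for col, exponent in params.sa_exponents.items():
        df[f"{col}_t"] = standardize_by_participant(
            power_transform(df[col].to_numpy(), exponent), ids, center=params.center_sa
        )
    for col in ("nscr", "mscr"):
        df[f"{col}_t"] = standardize_by_participant(
            df[col].to_numpy(), ids, center=params.center_scr
        )
    return df
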