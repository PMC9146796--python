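"""Growth-inhibition and supporting statistics for spheroid volume records.

Records live in a tidy DataFrame with columns ``spheroid_id``, ``condition``,
``day`` and ``volume_mm3`` — one row per spheroid per imaging timepoint.

Growth inhibition follows the xenograft-literature definition

    GI = 1 − mean(ΔV_treated) / mean(ΔV_control)

with per-spheroid volume deltas over a fixed interval, averaged
arithmetically within each arm.  GI = 1 means treated spheroids did not grow
at all; GI = 0 means treatment had no effect; GI > 1 (treated shrinkage) is
reported as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthInhibitionResult",
    "FoldChangeResult",
    "growth_inhibition",
    "fold_change",
    "welch_t_test",
    "count_volume_regression",
    "records_from_csv",
]

RECORD_COLUMNS = ("spheroid_id", "condition", "day", "volume_mm3")


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"growth records missing columns: {sorted(missing)}")
    if (records["volume_mm3"] <= 0).any():
        raise ValueError("volumes must be positive")
    if records.duplicated(subset=["spheroid_id", "day"]).any():
        raise ValueError("duplicate (spheroid_id, day) rows")
    return records


def _deltas(records: pd.DataFrame, t_start: float, t_end: float) -> pd.Series:
    """Per-spheroid V(t_end) − V(t_start); spheroids missing either timepoint dropped."""
    wide = records.pivot(index="spheroid_id", columns="day", values="volume_mm3")
    for t in (t_start, t_end):
        if t not in wide.columns:
            raise ValueError(f"no records at day {t}")
    complete = wide[[t_start, t_end]].dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} spheroid(s) missing day {t_start} or {t_end}; excluded"
        )
    return complete[t_end] - complete[t_start]


@dataclass(frozen=True)
class GrowthInhibitionResult:
    gi: float
    n_treated: int
    n_control: int
    mean_delta_treated: float   # mm³
    mean_delta_control: float   # mm³


def growth_inhibition(treated: pd.DataFrame, control: pd.DataFrame,
                      t_start: float, t_end: float) -> GrowthInhibitionResult:
    """Growth inhibition of the treated arm relative to control over [t_start, t_end]."""
    d_t = _deltas(_validate_records(treated), t_start, t_end)
    d_c = _deltas(_validate_records(control), t_start, t_end)
    if d_t.empty or d_c.empty:
        raise ValueError("need at least one complete spheroid per arm")
    mean_t, mean_c = float(d_t.mean()), float(d_c.mean())
    if mean_c == 0.0:
        raise ValueError("mean control volume change is zero; GI undefined")
    if mean_c < 0.0:
        warnings.warn("control arm shrank on average; GI sign is unconventional")
    return GrowthInhibitionResult(
        gi=1.0 - mean_t / mean_c,
        n_treated=len(d_t),
        n_control=len(d_c),
        mean_delta_treated=mean_t,
        mean_delta_control=mean_c,
    )


@dataclass(frozen=True)
class FoldChangeResult:
    per_spheroid: pd.Series  # fold V(t_end)/V(t_start), indexed by spheroid_id
    mean: float
    sd: float  # sample SD (ddof=1); NaN for a single spheroid


def fold_change(records: pd.DataFrame, t_start: float, t_end: float) -> FoldChangeResult:
    """Per-spheroid and mean volume fold change V(t_end)/V(t_start)."""
    records = _validate_records(records)
    wide = records.pivot(index="spheroid_id", columns="day", values="volume_mm3")
    for t in (t_start, t_end):
        if t not in wide.columns:
            raise ValueError(f"no records at day {t}")
    complete = wide[[t_start, t_end]].dropna()
    if complete.empty:
        raise ValueError("no spheroid has both timepoints")
    folds = complete[t_end] / complete[t_start]
    sd = float(folds.std(ddof=1)) if len(folds) > 1 else float("nan")
    return FoldChangeResult(per_spheroid=folds, mean=float(folds.mean()), sd=sd)


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Two-sided unequal-variance (Welch) t-test.

    Returns ``(t, df, p)`` with the Welch–Satterthwaite degrees of freedom.
    Implemented at the formula level; the classic frequentist comparison used
    for the headline treated-vs-control contrasts.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValueError("zero variance in both groups")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def count_volume_regression(counts, volumes) -> tuple[float, float, float]:
    """OLS of cell count on spheroid volume; returns (slope, intercept, r).

    Used to confirm that outer-diameter-derived volume tracks cell number.
    Constant counts give slope 0 and r = 0 by convention.
    """
    y = np.asarray(counts, dtype=float)
    x = np.asarray(volumes, dtype=float)
    if x.size != y.size:
        raise ValueError("counts and volumes must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0.0:
        raise ValueError("volumes have zero variance")
    if np.var(y) == 0.0:
        return 0.0, float(y.mean()), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def records_from_csv(path) -> pd.DataFrame:
    """Load and validate a growth-record CSV (spheroid_id, condition, day, volume_mm3)."""
    return _validate_records(pd.read_csv(path))
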