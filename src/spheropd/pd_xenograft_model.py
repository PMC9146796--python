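"""Two-population constant-radius-growth xenograft model.

Subcutaneous colorectal xenografts grow with a proliferating peripheral
shell and an inert (quiescent/necrotic) core, which makes the tumour radius
grow linearly in time:

    V(t) = (4/3) π (α t + β)³

with α the radius growth speed (mm/day) and β the starting radius (mm).
The link to on-chip spheroid data is the thin-shell closure

    α = k · s

where k is the specific growth rate of fully proliferating tissue (per day,
measured from on-chip spheroid fold change) and s is the proliferating-shell
thickness (mm, measured from xenograft histology): new volume per day is
k × shell volume ≈ k · 4πR²s, and dividing by the surface area 4πR² gives
the radius speed k·s.  The closure is exact in the limit s ≪ R.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .growth_analysis import fold_change

__all__ = [
    "XenograftModel",
    "ShellKinetics",
    "volume_at",
    "radius_from_volume",
    "derive_alpha",
    "specific_growth_rate_from_spheroids",
    "modeled_growth_inhibition",
    "fold_change_at",
    "trajectory",
]

#: nominal starting tumour volume used in xenograft studies, mm³
NOMINAL_STARTING_VOLUME = 100.0
#: comparison horizon for xenograft growth, days
DEFAULT_HORIZON = 14.0


@dataclass(frozen=True)
class XenograftModel:
    """Constant-radius-growth tumour: radius α·t + β."""

    alpha: float  # mm/day
    beta: float   # mm

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("starting radius beta must be positive")
        if self.alpha < 0:
            warnings.warn("negative radius growth rate: shrinking tumour")


@dataclass(frozen=True)
class ShellKinetics:
    """Ingredients of the α = k·s closure."""

    specific_growth_rate: float  # k, per day, of fully proliferating tissue
    shell_thickness: float       # s, mm, from xenograft histology

    def __post_init__(self) -> None:
        if self.specific_growth_rate < 0:
            raise ValueError("specific growth rate must be >= 0")
        if self.shell_thickness <= 0:
            raise ValueError("shell thickness must be positive")


def volume_at(model: XenograftModel, t) -> float | np.ndarray:
    """Tumour volume (mm³) at day(s) ``t``: (4/3)π(αt+β)³."""
    r = model.alpha * np.asarray(t, dtype=float) + model.beta
    if np.any(r <= 0):
        raise ValueError("radius driven non-positive at requested time")
    v = (4.0 / 3.0) * np.pi * r**3
    return float(v) if v.ndim == 0 else v


def radius_from_volume(volume: float) -> float:
    """Radius (mm) of the sphere with the given volume (mm³)."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return float((3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0))


def derive_alpha(kinetics: ShellKinetics) -> float:
    """Radius growth speed from the thin-shell closure α = k·s (mm/day)."""
    return kinetics.specific_growth_rate * kinetics.shell_thickness


def specific_growth_rate_from_spheroids(records: pd.DataFrame,
                                        window: tuple[float, float]) -> float:
    """Specific growth rate k (per day) from spheroid volumes over a window.

    k = ln(mean fold change)/Δt, so fully proliferating tissue multiplies
    its volume by the observed mean fold over the window.  For untreated
    spheroids the first 2 days (before size-related slowdown) are the
    appropriate window; for treated spheroids the full treatment course
    captures pause plus recovery.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window end must exceed start")
    fold = fold_change(records, t0, t1).mean
    if fold <= 0:
        raise ValueError("non-positive mean fold change")
    return float(np.log(fold) / (t1 - t0))


def modeled_growth_inhibition(treated: XenograftModel, control: XenograftModel,
                              horizon: float = DEFAULT_HORIZON) -> float:
    """Growth inhibition of modeled trajectories: 1 − ΔV_treated/ΔV_control."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if treated.beta != control.beta:
        raise ValueError("arms must share the starting radius beta")
    v0 = volume_at(control, 0.0)
    dv_c = volume_at(control, horizon) - v0
    dv_t = volume_at(treated, horizon) - v0
    if dv_c == 0.0:
        raise ValueError("control net growth is zero; GI undefined")
    return 1.0 - dv_t / dv_c


def fold_change_at(model: XenograftModel, horizon: float,
                   v0: float | None = None) -> float:
    """Volume fold change V(horizon)/V(0).

    ``v0`` defaults to the model's own starting volume (4/3)πβ³; pass the
    nominal 100 mm³ to use the rounded convention instead.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if v0 is None:
        v0 = volume_at(model, 0.0)
    return volume_at(model, horizon) / v0


def trajectory(model: XenograftModel, days) -> pd.DataFrame:
    """Volume trajectory as a DataFrame (day, volume_mm3)."""
    days = np.asarray(days, dtype=float)
    return pd.DataFrame({"day": days, "volume_mm3": volume_at(model, days)})
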