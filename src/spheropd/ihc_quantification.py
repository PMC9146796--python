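"""Immunohistochemistry positivity statistics and shell/core geometry.

Works from nucleus-detection tables (one row per nucleus: section
coordinates in µm and DAB optical density) or OD pixel maps, as produced by
standard digital-pathology tooling after colour deconvolution.  Positivity
is a simple threshold on OD: Ki67 (proliferation) >= 0.3 per nucleus, CC3
(apoptosis) >= 0.5 per pixel, with ties counted positive.

Xenograft sections show a proliferating peripheral shell and a quiescent or
necrotic core; :func:`radial_positive_profile` and
:func:`estimate_shell_geometry` quantify that partition from the radial
positivity profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ShellGeometry",
    "SectionQuantification",
    "KI67_CUTOFF",
    "CC3_CUTOFF",
    "ki67_positive_fraction",
    "cc3_positive_pixel_fraction",
    "radial_positive_profile",
    "estimate_shell_geometry",
    "overall_positive_fraction",
]

KI67_CUTOFF = 0.3
CC3_CUTOFF = 0.5

DETECTION_COLUMNS = ("x_um", "y_um", "dab_od")


@dataclass(frozen=True)
class SectionQuantification:
    """Whole-section positivity summary."""

    ki67_fraction: float
    cc3_pixel_fraction: float
    n_nuclei: int

    def __post_init__(self) -> None:
        for f in (self.ki67_fraction, self.cc3_pixel_fraction):
            if not (np.isnan(f) or 0.0 <= f <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class ShellGeometry:
    """Proliferating-shell partition of a roughly circular section.

    ``shell_thickness`` is measured inward from the section edge; the
    positivity fractions are detection-weighted means outside (shell) and
    inside (core) the boundary radius.
    """

    section_radius: float       # mm
    shell_thickness: float      # mm
    shell_positive_fraction: float
    core_positive_fraction: float  # NaN when the whole section is shell

    def __post_init__(self) -> None:
        if not 0.0 <= self.shell_thickness <= self.section_radius + 1e-12:
            raise ValueError("shell thickness must lie in [0, section_radius]")


def _check_detections(detections: pd.DataFrame) -> pd.DataFrame:
    missing = set(DETECTION_COLUMNS) - set(detections.columns)
    if missing:
        raise ValueError(f"detection table missing columns: {sorted(missing)}")
    if len(detections) == 0:
        raise ValueError("empty detection table")
    if (detections["dab_od"] < 0).any():
        raise ValueError("optical densities must be non-negative")
    return detections


def ki67_positive_fraction(detections: pd.DataFrame,
                           cutoff: float = KI67_CUTOFF) -> float:
    """Fraction of nuclei with DAB OD >= cutoff (ties positive)."""
    detections = _check_detections(detections)
    return float((detections["dab_od"] >= cutoff).mean())


def cc3_positive_pixel_fraction(od_image: np.ndarray, mask: np.ndarray,
                                cutoff: float = CC3_CUTOFF) -> float:
    """Fraction of in-mask pixels with OD >= cutoff (ties positive)."""
    od = np.asarray(od_image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if od.shape != mask.shape:
        raise ValueError("od_image and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    return float((od[mask] >= cutoff).mean())


def radial_positive_profile(detections: pd.DataFrame,
                            center: tuple[float, float] | None = None,
                            n_bins: int = 20,
                            cutoff: float = KI67_CUTOFF) -> pd.DataFrame:
    """Per-annulus Ki67-positive fraction, from the section centre outward.

    Annuli are equal-width from the centre (default: detection centroid) to
    the maximum detection radius.  Returns a DataFrame with columns
    ``r_inner_mm``, ``r_outer_mm``, ``n``, ``positive_fraction`` (NaN for
    empty annuli, which are also flagged with a warning).
    """
    detections = _check_detections(detections)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    x = detections["x_um"].to_numpy() / 1000.0
    y = detections["y_um"].to_numpy() / 1000.0
    if center is None:
        cx, cy = x.mean(), y.mean()
    else:
        cx, cy = center[0] / 1000.0, center[1] / 1000.0
    r = np.hypot(x - cx, y - cy)
    r_max = r.max()
    if r_max == 0.0:
        raise ValueError("all detections coincide with the centre; no radial span")
    edges = np.linspace(0.0, r_max, n_bins + 1)
    idx = np.clip(np.digitize(r, edges) - 1, 0, n_bins - 1)
    pos = detections["dab_od"].to_numpy() >= cutoff
    n = np.bincount(idx, minlength=n_bins)
    n_pos = np.bincount(idx, weights=pos.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        frac = np.where(n > 0, n_pos / np.maximum(n, 1), np.nan)
    if (n == 0).any():
        warnings.warn(f"{int((n == 0).sum())} empty radial bin(s)")
    return pd.DataFrame(
        {
            "r_inner_mm": edges[:-1],
            "r_outer_mm": edges[1:],
            "n": n,
            "positive_fraction": frac,
        }
    )


def estimate_shell_geometry(profile: pd.DataFrame,
                            threshold: float = 0.4) -> ShellGeometry:
    """Locate the proliferating shell from a radial positivity profile.

    Scanning outward from the centre, the shell starts at the inner edge of
    the first annulus whose positive fraction exceeds ``threshold``;
    ``shell_thickness`` is the distance from there to the section edge.  A
    profile entirely above threshold means the whole section proliferates
    (thickness = section radius, warning emitted); entirely below means no
    shell (thickness 0).
    """
    frac = profile["positive_fraction"].to_numpy()
    n = profile["n"].to_numpy()
    radius = float(profile["r_outer_mm"].iloc[-1])
    above = np.asarray((frac > threshold) & (n > 0))
    if not above.any():
        boundary = radius
    else:
        boundary = float(profile["r_inner_mm"].iloc[int(np.argmax(above))])
        if above[n > 0].all():
            warnings.warn("profile entirely above threshold: whole section proliferating")
    shell = (profile["r_inner_mm"] >= boundary) & (n > 0)
    core = (profile["r_inner_mm"] < boundary) & (n > 0)

    def weighted(sel) -> float:
        if not sel.any():
            return float("nan")
        w = n[sel]
        return float(np.sum(w * frac[sel]) / np.sum(w))

    return ShellGeometry(
        section_radius=radius,
        shell_thickness=radius - boundary,
        shell_positive_fraction=weighted(shell.to_numpy()),
        core_positive_fraction=weighted(core.to_numpy()),
    )


def overall_positive_fraction(profile: pd.DataFrame,
                              weighting: str = "count") -> float:
    """Whole-section positive fraction from a radial profile.

    ``weighting="count"`` weights annuli by detection count (equals the raw
    per-nucleus fraction); ``"area"`` weights by annulus area, which is the
    natural weighting when comparing with planimetric estimates of the
    proliferating fraction.
    """
    frac = profile["positive_fraction"].to_numpy()
    n = profile["n"].to_numpy()
    ok = n > 0
    if weighting == "count":
        w = n[ok].astype(float)
    elif weighting == "area":
        w = (profile["r_outer_mm"].to_numpy() ** 2
             - profile["r_inner_mm"].to_numpy() ** 2)[ok]
    else:
        raise ValueError("weighting must be 'count' or 'area'")
    return float(np.sum(w * frac[ok]) / np.sum(w))
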