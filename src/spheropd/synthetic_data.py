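"""Synthetic inputs with known ground truth for the whole pipeline.

Raw on-chip and histology data for this kind of experiment are rarely
published numerically, so every analysis step here is exercised against
generated data whose true parameters are known:

* spheroid growth time series — exponential control growth (defaults
  calibrated to 2.3-fold per 48 h) and a treated arm with a 2-day growth
  pause followed by recovery, with lognormal measurement noise applied to
  the measured *diameter* (the quantity an imaging pipeline actually reads)
  and propagated cubically to volume;
* bright-field-like images — a dark soft-edged disk on a bright background
  with Gaussian noise at a stated SNR, plus the true mask;
* xenograft-like sections — a uniform spatial point pattern in a disk, with
  Bernoulli Ki67 positivity at a high shell rate outside radius R−s and a
  low core rate inside, and DAB ODs drawn from two lognormal components
  straddling the 0.3 positivity cutoff;
* a deterministic stand-in plasma PK curve — peak at 0.5 h and
  mono-exponential decline (half-life 8 h) so that free drug at 48 h is
  below 2% of the peak, matching the qualitative shape of published mouse
  oxaliplatin kinetics at 8 mg/kg.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from .pk_exposure import ConcentrationProfile
from .spheroid_morphometry import SpheroidImage

__all__ = [
    "GrowthSimParams",
    "SectionSimParams",
    "simulate_growth",
    "expected_growth_inhibition",
    "render_spheroid_image",
    "simulate_section",
    "standard_pk_curve",
]

#: per-day specific growth rate giving 2.3-fold volume growth in 48 h
CONTROL_RATE = float(np.log(2.3) / 2.0)


@dataclass(frozen=True)
class GrowthSimParams:
    """Ground-truth parameters of the two-arm growth simulation.

    Defaults mirror the on-chip study conditions: 4 spheroids per arm,
    ~0.05 mm³ (≈0.46 mm diameter) starting volume, control growth of
    2.3-fold per 48 h, a 2-day treatment-induced pause with full recovery
    at the control rate afterwards, and 2% diameter measurement noise.
    Measurements at days 0, 2 and 7.
    """

    n_per_arm: int = 4
    v0_mean: float = 0.05          # mm³
    v0_cv: float = 0.10
    control_rate: float = CONTROL_RATE   # per day
    pause_days: float = 2.0
    recovery_rate: float | None = None   # per day; None -> control_rate
    noise_cv: float = 0.02               # CV of measured diameter
    timepoints: tuple[float, ...] = (0.0, 2.0, 7.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if min(self.v0_mean, self.control_rate) < 0 or self.v0_cv < 0:
            raise ValueError("rates and dispersions must be >= 0")
        if self.pause_days < 0 or self.noise_cv < 0:
            raise ValueError("pause_days and noise_cv must be >= 0")

    @property
    def effective_recovery_rate(self) -> float:
        return self.control_rate if self.recovery_rate is None else self.recovery_rate


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Median-one lognormal multiplier with the given coefficient of variation."""
    if cv == 0.0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(0.0, sigma, size))


def true_treated_volume(params: GrowthSimParams, v0, t) -> np.ndarray:
    """Noiseless treated-arm volume: flat through the pause, then exponential."""
    t = np.asarray(t, dtype=float)
    grown = np.clip(t - params.pause_days, 0.0, None)
    return v0 * np.exp(params.effective_recovery_rate * grown)


def simulate_growth(params: GrowthSimParams) -> pd.DataFrame:
    """Two-arm spheroid growth records (control + treated).

    Returns a tidy DataFrame (spheroid_id, condition, day, volume_mm3).
    Noise is applied multiplicatively to the measured diameter and enters
    volume as the cube of the diameter factor.  Reproducible for a fixed
    seed; the noiseless means depend only on the non-seed parameters.
    """
    rng = np.random.default_rng(params.seed)
    t = np.asarray(params.timepoints, dtype=float)
    rows = []
    for condition in ("control", "treated"):
        v0 = params.v0_mean * _lognormal_factor(rng, params.v0_cv, params.n_per_arm)
        for i in range(params.n_per_arm):
            if condition == "control":
                v_true = v0[i] * np.exp(params.control_rate * t)
            else:
                v_true = true_treated_volume(params, v0[i], t)
            d_factor = _lognormal_factor(rng, params.noise_cv, t.size)
            v_meas = v_true * d_factor**3
            for day, v in zip(t, v_meas):
                rows.append((f"{condition[0]}{i + 1}", condition, day, v))
    return pd.DataFrame(rows, columns=["spheroid_id", "condition", "day", "volume_mm3"])


def expected_growth_inhibition(params: GrowthSimParams,
                               t_start: float = 0.0,
                               t_end: float = 7.0) -> float:
    """Closed-form GI expectation for the noiseless generator means.

    With exponential control growth at rate r_c and a treated arm flat for
    p days then growing at r_r:

        GI = 1 − (e^{r_r (t_end − p)} − 1) / (e^{r_c t_end} − 1)

    (for t_start = 0 ≤ p ≤ t_end).  The simulate→measure→GI pipeline should
    match this within Monte-Carlo error.
    """
    if t_start != 0.0:
        raise ValueError("closed form assumes t_start = 0")
    p = min(params.pause_days, t_end)
    num = np.expm1(params.effective_recovery_rate * (t_end - p))
    den = np.expm1(params.control_rate * t_end)
    return float(1.0 - num / den)


def render_spheroid_image(diameter_mm: float, pixel_size_um: float,
                          snr: float = 10.0, seed: int = 0,
                          margin: float = 0.4,
                          edge_width_px: float = 2.0
                          ) -> tuple[SpheroidImage, np.ndarray]:
    """Bright-field-like image of one spheroid plus the ground-truth mask.

    Dark disk (intensity 0.4) on a bright background (1.0) with a soft edge
    of ``edge_width_px`` and additive Gaussian noise of SD = contrast/snr
    (``snr=inf`` for noiseless).  ``margin`` is extra frame space as a
    fraction of the diameter.  Raises if the disk would not fit the frame
    or spans fewer than 20 px.
    """
    radius_px = 0.5 * diameter_mm * 1000.0 / pixel_size_um
    if 2.0 * radius_px < 20.0:
        raise ValueError("disk spans < 20 px; decrease pixel size")
    half = int(np.ceil(radius_px * (1.0 + margin)))
    if half <= radius_px:
        raise ValueError("disk exceeds the frame; increase margin")
    n = 2 * half + 1
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - half, xx - half)
    bg, fg = 1.0, 0.4
    # linear ramp across the edge band approximates defocus blur
    edge = np.clip((r - radius_px) / edge_width_px + 0.5, 0.0, 1.0)
    img = fg + (bg - fg) * edge
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, (bg - fg) / snr, img.shape)
    mask = r <= radius_px
    return SpheroidImage(pixels=img, pixel_size=pixel_size_um), mask


@dataclass(frozen=True)
class SectionSimParams:
    """Ground truth for a xenograft-like section with shell/core structure.

    Defaults mirror untreated xenograft histology: an ~80% Ki67-positive
    proliferating shell and an essentially negative core, with the shell
    thickness chosen so the area-weighted overall positive fraction is
    ≈0.46.
    """

    section_radius: float = 4.0   # mm
    shell_thickness: float = 1.3  # mm
    p_shell: float = 0.80
    p_core: float = 0.03
    nuclei_per_mm2: float = 800.0
    seed: int = 0
    #: lognormal OD components (median, sigma of log) for negative/positive nuclei
    od_negative: tuple[float, float] = field(default=(0.10, 0.30))
    od_positive: tuple[float, float] = field(default=(0.60, 0.20))

    def __post_init__(self) -> None:
        if not 0 < self.shell_thickness <= self.section_radius:
            raise ValueError("need 0 < shell_thickness <= section_radius")
        for p in (self.p_shell, self.p_core):
            if not 0.0 <= p <= 1.0:
                raise ValueError("positivity probabilities must lie in [0, 1]")
        if self.nuclei_per_mm2 <= 0:
            raise ValueError("nuclei_per_mm2 must be positive")

    @property
    def expected_overall_fraction(self) -> float:
        """Area-weighted positive fraction implied by the shell/core split."""
        core_share = ((self.section_radius - self.shell_thickness)
                      / self.section_radius) ** 2
        return self.p_shell * (1.0 - core_share) + self.p_core * core_share


def simulate_section(params: SectionSimParams) -> pd.DataFrame:
    """Nucleus-detection table for a shell/core section.

    Nuclei are uniform in the disk; each is Bernoulli Ki67-positive with
    probability ``p_shell`` outside radius R−s and ``p_core`` inside.  ODs
    come from the positive or negative lognormal component, which straddle
    the 0.3 cutoff so that thresholding recovers the Bernoulli labels.
    Columns: x_um, y_um, dab_od, true_positive (ground truth; analysis code
    ignores it).
    """
    rng = np.random.default_rng(params.seed)
    R = params.section_radius
    n = rng.poisson(params.nuclei_per_mm2 * np.pi * R**2)
    # uniform points in a disk via sqrt-radius sampling
    r = R * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    x, y = r * np.cos(theta), r * np.sin(theta)
    in_shell = r > R - params.shell_thickness
    p = np.where(in_shell, params.p_shell, params.p_core)
    positive = rng.uniform(size=n) < p
    od = np.empty(n)
    med_n, sig_n = params.od_negative
    med_p, sig_p = params.od_positive
    od[~positive] = med_n * np.exp(rng.normal(0.0, sig_n, (~positive).sum()))
    od[positive] = med_p * np.exp(rng.normal(0.0, sig_p, positive.sum()))
    return pd.DataFrame(
        {"x_um": x * 1000.0, "y_um": y * 1000.0, "dab_od": od,
         "true_positive": positive}
    )


#: half-life (h) of the stand-in plasma decline; gives free(48 h)/free(peak) < 2%
PK_HALF_LIFE_H = 8.0
#: total plasma peak (µM) such that the free peak is ~3 µM at f_u = 0.33
PK_PEAK_TOTAL_UM = 9.09


def standard_pk_curve() -> ConcentrationProfile:
    """Deterministic stand-in total-plasma concentration curve (synthetic).

    The numeric curve for the mouse study this emulates is not published;
    this stand-in reproduces its stated qualitative features: a peak at
    0.5 h after dosing and a mono-exponential decline with an 8 h half-life,
    leaving < 2% of the peak free concentration measurable at 48 h.
    """
    k = np.log(2.0) / PK_HALF_LIFE_H  # per hour
    decline_t = np.array([0.5, 1, 2, 4, 8, 12, 24, 36, 48], dtype=float)
    decline_c = PK_PEAK_TOTAL_UM * np.exp(-k * (decline_t - 0.5))
    times = np.concatenate(([0.0, 0.25], decline_t))
    conc = np.concatenate(([0.0, 0.5 * PK_PEAK_TOTAL_UM], decline_c))
    return ConcentrationProfile(times=times, concentrations=conc, label="total")


def write_with_sidecar(df: pd.DataFrame, path, params) -> None:
    """Write a generated table plus a JSON sidecar of its true parameters."""
    df.to_csv(path, index=False)
    sidecar = str(path) + ".params.json"
    with open(sidecar, "w") as fh:
        json.dump(asdict(params), fh, indent=2, default=list)
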