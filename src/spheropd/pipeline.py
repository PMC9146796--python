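"""End-to-end reproducible runs: simulate → measure → quantify → model → report.

A run is described by a :class:`RunConfig` (optionally loaded from TOML) and
produces a bundle of CSV artifacts plus a ``summary.json`` that records every
seed and parameter, so two runs with the same config are numerically
identical.

Stages
------
1. exposure — stand-in plasma curve → free-drug correction → stepwise
   schedule → channel-transport prediction of the well concentration over
   the first schedule hours;
2. growth — two-arm spheroid growth simulation → growth inhibition and
   control fold change;
3. morphometry — rendered bright-field image → segmentation → size
   measurement, checked against the generator truth;
4. histology — simulated xenograft-like section → Ki67 fraction, radial
   profile, shell/core geometry;
5. scaling — specific growth rates from the spheroid arms, thin-shell
   closure α = k·s, 14-day xenograft trajectories, modeled folds and GI.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import growth_analysis as ga
from . import ihc_quantification as ihc
from . import pd_xenograft_model as pdm
from . import pk_exposure as pk
from . import spheroid_morphometry as sm
from . import synthetic_data as synth

__all__ = ["RunConfig", "PDConfig", "ExposureConfig", "load_config", "run_end_to_end"]

log = logging.getLogger("spheropd.pipeline")


@dataclass(frozen=True)
class PDConfig:
    """Settings of the spheroid→xenograft scaling stage."""

    shell_thickness_mm: float = 0.60   # calibrated closure input, not a measurement
    horizon_days: float = 14.0
    starting_volume_mm3: float = 100.0
    rounded_beta: bool = False         # True: β rounded to 0.1 mm (2.9 for 100 mm³)
    control_window: tuple[float, float] = (0.0, 2.0)
    treated_window: tuple[float, float] = (0.0, 7.0)

    @property
    def beta(self) -> float:
        r = pdm.radius_from_volume(self.starting_volume_mm3)
        return round(r, 1) if self.rounded_beta else r


@dataclass(frozen=True)
class ExposureConfig:
    """Settings of the exposure-construction stage."""

    unbound_fraction: float = 0.33
    breakpoints_h: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 48.0)
    transport: pk.ChannelTransport = field(default_factory=pk.ChannelTransport)
    #: hours of the schedule to propagate through the channel for the well trace
    transport_window_h: float = 2.0
    transport_dx_mm: float = 0.105


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    gi_window: tuple[float, float] = (0.0, 7.0)
    ki67_cutoff: float = ihc.KI67_CUTOFF
    cc3_cutoff: float = ihc.CC3_CUTOFF
    n_radial_bins: int = 20
    growth: synth.GrowthSimParams = field(default_factory=synth.GrowthSimParams)
    section: synth.SectionSimParams = field(default_factory=synth.SectionSimParams)
    pd: PDConfig = field(default_factory=PDConfig)
    exposure: ExposureConfig = field(default_factory=ExposureConfig)
    #: morphometry self-check: true diameter (mm), pixel size (µm), SNR
    image_diameter_mm: float = 0.5
    image_pixel_size_um: float = 2.0
    image_snr: float = 10.0


def load_config(path) -> RunConfig:
    """Build a RunConfig from a TOML file; missing keys keep their defaults."""
    import tomllib

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        data = tomllib.load(fh)

    def build(cls, section: dict):
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(section) - set(fields)
        if unknown:
            raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
        kwargs = {}
        for k, v in section.items():
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    kwargs = {}
    seed = data.pop("seed", None)
    for name, cls in (("growth", synth.GrowthSimParams),
                      ("section", synth.SectionSimParams),
                      ("pd", PDConfig)):
        if name in data:
            kwargs[name] = build(cls, data.pop(name))
    if "exposure" in data:
        exp = data.pop("exposure")
        transport = exp.pop("transport", None)
        if transport is not None:
            exp["transport"] = build(pk.ChannelTransport, transport)
        kwargs["exposure"] = build(ExposureConfig, exp)
    for k, v in data.items():
        kwargs[k] = tuple(v) if isinstance(v, list) else v
    if seed is not None:
        kwargs["seed"] = seed
        # a single top-level seed re-seeds the generators deterministically
        growth = kwargs.get("growth", synth.GrowthSimParams())
        section = kwargs.get("section", synth.SectionSimParams())
        kwargs["growth"] = dataclasses.replace(growth, seed=seed)
        kwargs["section"] = dataclasses.replace(section, seed=seed + 1)
    return RunConfig(**kwargs)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    return obj


def run_end_to_end(config: RunConfig, outdir) -> dict:
    """Execute every stage and write the artifact bundle to ``outdir``.

    Returns the summary dictionary (also written as ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": _jsonable(config)}

    # 1. exposure construction
    log.info("stage 1: exposure schedule")
    total = synth.standard_pk_curve()
    free = pk.free_concentration(total, pk.PlasmaBinding(config.exposure.unbound_fraction))
    schedule = pk.discretize_schedule(free, np.asarray(config.exposure.breakpoints_h))
    pk.profile_to_csv(free, outdir / "free_profile.csv")
    pk.schedule_to_csv(schedule, outdir / "dose_schedule.csv")
    window = config.exposure.transport_window_h
    t_grid = np.linspace(0.0, window, 241)
    well = pk.well_concentration(schedule, config.exposure.transport, t_grid,
                                 dx_mm=config.exposure.transport_dx_mm)
    pk.profile_to_csv(well, outdir / "well_concentration.csv")
    summary["exposure"] = {
        "free_peak_uM": float(free.concentrations.max()),
        "schedule_auc_uM_h": schedule.auc(),
        "profile_auc_uM_h": free.auc(schedule.breakpoints[0], schedule.breakpoints[-1]),
        "well_peak_uM_first_window": float(well.concentrations.max()),
        "advective_transit_min": config.exposure.transport.well_position
        / config.exposure.transport.mean_velocity,
    }

    # 2. growth simulation and inhibition
    log.info("stage 2: growth records and inhibition")
    records = synth.simulate_growth(config.growth)
    records.to_csv(outdir / "growth_records.csv", index=False)
    control = records[records.condition == "control"]
    treated = records[records.condition == "treated"]
    t0, t1 = config.gi_window
    gi = ga.growth_inhibition(treated, control, t0, t1)
    control_fold = ga.fold_change(control, 0.0, 2.0)
    welch = ga.welch_t_test(
        treated.loc[treated.day == t1, "volume_mm3"],
        control.loc[control.day == t1, "volume_mm3"],
    )
    summary["growth"] = {
        "gi": gi.gi,
        "gi_expected_closed_form": synth.expected_growth_inhibition(config.growth, t0, t1),
        "n_treated": gi.n_treated,
        "n_control": gi.n_control,
        "control_fold_48h_mean": control_fold.mean,
        "control_fold_48h_sd": control_fold.sd,
        "welch_day7": {"t": welch[0], "df": welch[1], "p": welch[2]},
    }

    # 3. morphometry self-check
    log.info("stage 3: morphometry")
    image, truth_mask = synth.render_spheroid_image(
        config.image_diameter_mm, config.image_pixel_size_um,
        snr=config.image_snr, seed=config.seed + 2,
    )
    mask = sm.segment_spheroid(image)
    meas = sm.measure(mask, image.pixel_size)
    summary["morphometry"] = {
        "true_diameter_mm": config.image_diameter_mm,
        "measured_diameter_mm": meas.equivalent_diameter,
        "measured_volume_mm3": meas.volume,
        "diameter_error_fraction": meas.equivalent_diameter / config.image_diameter_mm - 1.0,
    }

    # 4. section histology
    log.info("stage 4: section quantification")
    detections = simulated = synth.simulate_section(config.section)
    simulated.drop(columns=["true_positive"]).to_csv(
        outdir / "section_detections.csv", index=False
    )
    ki67 = ihc.ki67_positive_fraction(detections, config.ki67_cutoff)
    profile = ihc.radial_positive_profile(detections, n_bins=config.n_radial_bins,
                                          cutoff=config.ki67_cutoff)
    profile.to_csv(outdir / "radial_profile.csv", index=False)
    geometry = ihc.estimate_shell_geometry(profile)
    summary["histology"] = {
        "ki67_fraction": ki67,
        "overall_fraction_area_weighted": ihc.overall_positive_fraction(profile, "area"),
        "overall_fraction_count_weighted": ihc.overall_positive_fraction(profile, "count"),
        "shell_thickness_mm": geometry.shell_thickness,
        "true_shell_thickness_mm": config.section.shell_thickness,
        "shell_positive_fraction": geometry.shell_positive_fraction,
        "core_positive_fraction": geometry.core_positive_fraction,
        "n_nuclei": int(len(detections)),
    }

    # 5. spheroid → xenograft scaling
    log.info("stage 5: pharmacodynamic scaling")
    s = config.pd.shell_thickness_mm
    k_control = pdm.specific_growth_rate_from_spheroids(control, config.pd.control_window)
    k_treated = pdm.specific_growth_rate_from_spheroids(treated, config.pd.treated_window)
    alpha_c = pdm.derive_alpha(pdm.ShellKinetics(k_control, s))
    alpha_t = pdm.derive_alpha(pdm.ShellKinetics(k_treated, s))
    beta = config.pd.beta
    m_control = pdm.XenograftModel(alpha_c, beta)
    m_treated = pdm.XenograftModel(alpha_t, beta)
    days = np.arange(0.0, config.pd.horizon_days + 0.5)
    traj = pdm.trajectory(m_control, days).rename(columns={"volume_mm3": "volume_control_mm3"})
    traj["volume_treated_mm3"] = pdm.volume_at(m_treated, days)
    traj.to_csv(outdir / "pd_trajectories.csv", index=False)
    h = config.pd.horizon_days
    summary["pd_model"] = {
        "k_control_per_day": k_control,
        "k_treated_per_day": k_treated,
        "shell_thickness_mm": s,
        "alpha_control_mm_per_day": alpha_c,
        "alpha_treated_mm_per_day": alpha_t,
        "beta_mm": beta,
        "final_volume_control_mm3": pdm.volume_at(m_control, h),
        "final_volume_treated_mm3": pdm.volume_at(m_treated, h),
        "fold_control_model_v0": pdm.fold_change_at(m_control, h),
        "fold_treated_model_v0": pdm.fold_change_at(m_treated, h),
        "fold_control_nominal_v0": pdm.fold_change_at(
            m_control, h, v0=config.pd.starting_volume_mm3),
        "fold_treated_nominal_v0": pdm.fold_change_at(
            m_treated, h, v0=config.pd.starting_volume_mm3),
        "modeled_gi": pdm.modeled_growth_inhibition(m_treated, m_control, h),
    }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2)
    log.info("run complete: %s", outdir)
    return summary
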