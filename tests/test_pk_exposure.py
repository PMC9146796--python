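"""Exposure construction: binding correction, decline fit, schedule, transport."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spheropd.pk_exposure import (
    CFLViolation,
    ChannelTransport,
    ConcentrationProfile,
    DoseSchedule,
    PlasmaBinding,
    discretize_schedule,
    fit_exponential_decline,
    free_concentration,
    simulate_transport,
    well_concentration,
)


class TestFreeConcentration:
    def test_protein_binding_correction(self):
        """f_u = 0.33 scales totals (3.0, 0.3) uM to free (0.99, 0.099) uM."""
        total = ConcentrationProfile([1.0, 24.0], [3.0, 0.3], label="total")
        free = free_concentration(total, PlasmaBinding(0.33))
        assert free.label == "free"
        np.testing.assert_allclose(free.concentrations, [0.99, 0.099])
        np.testing.assert_array_equal(free.times, total.times)

    @pytest.mark.parametrize("fu,factor", [(1.0, 1.0), (0.0, 0.0)])
    def test_identity_and_annihilation(self, fu, factor, exponential_profile):
        free = free_concentration(exponential_profile, PlasmaBinding(fu))
        np.testing.assert_array_equal(
            free.concentrations, factor * exponential_profile.concentrations
        )

    def test_rejects_already_free_profile(self, exponential_profile):
        free = free_concentration(exponential_profile, PlasmaBinding(0.33))
        with pytest.raises(ValueError, match="refusing to correct twice"):
            free_concentration(free, PlasmaBinding(0.33))

    @given(
        a=st.lists(st.floats(0.0, 10.0), min_size=3, max_size=3),
        b=st.lists(st.floats(0.0, 10.0), min_size=3, max_size=3),
        fu=st.floats(0.0, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_linearity(self, a, b, fu):
        """Binding correction is pointwise linear: f_u(a+b) = f_u a + f_u b."""
        t = [0.0, 1.0, 2.0]
        binding = PlasmaBinding(fu)
        lhs = free_concentration(
            ConcentrationProfile(t, np.add(a, b)), binding
        ).concentrations
        rhs = (
            free_concentration(ConcentrationProfile(t, a), binding).concentrations
            + free_concentration(ConcentrationProfile(t, b), binding).concentrations
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


class TestProfileInvariants:
    def test_rejects_non_increasing_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ConcentrationProfile([0.0, 1.0, 1.0], [1.0, 1.0, 1.0])

    def test_rejects_negative_concentration(self):
        with pytest.raises(ValueError, match="non-negative"):
            ConcentrationProfile([0.0, 1.0], [1.0, -0.1])


class TestFitExponentialDecline:
    def test_noiseless_recovery(self, exponential_profile):
        c0, k = fit_exponential_decline(exponential_profile)
        assert c0 == pytest.approx(2.0, rel=1e-10)
        assert k == pytest.approx(0.1, rel=1e-10)

    def test_flat_profile_gives_zero_rate(self):
        profile = ConcentrationProfile([0.0, 1.0, 2.0, 3.0], [1.5] * 4)
        _, k = fit_exponential_decline(profile)
        assert k == pytest.approx(0.0, abs=1e-12)

    def test_fit_restricted_to_post_peak_points(self):
        """The rising limb before the peak must not bias the decline fit."""
        t = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0])
        c = np.where(t < 0.5, 4.0 * t, 2.0 * np.exp(-0.1 * (t - 0.5)))
        c0, k = fit_exponential_decline(ConcentrationProfile(t, c))
        assert k == pytest.approx(0.1, rel=1e-9)

    def test_noisy_recovery_within_simulation_se(self):
        """k-hat lands within 3 SE of truth; SE frozen from a 1000-replicate
        simulation of the same design (n=20 over 30 h, 5% lognormal noise)."""
        se_k = 0.00125
        rng = np.random.default_rng(42)
        t = np.linspace(0.0, 30.0, 20)
        c = 2.0 * np.exp(-0.1 * t) * np.exp(rng.normal(0.0, 0.05, t.size))
        _, k = fit_exponential_decline(ConcentrationProfile(t, c))
        assert abs(k - 0.1) < 3 * se_k

    def test_too_few_post_peak_points(self):
        with pytest.raises(ValueError, match=">= 3 points"):
            fit_exponential_decline(ConcentrationProfile([0.0, 1.0], [2.0, 1.0]))


class TestDiscretizeSchedule:
    def test_constant_profile_gives_constant_levels(self):
        profile = ConcentrationProfile([0.0, 10.0], [1.0, 1.0], label="free")
        sched = discretize_schedule(profile, [0.0, 2.0, 5.0, 10.0])
        np.testing.assert_allclose(sched.levels, 1.0)

    def test_linear_decay_single_interval(self):
        """Trapezoid oracle: 2 -> 0 uM over one interval averages to 1 uM."""
        profile = ConcentrationProfile([0.0, 4.0], [2.0, 0.0], label="free")
        sched = discretize_schedule(profile, [0.0, 4.0])
        assert sched.levels[0] == pytest.approx(1.0, rel=1e-12)

    def test_auc_preserved_on_exponential_profile(self, exponential_profile):
        """Step levels preserve interval AUCs of the piecewise-linear profile."""
        bp = np.array([0.0, 2.0, 5.0, 10.0, 15.0, 22.0, 30.0])
        sched = discretize_schedule(exponential_profile, bp)
        for lo, hi, level in zip(bp[:-1], bp[1:], sched.levels):
            assert level * (hi - lo) == pytest.approx(
                exponential_profile.auc(lo, hi), rel=1e-9
            )
        assert sched.auc() == pytest.approx(exponential_profile.auc(0.0, 30.0), rel=1e-9)

    def test_rejects_breakpoints_outside_span(self, exponential_profile):
        with pytest.raises(ValueError, match="outside the profile span"):
            discretize_schedule(exponential_profile, [0.0, 40.0])


class TestWellConcentration:
    def test_short_channel_approaches_zero_lag(self):
        """With a tiny channel length the well sees the schedule unchanged."""
        transport = ChannelTransport(length=0.5, well_position=0.25)
        sched = DoseSchedule([0.0, 1.0], [1.0])
        t_grid = np.linspace(0.0, 0.5, 61)
        well = well_concentration(sched, transport, t_grid, dx_mm=0.05)
        # past a few transit times the well must sit at the inlet level
        assert np.all(well.concentrations[t_grid > 0.05] > 0.99)

    def test_step_mid_rise_matches_advective_transit(self, chip_transport):
        """Mid-rise of a step at 10.5 mm arrives after ~10.5 min (U = 1 mm/min)."""
        sched = DoseSchedule([0.0, 2.0], [1.0])
        t_grid = np.linspace(0.0, 1.0, 121)
        well = well_concentration(sched, chip_transport, t_grid)
        t_mid_min = np.interp(0.5, well.concentrations, well.times) * 60.0
        transit = chip_transport.well_position / chip_transport.mean_velocity
        assert t_mid_min == pytest.approx(transit, rel=0.05)

    def test_completed_pulse_mass_balance(self, chip_transport):
        """Outlet advective-flux integral matches the inlet's within 1%."""
        sched = DoseSchedule([0.0, 1.0], [2.0])
        sol = simulate_transport(sched, chip_transport, t_end_h=2.0)
        assert sol.outlet_flux_integral == pytest.approx(
            sol.inlet_flux_integral, rel=0.01
        )

    def test_maximum_principle_on_random_schedules(self, chip_transport):
        """Well trace stays within [min, max] of the inlet levels (incl. 0 start)."""
        rng = np.random.default_rng(5)
        for _ in range(3):
            levels = rng.uniform(0.0, 3.0, size=4)
            sched = DoseSchedule(np.linspace(0.0, 1.0, 5), levels)
            well = well_concentration(
                sched, chip_transport, np.linspace(0.0, 1.2, 60), dx_mm=0.1
            )
            assert well.concentrations.min() >= -1e-9
            assert well.concentrations.max() <= levels.max() + 1e-9

    def test_grid_refinement_convergence(self, chip_transport):
        """Halving dx changes the well trace by < 1% RMS of the step height."""
        sched = DoseSchedule([0.0, 2.0], [1.0])
        t_grid = np.linspace(0.0, 1.0, 121)
        coarse = well_concentration(sched, chip_transport, t_grid, dx_mm=0.1)
        fine = well_concentration(sched, chip_transport, t_grid, dx_mm=0.05)
        rms = np.sqrt(np.mean((coarse.concentrations - fine.concentrations) ** 2))
        assert rms < 0.01

    def test_cfl_violation_reported_not_subsampled(self, chip_transport):
        sched = DoseSchedule([0.0, 1.0], [1.0])
        with pytest.raises(CFLViolation, match="exceeds the stability limit"):
            simulate_transport(sched, chip_transport, 0.5, dx_mm=0.1, dt_min=1.0)
        with pytest.raises(CFLViolation, match="cell P"):
            simulate_transport(sched, chip_transport, 0.5, dx_mm=2.0)

    def test_zero_flow_rejected(self):
        with pytest.raises(ValueError):
            ChannelTransport(flow_rate=0.0)


class TestTransportGeometry:
    def test_taylor_aris_dispersion_value(self, chip_transport):
        """U = 1 mm/min, Pe = U h / D ~ 20.3, D_eff = D (1 + Pe^2/210)."""
        assert chip_transport.mean_velocity == pytest.approx(1.0)
        d = 8.2e-6 * 100 * 60
        pe = 1.0 * 1.0 / d
        assert chip_transport.peclet == pytest.approx(pe)
        assert chip_transport.effective_dispersion == pytest.approx(
            d * (1 + pe**2 / 210)
        )

    def test_well_beyond_channel_rejected(self):
        with pytest.raises(ValueError, match="well_position"):
            ChannelTransport(well_position=30.0)
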