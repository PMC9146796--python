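"""Growth inhibition, fold change, Welch test, count-volume regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from spheropd.growth_analysis import (
    count_volume_regression,
    fold_change,
    growth_inhibition,
    welch_t_test,
)


def _records(condition, volumes_by_day):
    rows = []
    for sid, series in volumes_by_day.items():
        for day, v in series.items():
            rows.append((sid, condition, day, v))
    return pd.DataFrame(rows, columns=["spheroid_id", "condition", "day", "volume_mm3"])


class TestGrowthInhibition:
    def test_hand_computed_seventy_percent(self, toy_records):
        """Control mean dV = 200, treated mean dV = 60 -> GI = 0.70 exactly."""
        control = toy_records[toy_records.condition == "control"]
        treated = toy_records[toy_records.condition == "treated"]
        res = growth_inhibition(treated, control, 0.0, 7.0)
        assert res.gi == pytest.approx(0.70, abs=1e-15)
        assert res.mean_delta_control == pytest.approx(200.0)
        assert res.mean_delta_treated == pytest.approx(60.0)
        assert (res.n_treated, res.n_control) == (2, 2)

    def test_full_inhibition_when_treated_static(self):
        control = _records("control", {"c1": {0: 100.0, 7: 300.0}})
        treated = _records("treated", {"t1": {0: 80.0, 7: 80.0}})
        assert growth_inhibition(treated, control, 0, 7).gi == pytest.approx(1.0)

    def test_null_effect_when_groups_identical(self, toy_records):
        control = toy_records[toy_records.condition == "control"]
        res = growth_inhibition(control, control, 0.0, 7.0)
        assert res.gi == pytest.approx(0.0, abs=1e-15)

    def test_missing_timepoint_excluded_with_warning(self, toy_records):
        control = toy_records[toy_records.condition == "control"]
        treated = toy_records[toy_records.condition == "treated"]
        # drop t1's endpoint: only t0 (dV = 40) remains
        treated = treated.drop(treated[(treated.spheroid_id == "t1")
                                       & (treated.day == 7.0)].index)
        with pytest.warns(UserWarning, match="excluded"):
            res = growth_inhibition(treated, control, 0.0, 7.0)
        assert res.n_treated == 1
        assert res.gi == pytest.approx(1 - 40.0 / 200.0)

    def test_zero_control_growth_rejected(self):
        control = _records("control", {"c1": {0: 100.0, 7: 100.0}})
        treated = _records("treated", {"t1": {0: 100.0, 7: 120.0}})
        with pytest.raises(ValueError, match="GI undefined"):
            growth_inhibition(treated, control, 0, 7)

    def test_shrinking_treated_gives_gi_above_one(self):
        control = _records("control", {"c1": {0: 100.0, 7: 300.0}})
        treated = _records("treated", {"t1": {0: 100.0, 7: 60.0}})
        assert growth_inhibition(treated, control, 0, 7).gi == pytest.approx(1.2)

    @given(scale=st.floats(1e-3, 1e3))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_unit_rescaling(self, scale):
        """GI is dimensionless: multiplying every volume by c leaves it unchanged."""
        toy_records = pd.concat([
            _records("control", {"c0": {0: 100.0, 7: 250.0},
                                 "c1": {0: 100.0, 7: 350.0}}),
            _records("treated", {"t0": {0: 100.0, 7: 140.0},
                                 "t1": {0: 100.0, 7: 180.0}}),
        ])
        control = toy_records[toy_records.condition == "control"]
        treated = toy_records[toy_records.condition == "treated"]
        gi0 = growth_inhibition(treated, control, 0.0, 7.0).gi
        scaled = toy_records.assign(volume_mm3=toy_records.volume_mm3 * scale)
        gi1 = growth_inhibition(
            scaled[scaled.condition == "treated"],
            scaled[scaled.condition == "control"], 0.0, 7.0,
        ).gi
        assert gi1 == pytest.approx(gi0, rel=1e-9)

    def test_untreated_contamination_moves_gi_toward_zero(self):
        """Adding control-behaving spheroids to the treated arm dilutes GI."""
        control = _records("control", {f"c{i}": {0: 100.0, 7: 300.0} for i in range(4)})
        gis = []
        for n_contaminant in range(3):
            vols = {f"t{i}": {0: 100.0, 7: 160.0} for i in range(4)}
            vols.update(
                {f"x{i}": {0: 100.0, 7: 300.0} for i in range(n_contaminant)}
            )
            gis.append(growth_inhibition(_records("treated", vols), control, 0, 7).gi)
        assert gis[0] > gis[1] > gis[2] > 0


class TestFoldChange:
    def test_division(self):
        rec = _records("control", {"c1": {0: 0.05, 2: 0.115}})
        assert fold_change(rec, 0, 2).per_spheroid.iloc[0] == pytest.approx(2.3)

    def test_constant_volume_fold_one(self):
        rec = _records("control", {"c1": {0: 0.05, 2: 0.05}})
        assert fold_change(rec, 0, 2).mean == pytest.approx(1.0)

    def test_mean_and_sd(self):
        rec = _records("control", {"c1": {0: 1.0, 2: 2.0}, "c2": {0: 1.0, 2: 3.0}})
        res = fold_change(rec, 0, 2)
        assert res.mean == pytest.approx(2.5)
        assert res.sd == pytest.approx(np.sqrt(0.5), abs=1e-4)

    def test_missing_timepoint_rejected(self):
        rec = _records("control", {"c1": {0: 1.0}})
        with pytest.raises(ValueError, match="no records at day"):
            fold_change(rec, 0, 2)


class TestWelchTTest:
    def test_identical_groups(self):
        t, _, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_clear_shift_significant(self):
        t, df, p = welch_t_test([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert p < 0.001

    def test_antisymmetry(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 9.0, 11.0]
        t1, df1, p1 = welch_t_test(a, b)
        t2, df2, p2 = welch_t_test(b, a)
        assert t2 == pytest.approx(-t1)
        assert df2 == pytest.approx(df1)
        assert p2 == pytest.approx(p1)

    def test_matches_scipy_to_1e10(self):
        """Formula-level implementation vs scipy's Welch test on fixed inputs."""
        rng = np.random.default_rng(3)
        a = rng.normal(1.0, 1.0, 8)
        b = rng.normal(1.8, 2.5, 5)
        t, df, p = welch_t_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert df == pytest.approx(ref.df, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            welch_t_test([1.0], [1.0, 2.0])


class TestCountVolumeRegression:
    def test_exact_line(self):
        v = np.array([0.05, 0.1, 0.2, 0.4])
        slope, intercept, r = count_volume_regression(1e6 * v, v)
        assert slope == pytest.approx(1e6)
        assert r == pytest.approx(1.0)

    def test_constant_counts(self):
        slope, _, r = count_volume_regression([5.0, 5.0, 5.0], [0.1, 0.2, 0.3])
        assert slope == 0.0
        assert r == 0.0

    def test_noisy_line_slope_within_simulated_ci(self):
        """Slope lands within 3 SE of truth, SE from the analytic OLS formula
        cross-checked against a replicate simulation at development time."""
        rng = np.random.default_rng(0)
        v = np.linspace(0.05, 0.5, 12)
        counts = 1e6 * v + rng.normal(0.0, 2e4, v.size)
        slope, _, _ = count_volume_regression(counts, v)
        se = 2e4 / np.sqrt(np.sum((v - v.mean()) ** 2))
        assert abs(slope - 1e6) < 3 * se

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="n >= 3"):
            count_volume_regression([1.0, 2.0], [0.1, 0.2])
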