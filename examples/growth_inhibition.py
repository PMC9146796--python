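"""Growth inhibition from a simulated two-arm on-chip experiment.

Simulates 4 control and 4 treated spheroids imaged at days 0, 2 and 7:
controls grow 2.3-fold per 48 h; treated spheroids pause for 2 days
(the transient drug effect) and then regrow.  Computes the xenograft-style
growth-inhibition statistic and the day-7 Welch test.
"""

from spheropd import (
    GrowthSimParams,
    expected_growth_inhibition,
    fold_change,
    growth_inhibition,
    simulate_growth,
    welch_t_test,
)

params = GrowthSimParams(seed=0)
records = simulate_growth(params)
control = records[records.condition == "control"]
treated = records[records.condition == "treated"]

folds = fold_change(control, 0.0, 2.0)
print(f"control 48 h fold change: {folds.mean:.2f} +/- {folds.sd:.2f} "
      f"(generator truth 2.30)")

res = growth_inhibition(treated, control, 0.0, 7.0)
print(f"growth inhibition over 7 days: {res.gi:.2f} "
      f"(n={res.n_treated} treated vs n={res.n_control} control)")
print(f"closed-form generator expectation: "
      f"{expected_growth_inhibition(params):.3f} — a 2-day pause with full "
      "recovery; the measured on-chip value of ~0.70 corresponds to a "
      "slightly slower post-pause regrowth.")

t, df, p = welch_t_test(
    treated.loc[treated.day == 7.0, "volume_mm3"],
    control.loc[control.day == 7.0, "volume_mm3"],
)
print(f"day-7 Welch test: t = {t:.2f}, df = {df:.1f}, p = {p:.2g}")
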