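"""Build an in vivo-like oxaliplatin perfusion schedule and predict the well exposure.

Starts from a tabulated total-plasma concentration curve (the synthetic
stand-in for a mouse 8 mg/kg dose), corrects it to free drug with the 33%
unbound fraction, discretizes it into an AUC-preserving stepwise schedule,
and propagates the first two hours through the perfusion channel to see the
lag and smearing the spheroid actually experiences.
"""

import numpy as np

from spheropd import (
    ChannelTransport,
    PlasmaBinding,
    discretize_schedule,
    free_concentration,
    standard_pk_curve,
    well_concentration,
)

total = standard_pk_curve()
free = free_concentration(total, PlasmaBinding(unbound_fraction=0.33))
print(f"total peak {total.concentrations.max():.2f} uM -> "
      f"free peak {free.concentrations.max():.2f} uM (67% protein-bound)")

schedule = discretize_schedule(free, [0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 48.0])
print("stepwise schedule (uM):",
      np.array2string(schedule.levels, precision=3))
print(f"schedule AUC {schedule.auc():.3f} uM*h == profile AUC "
      f"{free.auc():.3f} uM*h (exposure preserved)")

chip = ChannelTransport()  # 21 x 2 x 1 mm channel, 2 uL/min, well at 10.5 mm
well = well_concentration(schedule, chip, np.linspace(0.0, 2.0, 241))
t_half_rise = np.interp(0.5 * schedule.levels[0], well.concentrations, well.times)
print(f"well mid-rise at {t_half_rise * 60:.1f} min "
      f"(advective transit {chip.well_position / chip.mean_velocity:.1f} min): "
      "the channel delays and smooths each concentration step slightly, "
      "but the programmed exposure reaches the spheroid essentially intact.")
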