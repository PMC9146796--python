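"""Quantify the proliferating shell of a xenograft-like section.

Simulates a 4 mm-radius Ki67-stained section with an 80%-positive
peripheral shell (1.3 mm thick) and a 3%-positive core, then recovers the
partition from the radial positivity profile alone.
"""

from spheropd import (
    SectionSimParams,
    estimate_shell_geometry,
    ki67_positive_fraction,
    overall_positive_fraction,
    radial_positive_profile,
    simulate_section,
)

params = SectionSimParams(seed=0)
detections = simulate_section(params)
print(f"{len(detections)} nuclei in a {params.section_radius} mm section")

frac = ki67_positive_fraction(detections)  # OD >= 0.3 per nucleus
profile = radial_positive_profile(detections, center=(0.0, 0.0), n_bins=20)
geom = estimate_shell_geometry(profile)

print(f"whole-section Ki67+ fraction: {frac:.3f} (count-weighted)")
print(f"area-weighted overall fraction: "
      f"{overall_positive_fraction(profile, 'area'):.3f} "
      f"(geometric expectation {params.expected_overall_fraction:.3f})")
print(f"estimated shell thickness: {geom.shell_thickness:.2f} mm "
      f"(true {params.shell_thickness} mm; one radial bin = "
      f"{geom.section_radius / 20:.2f} mm)")
print(f"shell / core positivity: {geom.shell_positive_fraction:.2f} / "
      f"{geom.core_positive_fraction:.2f}")
print("Only the peripheral shell proliferates — roughly half the section "
      "area — which is why a small, fully proliferative spheroid can stand "
      "in for the growing part of a much larger xenograft.")
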