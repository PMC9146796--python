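# Demo configuration for `spheropd run --config examples/demo_config.toml`.
# Every key is optional; omitted keys keep the defaults, which are the
# study conditions (4 spheroids/arm, 2.3-fold/48 h control growth, 2-day
# treatment pause, 0.6 mm closure shell, 14-day horizon).

seed = 0

[growth]
n_per_arm = 4
pause_days = 2.0
noise_cv = 0.02

[section]
section_radius = 4.0
shell_thickness = 1.3
p_shell = 0.80
p_core = 0.03

[pd]
shell_thickness_mm = 0.60
horizon_days = 14.0
starting_volume_mm3 = 100.0
rounded_beta = true

[exposure]
unbound_fraction = 0.33
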