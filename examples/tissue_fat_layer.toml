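# Three-layer tissue stack (0.6 mm skin, 0.3 mm fat, muscle below),
# 30 s freeze at body temperature.

[geometry]
r_max_mm = 12.0
z_max_mm = 12.0

[grid]
n_r = 120
n_z = 120

[materials]
set = "tissue"
skin_thickness_mm = 0.6
fat_thickness_mm = 0.3

[temperatures]
bath_C = 34.0

[schedule]
freeze_s = 30.0

[output]
isotherm_levels_C = [0.0, -40.0]
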