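# 30 s freeze of 5% gelatin hydrogel under the 4 mm LN2 applicator,
# followed by 60 s of thawing; quick grid for demonstration.

[geometry]
r_max_mm = 12.0
z_max_mm = 12.0
applicator_radius_mm = 4.0
press_in_depth_mm = 1.0

[grid]
n_r = 128
n_z = 128

[materials]
set = "hydrogel"

[temperatures]
applicator_C = -196.0
bath_C = 34.0

[schedule]
freeze_s = 30.0
thaw_s = 60.0

[output]
isotherm_levels_C = [0.0, -10.0, -40.0]
trace_interval_s = 1.0
snapshot_interval_s = 10.0
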