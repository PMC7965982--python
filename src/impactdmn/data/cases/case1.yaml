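# Fall from a 2-story house roof; left frontal head impact.
case: 1
location: fronto_polar
impactor: flat
# gutter height of a 2-story house + gutter + 50th-percentile standing
# height - head-to-contact offset.  NOTE: these components sum to 7.46 m
# but the reconstruction narrative carries 7.3 m; the printed total is
# kept as the velocity input and the discrepancy is reported, not
# silently corrected.
height_components: [5.7, 0.1, 1.76, -0.1]
height_printed_m: 7.3
velocity_rounding: integer
head_mass_kg: 6.82
accel_g: 80
velocity_range_ms: [2.24, 12.0]
observed_damage_percent: 1.48
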