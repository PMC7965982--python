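# Fall from a 3-story roof; left temporal/frontal impact.
case: 7
location: temporal
impactor: flat
# gutter height of a 3-story house + gutter + standing height - offset.
height_components: [8.3, 0.1, 1.76, -0.1]
velocity_rounding: decimal1
velocity_range_ms: [null, 14.1]
observed_damage_percent: 8.93
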