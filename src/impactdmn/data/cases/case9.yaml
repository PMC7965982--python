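# Cyclist knocked off a bike; left parietal ground impact.
case: 9
location: lateral_fronto_parietal
impactor: flat
# simulated similar-case vertical-velocity range from the literature.
velocity_range_ms: [4.0, 5.4]
observed_damage_percent: 6.17
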