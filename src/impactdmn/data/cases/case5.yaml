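# Pedestrian hit by a cyclist; impact behind the right ear.
case: 5
location: lateral_fronto_parietal
impactor: flat
# threshold velocity for impact-related fracture.
velocity_range_ms: [5.0, 5.0]
observed_damage_percent: 4.0
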