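# Charged by a bull, thrown onto concrete; occipital impact.
case: 8
location: occipital
impactor: flat
# lower bound: backwards fall from standing; upper bound: minimum
# velocity for frontal-bone fracture, 20 mph converted at 2 decimals.
vehicle_speed_mph: [20, 40]
mph_rounding_decimals: 2
velocity_range_ms: [6.75, 8.94]
observed_damage_percent: 19.43
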