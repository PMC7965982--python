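# Pedestrian hit by a car at ~30 mph; right orbital/frontal impact.
case: 6
location: fronto_polar
impactor: flat
vehicle_speed_mph: [30]
mph_rounding_decimals: 1
head_mass_kg: 6.82
accel_g: 80
velocity_range_ms: [9.0, 9.0]
observed_damage_percent: 2.53
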