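# Pedestrian hit by a van at 20-30 mph; secondary occipital ground impact.
case: 4
location: occipital
impactor: flat
vehicle_speed_mph: [20, 30]
# secondary-impact range 15-35 km/h from pedestrian-impact literature.
velocity_range_ms: [4.17, 9.72]
observed_damage_percent: 14.67
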