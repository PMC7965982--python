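# Kicked by a horse, backwards fall, occipital ground impact.
case: 3
location: occipital
impactor: flat
# literature fall-velocity range; not derived in-package.
velocity_range_ms: [3.2, 4.8]
observed_damage_percent: 5.17
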