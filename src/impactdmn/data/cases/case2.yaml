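# Punch to the face, backwards fall onto the occiput.
case: 2
location: occipital
impactor: flat
# literature translational-velocity range for a backwards fall from
# standing (straight body vs bent at waist); not derived in-package.
velocity_range_ms: [4.85, 6.75]
observed_damage_percent: 3.2
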