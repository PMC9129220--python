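# High-resource ICU archetype: a university hospital running internationally
# standardized critical-care protocols.  Uniform pass probability 0.90 per
# scored indicator puts the expected total near 88% of the 26-point maximum
# (22*0.90 + 0.90^3 + 0.90^4 + 2*0.90^2 ~ 22.8); complete documentation, so
# no missingness.
name: high_resource
default_pass_prob: 0.90
pass_prob: {}
default_missing_prob: 0.0
missing_prob: {}
default_na_prob: 0.0
na_prob: {}
rater_flip_prob: 0.0
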