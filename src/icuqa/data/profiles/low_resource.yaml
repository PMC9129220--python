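# Low-resource ICU archetype: an understaffed public-hospital unit without
# standardized critical-care protocols.  Uniform pass probability 0.55 per
# scored indicator puts the expected total near half of the 26-point maximum
# (grouped items compound: 22*0.55 + 0.55^3 + 0.55^4 + 2*0.55^2 ~ 13.0 before
# missing-data penalties); 2% per-indicator missingness exercises the penalty
# rule at a realistic chart-documentation level.
name: low_resource
default_pass_prob: 0.55
pass_prob: {}
default_missing_prob: 0.02
missing_prob: {}
default_na_prob: 0.0
na_prob: {}
rater_flip_prob: 0.0
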