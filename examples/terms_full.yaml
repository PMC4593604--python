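# Ordered term list for the full-window MANOVA (pre + post concatenated).
# Well location and biological repeat enter as main effects only: the
# location effect is assumed invariant across strains, stages, trials and
# stimuli, and likewise for the biological repeat.  Order matters: sums of
# squares are sequential.
- well
- bio_rep
- strain
- stage_dpf
- trial_index
- stimulus
- "strain:stage_dpf"
- "strain:trial_index"
- "strain:stimulus"
- "stage_dpf:trial_index"
- "stage_dpf:stimulus"
- "trial_index:stimulus"
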