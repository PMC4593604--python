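# Ordered term list for single-stimulus models (Light-On or Light-Off fitted
# separately; the stimulus factor is absent because only one level remains).
- well
- bio_rep
- strain
- stage_dpf
- trial_index
- "strain:stage_dpf"
- "strain:trial_index"
- "stage_dpf:trial_index"
- "strain:stage_dpf:trial_index"
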