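# Reduced synthetic plate experiment for the demo workflow: the full design
# shape (3 strains x 2 biological repeats x 3 On/Off trials) on a 4x6 plate
# section, two assay days, with shortened phases so the demo runs quickly.
rows: 4
cols: 6
strains: {AB: 0.070, TL: 0.060, TLAB: 0.065}
strain_resp_mod: {AB: 1.15, TL: 1.0, TLAB: 0.85}
stages: [4, 6]
stage_mult: {4: 0.75, 6: 1.0}
stage_resp_mod: {4: 0.6, 6: 1.0}
n_bio_reps: 2
bio_rep_effects: [0.0, 0.005]
tech_rep_effects: [0.01, 0.0, 0.0]
location_coef: 0.02
on_amp: 0.35
on_decay: 0.45
on_sustain: 0.04
off_amp: 0.25
off_decay: 0.9
off_sustain: 0.09
animal_sd: 0.02
ar1_rho: 0.5
ar1_innov_sd: 0.02
obs_sd: 0.0
fps: 30
dark_adapt_s: 12600
record_lead_s: 40
n_trials: 3
phase_len_s: 70
seed: 1
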