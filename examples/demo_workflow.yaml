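# End-to-end demo: simulate a reduced plate experiment, window it around the
# light changes, then run the strain-comparison battery, a planning curve,
# the full sequential MANOVA and the per-second effect-size dynamics.
# Run from the repository root:
#   vmr pipeline --config examples/demo_workflow.yaml --seed 1 --out-dir demo_out
stages:
  - stage: simulate
    config: examples/sim_config.yaml
    mode: second
    out: {activity: activity.csv, schedule: schedule.csv}
  - stage: window
    activity: "@activity.csv"
    schedule: "@schedule.csv"
    pre: 30
    post: 30
    out: {windows: windows.csv}
  - stage: traces
    windows: "@windows.csv"
    grouping: [strain, stimulus]
    out: {table: traces.csv}
  - stage: hotelling
    windows: "@windows.csv"
    group_field: strain
    window_tags: [pre, post]
    stimulus: "on"
    out: {table: strain_comparison.csv}
  - stage: power-curve
    p_grid: [2, 10, 30, 60]
    deltas: [0.5, 0.6, 0.7, 0.8]
    target: 0.8
    out: {table: power_curve.csv}
  - stage: manova
    windows: "@windows.csv"
    response: full
    terms:
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
    out: {table: manova.csv}
  - stage: dynamics
    windows: "@windows.csv"
    stimulus: "on"
    terms:
      - well
      - bio_rep
      - strain
      - stage_dpf
      - trial_index
      - "strain:stage_dpf"
    out: {table: dynamics_on.csv}
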