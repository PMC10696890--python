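# Desk-scale configuration for the numbered analysis scripts.
# Every stage derives its randomness from master_seed; reruns are
# bit-reproducible.
out_dir: results/run
master_seed: 0
n_regions: 24
cohort: AD
subject_index: 0
G_true: 2.0
g_grid: {min: 1.0, max: 3.0, step: 0.5}
trials_per_g: 2
n_calls: 20
n_trials: 2
trial_duration_s: 160.0
tr_s: 3.0
burn_in_s: 10.0
target_duration_s: 310.0
bounds_mode: 2d
shuffle_n_maps: 5
shuffle_trials_per_map: 3
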