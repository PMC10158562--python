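# Scaled-down profile: full analysis chain on a small synthetic cohort.
design:
  n_subjects_per_group: 5
  n_electrodes: 32
  n_trials: 40
min_trials: 25
n_perm_tanova: 1000
n_perm_tct: 500
k_range: [2, 3, 4, 5, 6, 7, 8, 9, 10]
out_dir: runs/demo
seed: 0
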