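# Full study-scale profile: every analysis parameter at its study-default value
# and the synthetic cohort at the emulated study size
# (4 groups x 20 subjects x 2 conditions, 128 electrodes, 512 Hz).
design:
  n_groups: 4
  n_subjects_per_group: 20
  n_trials: 60
  n_electrodes: 128
  sampling_rate: 512.0
hp_hz: 0.2
lp_hz: 30.0
artifact_threshold_uv: 100.0
min_trials: 55
rt_lo_ms: 500.0
rt_hi_ms: 2000.0
alpha_waveform: 0.01
min_consec_tf_waveform: 10
min_adjacent_electrodes: 5
alpha_tanova: 0.01
min_consec_tf_tanova: 12
n_perm_tanova: 5000
n_perm_tct: 1000
k_range: [2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20]
gev_threshold: 0.95
min_duration_tf: 12
merge_correlation: 0.95
min_presence_tf: 12
p1_window_ms: [80.0, 160.0]
fit_window1_tf: [35, 103]
fit_window2_start_tf: 100
out_dir: runs/study
seed: 0
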