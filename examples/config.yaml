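# Full-pipeline configuration for `mgsms run --config examples/config.yaml`.
# All defaults mirror the study conditions; shrink n_subjects / n_trials for
# a quick look.
outdir: run
seed: 0
n_subjects: 4
n_trials: 24
fs_eeg: 250.0
snr: 8.0
dwell_mean: 0.08
coupling_beta: 0.2
far_tp_boost: 0.08
blink_prob: 0.2
filter_lo: 1.0
filter_hi: 30.0
filter_order: 6
k: 8
n_restarts: 50
smooth_window: 0.03
write_labels: false
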