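"""Generate a small synthetic MGS session and look at what it contains.

The generator plants a known semi-Markov sequence over 8 polarity states
(A+/- ... D+/-) into 20-channel EEG, with task events and 1000 Hz gaze.
"""

import numpy as np

from mgsms import synth

cfg = synth.TaskConfig(n_subjects=1, n_trials=24, seed=7)
truth = synth.default_ground_truth()
session = synth.simulate_session(cfg, truth)
sub = session.subjects[0]

print("trial events (first 3):")
print(sub.events.head(3).to_string(index=False))
print(f"\nEEG array: {sub.eeg.shape} (channels x samples at {cfg.fs_eeg:g} Hz)")
print(f"gaze samples: {len(sub.gaze)} at {cfg.fs_gaze:g} Hz")

first = sub.planted_labels[0]
states = [first.states[s] for s, _, _ in first.segments[:8]]
print(f"planted states of trial 0 (first 8 segments): {states}")
dwell = np.mean([ln / cfg.fs_eeg for sq in sub.planted_labels for _, _, ln in sq.segments])
print(f"mean planted dwell: {dwell * 1000:.0f} ms (generator mean {truth.dwell_mean * 1000:.0f} ms)")
# Each trial is fixation (1 s) / stimulus (300 ms) / memory (1.5-2.5 s) /
# saccade (1 s); the planted chain and dwell law are the recovery targets
# for the segmentation pipeline.
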