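"""Run the complete study analysis and print the statistical battery.

This is the in-memory equivalent of `mgsms run`: simulate, preprocess,
score behavior, segment, back-fit, compute microstate parameters, and test
the brain-behavior relationships.  A moderate size (8 subjects x 60 trials)
keeps it quick; the acceptance script runs the full 17 x 120 design.
"""

import json

from mgsms import pipeline, synth

cfg = synth.TaskConfig(n_subjects=8, n_trials=60, seed=42)
truth = synth.default_ground_truth()
result = pipeline.run_study(cfg, truth)

print(f"valid trials: {int(result.behavior['valid'].sum())}/{len(result.behavior)}")
print(json.dumps(result.stats, indent=2, default=str))
# Key outputs: error_tp_correlation pools subject x target-position means of
# saccade error against TP(D+ -> D-) in the memory window (the planted
# coupling makes it positive); tp_dplus_dminus_high_vs_low_error contrasts
# that transition between high- and low-error subjects;
# condition_tp_contrasts tests the planted near/far A- -> D- difference.
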