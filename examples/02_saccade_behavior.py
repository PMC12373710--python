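"""Compute per-trial saccade outcomes and the near/far error contrast.

Saccade error is the target-to-landing distance in degrees of visual angle;
trials with blinks, broken fixation, or error > 2 dva are rejected, and the
rest are tagged low (< 0.5 dva) / mid / high (> 1.5 dva) error.
"""

import pandas as pd

from mgsms import behavior as beh
from mgsms import stats as st
from mgsms import synth

cfg = synth.TaskConfig(n_subjects=8, n_trials=48, seed=3)
truth = synth.default_ground_truth()
session = synth.simulate_session(cfg, truth, render_eeg=False)

frames = [
    beh.analyze_subject(s.gaze, s.events, cfg.center_px, cfg.px_per_deg)
    for s in session.subjects
]
outcomes = pd.concat(frames, ignore_index=True)
valid = outcomes[outcomes["valid"]]

print(f"valid trials: {len(valid)}/{len(outcomes)}")
print("\nrejection reasons:")
print(outcomes["reject_reason"].value_counts().to_string())
print("\nerror groups among valid trials:")
print(valid["error_group"].value_counts().to_string())

wide = valid.groupby(["subject", "condition"])["error_dva"].mean().unstack()
res = st.signedrank(wide["far"].to_numpy(), wide["near"].to_numpy())
print(
    f"\nmean error far {wide['far'].mean():.3f} dva vs near {wide['near'].mean():.3f} dva, "
    f"signed-rank p = {float(res.effects['p_unc'].iloc[0]):.4f}"
)
# Far (12 deg) targets draw systematically larger memory-guided saccade
# errors than near (6 deg) ones — the behavioral signature of eccentricity.
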