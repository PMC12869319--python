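"""From raw gaze samples to a per-subject sign-tracking bias.

A trial's gaze index is p(CS) - p(US): +1 means the subject looked only at
the reward-predicting cue, -1 only at the outcome location. The
sign-tracking bias is the through-origin slope of the index on the cue's
reward value (CHF), so positive values mean stronger cue attraction for
higher rewards.

Run:  python examples/02_gaze_bias.py
"""

import numpy as np
import pandas as pd

import neurotopo as nt

# --- one hand-made trial: 100 samples, 70 on the cue, 30 on the background
aoi = nt.AoiLayout(left=(100, 300, 500, 700), right=(1420, 300, 1820, 700))
samples = pd.DataFrame({
    "t_s": 2.0 + 0.002 * np.arange(100),          # third second of the cue
    "x_px": [300.0] * 70 + [960.0] * 30,
    "y_px": 500.0,
    "valid": True,
})
trial = nt.fixation_proportions(samples, aoi, cs_side="left", cs_value=2.0)
print(f"hand-made trial: p(CS)={trial.p_cs:.2f} p(US)={trial.p_us:.2f} "
      f"-> gaze index {nt.gaze_index(trial):+.2f}")

# --- a full simulated subject: 80 conditioning trials, true bias 0.15
schedule = nt.build_pavlovian_schedule(seed=3)
trials = nt.simulate_gaze_subject(beta1=0.15, noise_sd=0.1, schedule=schedule, seed=3)
fit = nt.sign_tracking_bias(trials)
print(f"simulated subject: beta1 = {fit.beta1:.3f} +/- {fit.stderr:.3f} "
      f"({fit.n_trials_used} trials) — true value 0.15")

# --- learning check: choosing the lower-valued cue >10% of the time excludes
choices = nt.build_forced_choice_schedule(seed=3).assign(chosen=lambda d: d["correct"])
choices.loc[:3, "chosen"] = np.where(choices.loc[:3, "correct"] == "first",
                                     "second", "first")   # 4 forced errors
check = nt.forced_choice_error_rate(choices)
print(f"forced choice: error rate {check.error_rate:.3f} "
      f"-> excluded = {check.excluded} (rule: strictly above 10%)")
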