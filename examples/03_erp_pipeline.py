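"""Epochs to ERP: selection, baseline, artifact rejection, averaging, GFP.

The pipeline keeps correct-rejection epochs of liked items, baseline-
corrects on the pre-onset samples, drops epochs with >30 µV sample-to-
sample jumps or >80 µV amplitudes (strict bounds: exactly 30/80 survive),
averages, and re-references to the common average.

Run:  python examples/03_erp_pipeline.py
"""

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

import neurotopo as nt

rng = np.random.default_rng(7)
n_epochs, n_e, sfreq = 40, 64, 1024.0
onset = round(0.100 * sfreq)                 # 100 ms baseline
n_tf = round(0.800 * sfreq)                  # -100..+700 ms window

# band-limited noise, as after 0.5-40 Hz filtering: smooth, ~8 µV
data = gaussian_filter1d(rng.normal(size=(n_epochs, n_e, n_tf)), sigma=8, axis=-1)
data *= 8.0 / data.std()
data[5, 10, 380:420] += 120.0 * np.hanning(40)   # one slow amplitude artifact
data[9, 20, 400] += 45.0                         # one single-sample jump
meta = pd.DataFrame({
    "trial_type": ["NoGo"] * 30 + ["Go"] * 10,
    "correct": [True] * 25 + [False] * 5 + [True] * 10,
    "liking": rng.integers(40, 100, n_epochs),
})
meta.loc[[5, 9], "liking"] = 90      # keep the artifact epochs selectable
epochs = nt.EpochSet(data, sfreq, onset, metadata=meta)

erp, report = nt.preprocess_epochs(epochs, correct_rejection=True, min_liking=60)
print(f"epochs in: {report.n_epochs_in} (correct rejections of liked items)")
print(f"kept: {report.n_epochs_kept}  "
      f"jump-rejected: {report.pct_epochs_jump_rejected:.1f}%  "
      f"amplitude-rejected: {report.pct_epochs_amplitude_rejected:.1f}%")

# each timeframe of the ERP is a scalp map; GFP summarises its strength
series = nt.gfp_series(erp)
peak = series.argmax()
print(f"ERP shape {erp.shape}; every map sums to "
      f"{abs(erp.sum(axis=0)).max():.1e} µV (common average reference)")
print(f"peak GFP {series[peak]:.2f} µV at {(peak - onset) / sfreq * 1000:.0f} ms "
      "(pure noise here, so the peak latency is arbitrary)")
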