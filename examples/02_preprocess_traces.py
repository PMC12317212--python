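"""Preprocess raw pupil traces into clean, binned trials.

Blink runs are extended by 100 ms on each side and linearly interpolated,
traces are low-pass smoothed (4 Hz, zero phase), trials with > 20% missing
samples or dilation-speed spikes are excluded, and retained trials are
baseline-corrected (mean of the 400 ms before stimulus onset) and averaged
into 150 consecutive 20-ms bins.
"""

import numpy as np

import pupilforget as pf

config = pf.SimulationConfig(n_subjects=10, n_items=40, seed=42)
_, traces, _ = pf.simulate_experiment(config)

clean, report = pf.preprocess_all(traces, pf.PreprocessConfig())

print(f"retained {report['n_retained']}/{report['n_trials']} trials; "
      f"{report['percent_removed']:.1f}% removed "
      f"({report['n_excluded_missing']} missing, "
      f"{report['n_excluded_spike']} spike)")

kept = clean.retained()
print(f"binned matrix: {kept.bins.shape} (trials x 20-ms bins)")
print("grand-average baseline-corrected pupil by 500-ms epoch (a.u.):")
grand = kept.bins.mean(axis=0)
for k in range(0, 150, 25):
    print(f"  {k * 20:5d}-{(k + 25) * 20:d} ms: {grand[k:k + 25].mean():7.2f}")
print("Positive values = dilation relative to the pre-stimulus baseline; "
      "the event-locked response builds over the 3-s test window.")
assert not np.isnan(kept.bins).any()
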