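"""Generate a synthetic directed-forgetting experiment and look at it.

Builds a small remember/forget (R/F) cued study: each subject sees every
scene once at test, half as the studied original ("Old") and half mirrored
("Lure"), with recognition responses drawn from a signal-detection model
and 1-kHz pupil traces carrying an extra late dilation on F-cued miss
trials only.
"""

import pupilforget as pf

config = pf.SimulationConfig(n_subjects=10, n_items=40, seed=42)
trials, traces, truth = pf.simulate_experiment(config)

print(f"{len(trials)} trials, traces {traces.pupil.shape} "
      f"({traces.times[0]}..{traces.times[-1]} ms)")
print("\nTrials per condition x image type:")
print(trials.groupby(["condition", "image_type"]).size().unstack())
print("\nAccuracy by condition (R-cued scenes should be remembered better):")
print(trials.groupby("condition")["accuracy"].mean().round(3))

n_missing = int((traces.pupil != traces.pupil).sum())
print(f"\n{n_missing} samples are missing (blinks) "
      f"({100 * n_missing / traces.pupil.size:.1f}% of all samples); "
      "preprocessing will repair or exclude them.")
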