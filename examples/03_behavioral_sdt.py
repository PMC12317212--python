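"""Behavioral analysis: multilevel probit model and subject-level d'.

The probit mixed model of trial-level "old" responses puts its
coefficients on the d' scale: with +/-0.5 sum coding, the image-type
coefficient estimates average sensitivity and the condition x type
interaction the d' difference between remember- and forget-cued scenes
(the directed-forgetting effect). Subject-level d' and criterion use
loglinear-corrected rates and paired t-tests.
"""

import pupilforget as pf

config = pf.SimulationConfig(n_subjects=30, n_items=40, seed=7)
trials, _ = pf.simulate_behavior(config)

summary = pf.sdt_summary(trials)
print("mean subject-level SDT indices by cue:")
print(summary.groupby("condition")[["hr_corr", "far_corr", "dprime",
                                    "criterion"]].mean().round(3))

d = pf.compare_conditions(summary, "dprime", ("R", "F"))
print(f"\ndirected-forgetting effect on d': t({d.df}) = {d.t:.2f}, "
      f"p = {d.p:.4f}, Cohen's d_z = {d.dz:.2f}")
print(f"  (mean d' R = {d.mean_a:.2f}, F = {d.mean_b:.2f})")

model = pf.fit_accuracy_glmm(trials)
print(f"\nprobit mixed model (random structure: {model.random_structure}):")
print(model.coef.round(3).to_string(index=False))
print("image_type ~ average d'; condition:image_type ~ d'(F) - d'(R).")
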