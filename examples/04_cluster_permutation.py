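"""Cluster-based permutation test on miss-trial pupil dilation.

The planned comparison: among old images the participant failed to
recognize (miss trials), does pupil dilation differ between forget-cued
(intentional forgetting) and remember-cued (incidental forgetting) scenes?
Per 20-ms bin a condition model is fit; runs of >= 10 consecutive
significant bins form clusters scored by their summed t statistics, and
each cluster mass is compared against 1000 label-shuffled experiments.
"""

import pupilforget as pf

config = pf.SimulationConfig(n_subjects=30, n_items=40, seed=21)
_, traces, _ = pf.simulate_experiment(config)
clean, _ = pf.preprocess_all(traces)

result = pf.run_contrast(clean, subset={"image_type": "Old", "accuracy": False},
                         spec="subject", n_perm=1000, seed=1)

print(f"miss-trial contrast ({result.levels[1]} vs {result.levels[0]}), "
      f"{len(result.permutation.null_max_mass)} permutations:")
if result.permutation.clusters:
    for c in result.permutation.clusters:
        lo, hi = c.time_window_ms()
        print(f"  cluster bins {c.start_bin}-{c.end_bin} ({lo}-{hi} ms), "
              f"mass = {c.mass:.1f}, corrected p = {c.p:.3f}")
    print("A significant late cluster indicates greater dilation for "
          "forget-cued than remember-cued misses — the generative model "
          "injects exactly such a difference from 1880 ms on.")
else:
    print("  no cluster of >= 10 consecutive significant bins")

# the same machinery on hit trials is a null comparison by construction
null = pf.run_contrast(clean, subset={"image_type": "Old", "accuracy": True},
                       spec="subject", n_perm=1000, seed=1)
ps = [c.p for c in null.permutation.clusters]
print(f"hit-trial contrast: {len(ps)} cluster(s)"
      + (f", smallest p = {min(ps):.3f}" if ps else " (as expected under the null)"))
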