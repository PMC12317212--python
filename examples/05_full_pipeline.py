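"""Run the whole pipeline (simulate -> preprocess -> behavior -> clusters)
from one config, writing every table, plot and a replayable manifest."""

from pathlib import Path

import pupilforget as pf

out = Path("example_run")
config = pf.PipelineConfig(
    output_dir=str(out),
    simulation=pf.SimulationConfig(n_subjects=20, n_items=40, seed=11),
    n_permutations=500,
    seed=11,
)
result = pf.run_pipeline(config)

print("cluster table:")
print(result["cluster_table"].to_string(index=False))
d = result["behavior"]["dprime_test"]
print(f"\nd' R vs F: t({d.df}) = {d.t:.2f}, p = {d.p:.4f}, d_z = {d.dz:.2f}")
print(f"exclusions: {result['exclusion_report']['percent_removed']:.1f}% of trials")
print(f"\noutputs in {out}/: " + ", ".join(sorted(p.name for p in out.iterdir())))
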