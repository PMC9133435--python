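"""Assess whether the recovered component groups are statistically separable.

Decomposes every trial of a small session, pools per-component features
(median frequency, spectral centroid, log energy) and computes the Gaussian
Bhattacharyya distance between the low and high groups, with rank-sum tests
on the median frequencies.
"""

import pandas as pd

from semgspec import assess, pipeline, synthetic

cfg = pipeline.PipelineConfig()
cfg.synthesis = synthetic.SessionConfig(subjects=2, trials_per_subject=2, seed=3)
cfg.decomposition.n_components = 2
cfg.decomposition.seed = 3

result = pipeline.run_pipeline(cfg, "simulate")

print("per-trial decompositions:")
for r in result.trials:
    print(f"  {r.trial_id}: n={r.n}, VAF={r.vaf_percent:.2f}%, "
          f"energy crossover at {r.crossover_s} s")

report = result.separability
print(f"\nBhattacharyya distance between component groups: {report.bdist:.2f}")
print(f"highly separable (Bdist > {report.threshold}): {report.highly_separable}")
print(f"low-vs-high median-frequency rank-sum p = {report.low_vs_high_p:.2e}")
print("\ngroup median-frequency summary:")
print(report.group_summary.to_string(index=False))
print("\nA Bdist far above 3.5 means the two spectral components occupy "
      "essentially non-overlapping regions of feature space (Bayes error ~2% "
      "or less), validating the two-component description.")
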