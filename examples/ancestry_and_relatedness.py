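"""Ancestry mixture estimation and relatedness pruning.

Combines the cohort with a five-population reference panel, runs PCA on
the merged genotypes (projecting held-out samples instead would shrink
them toward the origin and make them look admixed), solves for ancestry
proportions under the Mahalanobis metric, and applies the >= 90% European
retention rule. Then demonstrates pi-hat relatedness pruning on a
duplicated sample.
"""

import numpy as np
import pandas as pd

import regeqtl as rq

config = rq.SimConfig(n_cases=30, n_controls=20, n_variants=4000, n_genes=5, seed=4)
panel = rq.simulate_reference_panel(config, n_per_pop=40)
cohort = rq.simulate_cohort(config)  # same base frequencies as panel's EUR

merged = cohort.concat_samples(panel)
scores, _ = rq.compute_pca(merged, k=10)
cohort_scores = scores.loc[cohort.samples.index[:5]]
panel_scores = scores.loc[panel.samples.index]

estimates, retained = rq.estimate_ancestry(
    cohort_scores, panel_scores, panel.samples["population"]
)
print("ancestry proportions of five cohort samples (EUR cohort):")
for est in estimates:
    w = ", ".join(f"{k}={v:.2f}" for k, v in est.proportions.items() if v > 0.01)
    print(f"  {est.sample}: {w}")
print(f"retained by the >=90% EUR rule: {len(retained)} / 5")

# relatedness: duplicate one sample and prune at pi-hat > 0.12
dup = cohort.subset_samples(list(cohort.samples.index[:6]))
dup.dosage[5] = dup.dosage[0]
afs = np.nanmean(cohort.dosage, axis=0) / 2
kept, flagged = rq.remove_relateds(dup, pihat_threshold=0.12, seed=0, freqs=afs)
worst = max(flagged, key=lambda e: e.pihat)
print(f"\nmost related pair: {worst.sample_a}/{worst.sample_b} "
      f"pi-hat = {worst.pihat:.2f}; samples kept: {len(kept)} / 6")
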