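"""QC'd additive logistic association with LD clumping and index FDR.

Simulates a 986/415 cohort with one planted risk eQTL (OR 1.67 at MAF 0.3)
among 149 null eQTLs, masks low-quality calls (DP < 20 or GQ <= 30), drops
variants failing MAF > 0.05 / call-rate filters, fits the additive model
with sex and 10 ancestry PCs, and reports the inflation factor and the
FDR-significant index eQTLs. The planted variant should top the list with
an odds ratio near 1.67.
"""

import numpy as np

import regeqtl as rq

config = rq.SimConfig(
    n_cases=986, n_controls=415, n_variants=150, n_genes=30,
    planted_risk=(
        [rq.PlantedEffect(0, 1.67, "G0000", 0.5)]
        + [rq.PlantedEffect(1 + i, 1.0, f"G{1 + i % 29:04d}", 0.5)
           for i in range(149)]
    ),
    maf_range=(0.3, 0.3), seed=1,
    contig_lengths={"chr1": 60_000_000, "chr2": 60_000_000},
)
cohort = rq.simulate_cohort(config)
risk_id = cohort.variants["variant_id"].iloc[0]

records, masked = rq.variant_qc(cohort)
passed = {r.variant_id for r in records if r.passed}
print(f"variants passing QC: {len(passed)} / {len(records)}")

tested = masked.subset_variants(
    np.flatnonzero(masked.variants["variant_id"].isin(passed))
)
results = rq.association_scan(
    tested, covariate_cols=["sex"] + [f"PC{i}" for i in range(1, 11)]
)
lam = rq.genomic_inflation(results["p"].to_numpy()).lambda_gc
print(f"genomic inflation factor: {lam:.3f} "
      "(centers on 1 without stratification; noisy at only 150 tests)")

clumped = rq.ld_clump(results, tested, r2_threshold=0.6, fdr_threshold=0.1)
sig = clumped.query("significant")
print(f"\nindex eQTLs: {int(clumped['is_index'].sum())}; significant at FDR<0.1: {len(sig)}")
print(sig[["variant_id", "or", "ci_lo", "ci_hi", "p", "q"]].round(4).to_string(index=False))
print(f"\nplanted risk variant was {risk_id}")
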