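"""End-to-end synthetic pipeline run with a reported survival funnel.

Glues the stages together on generated inputs: build the regulatory eQTL
test set, QC and associate, clump and FDR-select index eQTLs, replicate
against an independent case cohort and aggregate control frequencies, and
integrate to gene level. Returns every intermediate table plus a funnel of
candidate counts (significant eQTLs -> accessible -> regulatory -> post-QC
-> index eQTLs -> replicated loci -> selected genes), which is
deterministic for a fixed config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association as assoc
from . import genes as gene_mod
from . import regulatory as reg
from . import replication as repl
from .synthetic import BRAIN_REGIONS, SimConfig, simulate_cohort, \
    simulate_eqtl_catalog, simulate_regulatory_tracks, \
    simulate_replication_frequencies

__all__ = ["PipelineResult", "run_pipeline", "demo_config"]


def demo_config(seed: int = 20240917) -> SimConfig:
    """The shipped demonstration study: a small cohort with planted truth.

    One gene (G0000) carries three independent risk eQTLs (OR 1.8), a second
    (G0001) two protective ones (OR 1.67 with negative expression betas), a
    third one risk eQTL, plus 80 null eQTLs (OR 1.0) spread over decoy genes;
    90% of planted eQTLs fall in accessible chromatin and 90% in loop
    anchors, so the funnel loses candidates at each regulatory stage.
    """
    from .synthetic import PlantedEffect

    planted = [
        PlantedEffect(0, 1.8, "G0000", 0.6),
        PlantedEffect(1, 1.8, "G0000", 0.55),
        PlantedEffect(2, 1.8, "G0000", 0.5),
        PlantedEffect(40, 1.67, "G0001", -0.5),
        PlantedEffect(41, 1.67, "G0001", -0.45),
        PlantedEffect(80, 1.5, "G0002", 0.4),
    ]
    planted += [
        PlantedEffect(100 + i, 1.0, f"G{3 + i % 25:04d}", 0.5 if i % 2 else -0.5)
        for i in range(80)
    ]
    return SimConfig(
        n_cases=300,
        n_controls=150,
        n_variants=400,
        n_genes=30,
        planted_risk=planted,
        peak_overlap_frac=0.9,
        loop_overlap_frac=0.9,
        seed=seed,
        contig_lengths={"chr1": 20_000_000, "chr2": 20_000_000},
    )


@dataclass
class PipelineResult:
    funnel: reg.FunnelReport
    lambda_gc: float
    assoc_results: pd.DataFrame
    qc_records: list
    replication: pd.DataFrame
    gene_results: pd.DataFrame
    config: SimConfig = None

    def funnel_dict(self) -> dict[str, int]:
        return self.funnel.to_dict()


def run_pipeline(
    config: SimConfig,
    covariate_cols: list[str] | None = None,
    bf_params: gene_mod.BayesFactorParams | None = None,
    replication_alpha: float = 0.05,
) -> PipelineResult:
    """Run test-set construction, association, replication and gene scoring.

    Relatedness pruning and ancestry filtering are not re-applied here: the
    generator emits an unrelated single-ancestry cohort by construction, and
    the pairwise IBD estimator is quadratic in samples. Those gates are
    exercised on their own fixtures.
    """
    if covariate_cols is None:
        covariate_cols = ["sex"] + [f"PC{i}" for i in range(1, 11)]
    bf_params = bf_params or gene_mod.BayesFactorParams()

    cohort = simulate_cohort(config)
    catalog = simulate_eqtl_catalog(config)
    peaks, loops = simulate_regulatory_tracks(config, cohort)

    sig_rows, candidates = reg.filter_significant_eqtls(
        catalog, known_regions=BRAIN_REGIONS
    )
    accessibility = reg.accessibility_union(peaks.values())
    regulatory = reg.build_regulatory_regions(peaks.values(), loops)
    selected, funnel = reg.select_regulatory_eqtls(
        candidates, regulatory, accessibility=accessibility
    )

    qc_records, masked = assoc.variant_qc(cohort, test_set=selected)
    passing = {r.variant_id for r in qc_records if r.passed}
    funnel.post_qc = len(passing)
    cols = np.flatnonzero(masked.variants["variant_id"].isin(passing))
    tested = masked.subset_variants(cols)

    results = assoc.association_scan(tested, covariate_cols=covariate_cols)
    lam = (
        assoc.genomic_inflation(results["p"].to_numpy()).lambda_gc
        if len(results)
        else float("nan")
    )
    clumped = assoc.ld_clump(results, tested)
    indices = clumped[clumped["is_index"]]
    funnel.index_eqtls = len(indices)
    sig_indices = indices[indices["significant"]]

    variant_idx = {
        vid: j for j, vid in enumerate(cohort.variants["variant_id"])
    }
    rep_cols = np.array(
        [variant_idx[v] for v in clumped["variant_id"]], dtype=int
    )
    array_cases, aggregate = simulate_replication_frequencies(
        config, variant_indices=rep_cols
    )
    decision = repl.cross_cohort_confirm(
        sig_indices[["variant_id", "beta"]],
        array_cases,
        aggregate,
        alpha=replication_alpha,
    )
    funnel.replicated_loci = int(decision["retained"].sum()) if len(decision) else 0

    # gene-level integration: WGS stats from the scan; array-cohort stats
    # from the allelic contrast of array cases vs aggregate controls
    wgs_stats = clumped.set_index("variant_id")[["z", "se"]]
    arr_rows = []
    agg_by_id = {r.variant_id: r for r in aggregate.itertuples()}
    for r in array_cases.itertuples():
        ctr = agg_by_id[r.variant_id]
        c = repl.af_contrast(
            repl.CohortFrequency(r.variant_id, int(r.ac), int(r.an)),
            repl.CohortFrequency(ctr.variant_id, int(ctr.ac), int(ctr.an)),
        )
        log_or = np.log(c.or_)
        se = (np.log(c.ci95[1]) - np.log(c.ci95[0])) / (2 * 1.96)
        arr_rows.append(
            {"variant_id": r.variant_id, "z": log_or / se, "se": se}
        )
    array_stats = pd.DataFrame(arr_rows).set_index("variant_id")

    tested_rows = sig_rows[sig_rows["variant_id"].isin(passing)]
    genes_wgs = gene_mod.gene_scan(
        tested_rows, wgs_stats, bf_params, seed=config.seed
    )
    genes_array = gene_mod.gene_scan(
        tested_rows, array_stats, bf_params, seed=config.seed + 1
    )
    annotation = pd.DataFrame(
        {"gene": config.gene_ids, "protein_coding": True}
    )
    gene_table = (
        gene_mod.select_genes(genes_wgs, genes_array, annotation)
        if len(genes_wgs) and len(genes_array)
        else pd.DataFrame(columns=["gene", "selected"])
    )
    funnel.selected_genes = (
        int(gene_table["selected"].sum()) if len(gene_table) else 0
    )

    return PipelineResult(
        funnel=funnel,
        lambda_gc=lam,
        assoc_results=clumped,
        qc_records=qc_records,
        replication=decision,
        gene_results=gene_table,
        config=config,
    )
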