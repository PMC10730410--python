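"""Synthetic cohort, catalog, track, expression and EHR generators.

Every input the pipeline consumes can be generated here with planted,
parameterized structure, so each downstream stage has a recoverable ground
truth: risk variants with known odds ratios, eQTLs with known effect signs,
regulatory tracks with a controllable fraction of eQTLs covered, expression
shifts, and diagnosis prevalences.

Default magnitudes mirror a typical suicide-death WGS cohort: 986 cases and
415 controls, planted odds ratios near 1.67 at common minor-allele
frequencies, 13 brain regions in the eQTL catalog, and diagnostic-category
prevalences matching the published clinical characteristics of such cohorts
(e.g. pain 69.5%, bipolar disorder 42.3%).

All generators draw from `numpy.random.default_rng` streams derived
deterministically from ``SimConfig.seed`` plus a per-generator tag, so a
fixed config yields byte-identical outputs and individual inputs can be
regenerated independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .intervals import LoopRecord, RegionSet
from .io import GenotypeDataset

__all__ = [
    "BRAIN_REGIONS",
    "DX_CATEGORIES",
    "PlantedEffect",
    "SimConfig",
    "simulate_cohort",
    "simulate_eqtl_catalog",
    "simulate_regulatory_tracks",
    "simulate_expression",
    "simulate_ehr",
    "simulate_reference_panel",
    "simulate_replication_frequencies",
]

BRAIN_REGIONS: tuple[str, ...] = (
    "amygdala",
    "anterior_cingulate_cortex",
    "caudate",
    "cerebellar_hemisphere",
    "cerebellum",
    "cortex",
    "frontal_cortex",
    "hippocampus",
    "hypothalamus",
    "nucleus_accumbens",
    "pituitary",
    "putamen",
    "substantia_nigra",
)

# Diagnostic categories with prevalences observed in the WGS suicide cohort.
DX_CATEGORIES: dict[str, float] = {
    "alcohol_related": 0.287,
    "asthma": 0.164,
    "anxiety": 0.526,
    "bipolar_disorder": 0.423,
    "broad_depression": 0.633,
    "neurodegenerative": 0.136,
    "drug_related": 0.394,
    "eating_related": 0.022,
    "mdd": 0.391,
    "obesity": 0.205,
    "opioid_misuse": 0.182,
    "pain": 0.695,
    "schizophrenia": 0.063,
    "sleep_related": 0.294,
    "suicidal_ideation": 0.298,
}

PEAK_ASSAYS: tuple[str, ...] = (
    "H2AFZ", "H3F3A", "H3K27ac", "H3K27me3", "H3K36me3", "H3K4me1",
    "H3K4me2", "H3K4me3", "H3K79me2", "H3K9ac", "H3K9me2", "H3K9me3",
    "H4K20me1", "ATAC", "DNase",
)


@dataclass(frozen=True)
class PlantedEffect:
    """A risk eQTL: variant column index, trait odds ratio, target gene, eQTL beta."""

    variant: int
    odds_ratio: float
    gene: str
    eqtl_beta: float

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError(f"odds ratio must be > 0, got {self.odds_ratio}")


@dataclass
class SimConfig:
    """Parameters of one synthetic study."""

    n_cases: int = 986
    n_controls: int = 415
    n_variants: int = 1000
    n_genes: int = 50
    populations: list[tuple[str, float]] = field(
        default_factory=lambda: [("EUR", 0.0)]
    )
    planted_risk: list[PlantedEffect] = field(default_factory=list)
    maf_range: tuple[float, float] = (0.05, 0.5)
    peak_overlap_frac: float = 1.0
    loop_overlap_frac: float = 1.0
    de_effects: list[tuple[str, str, float]] = field(default_factory=list)
    dx_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DX_CATEGORIES)
    )
    seed: int = 0
    # plumbing knobs
    contig_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 50_000_000, "chr2": 50_000_000}
    )
    n_regions: int = 13
    n_decoy_pairs: int | None = None  # defaults to n_genes
    dp_low_frac: float = 0.02  # fraction of calls with DP < 20
    gq_low_frac: float = 0.02  # fraction of calls with GQ <= 30
    n_studies: int = 1

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_variants", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("peak_overlap_frac", "loop_overlap_frac",
                     "dp_low_frac", "gq_low_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 0.5):
            raise ValueError(f"maf_range must be within [0, 0.5], got {self.maf_range}")
        for p in self.dx_prevalence.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence outside [0,1]: {p}")
        self.planted_risk = [
            e if isinstance(e, PlantedEffect) else PlantedEffect(*e)
            for e in self.planted_risk
        ]
        for e in self.planted_risk:
            if not 0 <= e.variant < self.n_variants:
                raise ValueError(f"planted variant index {e.variant} out of range")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-generator stream: seed + CRC32 of the tag."""
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @property
    def case_fraction(self) -> float:
        return self.n_cases / (self.n_cases + self.n_controls)


def _base_afs(config: SimConfig) -> np.ndarray:
    rng = config.rng("afs")
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.n_variants)


def _population_afs(base: np.ndarray, fst: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols drift of base allele frequencies at divergence fst."""
    if fst <= 0:
        return base.copy()
    a = base * (1 - fst) / fst
    b = (1 - base) * (1 - fst) / fst
    return np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)


def _variant_table(config: SimConfig) -> pd.DataFrame:
    rng = config.rng("positions")
    contigs = list(config.contig_lengths)
    # spread variants across contigs proportionally to length
    lens = np.array([config.contig_lengths[c] for c in contigs], dtype=float)
    counts = np.floor(lens / lens.sum() * config.n_variants).astype(int)
    counts[0] += config.n_variants - counts.sum()
    rows = []
    bases = np.array(list("ACGT"))
    for contig, k in zip(contigs, counts):
        pos = np.sort(
            rng.choice(config.contig_lengths[contig] - 1, size=k, replace=False) + 1
        )
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append((contig, int(p), bases[ref], bases[alt]))
    df = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    df["biallelic"] = True
    df["variant_id"] = [
        f"{c}:{p}:{r}:{a}" for c, p, r, a in zip(df.contig, df.pos, df.ref, df.alt)
    ]
    return df


def _draw_quality(rng: np.random.Generator, shape: tuple[int, int],
                  low_frac: float, kind: str) -> np.ndarray:
    """Per-call DP or GQ with a configured fraction in the failing range."""
    low = rng.random(shape) < low_frac
    if kind == "dp":
        vals = rng.integers(20, 61, size=shape)
        vals[low] = rng.integers(5, 20, size=int(low.sum()))
    else:  # gq, failing means <= 30
        vals = rng.integers(31, 100, size=shape)
        vals[low] = rng.integers(1, 31, size=int(low.sum()))
    return vals.astype(np.int64)


def simulate_cohort(config: SimConfig) -> GenotypeDataset:
    """Simulate a case/control WGS cohort with planted additive risk effects.

    Genotypes are two binomial allele draws at the population allele
    frequency; case status comes from a logistic model whose intercept is
    calibrated to the configured case fraction and whose log-odds include the
    planted per-allele effects. Because the analysis model is also logistic,
    downstream odds-ratio estimates are unbiased under case/control sampling.
    """
    rng = config.rng("cohort")
    variants = _variant_table(config)
    base = _base_afs(config)
    label, fst = config.populations[0]
    afs = _population_afs(base, fst, config.rng("pop0"))

    n_needed = config.n_cases + config.n_controls
    betas = np.zeros(config.n_variants)
    for e in config.planted_risk:
        betas[e.variant] += np.log(e.odds_ratio)
    # intercept centred so the expected case probability is the case fraction
    b0 = logit(config.case_fraction) - float(betas @ (2 * afs))

    got_case: list[np.ndarray] = []
    got_ctrl: list[np.ndarray] = []
    n_case = n_ctrl = 0
    while n_case < config.n_cases or n_ctrl < config.n_controls:
        batch = max(2 * n_needed, 500)
        g = rng.binomial(2, afs, size=(batch, config.n_variants)).astype(np.int8)
        p_case = expit(b0 + g @ betas)
        status = rng.random(batch) < p_case
        if n_case < config.n_cases:
            got_case.append(g[status][: config.n_cases - n_case])
            n_case += len(got_case[-1])
        if n_ctrl < config.n_controls:
            got_ctrl.append(g[~status][: config.n_controls - n_ctrl])
            n_ctrl += len(got_ctrl[-1])
    dosage = np.vstack(got_case + got_ctrl).astype(float)

    phenotype = np.r_[np.ones(config.n_cases), np.zeros(config.n_controls)]
    meta = pd.DataFrame(
        {
            "phenotype": phenotype.astype(int),
            "sex": rng.integers(0, 2, size=n_needed),
            "age": np.clip(rng.normal(32.1, 13.4, size=n_needed), 18, 90).round(1),
        },
        index=pd.Index([f"S{i:05d}" for i in range(n_needed)], name="sample"),
    )
    for k in range(10):
        meta[f"PC{k + 1}"] = rng.normal(0, 0.01, size=n_needed)

    qshape = (n_needed, config.n_variants)
    dp = _draw_quality(config.rng("dp"), qshape, config.dp_low_frac, "dp")
    gq = _draw_quality(config.rng("gq"), qshape, config.gq_low_frac, "gq")
    return GenotypeDataset(samples=meta, variants=variants, dosage=dosage,
                           dp=dp, gq=gq)


def simulate_eqtl_catalog(config: SimConfig) -> pd.DataFrame:
    """Per-(variant, gene, region) eQTL summary rows with beta, SE and FDR.

    Planted pairs with non-zero beta are significant (FDR < 0.05) in at least
    one of the brain regions; planted pairs whose beta is zero draw a null
    FDR ~ Uniform(0,1); decoy pairs draw FDR ~ Uniform(0.05, 1) so they never
    enter the significant set by construction.
    """
    if config.n_regions < 1:
        raise ValueError("need at least one brain region")
    rng = config.rng("catalog")
    variants = _variant_table(config)
    regions = list(BRAIN_REGIONS[: config.n_regions])
    genes = config.gene_ids

    pairs: list[tuple[int, str, float, str]] = []  # (variant idx, gene, beta, kind)
    planted_set = set()
    for e in config.planted_risk:
        pairs.append((e.variant, e.gene, e.eqtl_beta, "planted"))
        planted_set.add((e.variant, e.gene))
    n_decoys = config.n_decoy_pairs if config.n_decoy_pairs is not None else config.n_genes
    while len(pairs) < len(config.planted_risk) + n_decoys:
        v = int(rng.integers(config.n_variants))
        g = genes[int(rng.integers(config.n_genes))]
        if (v, g) in planted_set:
            continue
        planted_set.add((v, g))
        pairs.append((v, g, float(rng.normal(0, 0.1)), "decoy"))

    rows = []
    for v, g, beta, kind in pairs:
        vr = variants.iloc[v]
        if kind == "planted" and beta != 0:
            sig = rng.random(len(regions)) < 0.5
            sig[int(rng.integers(len(regions)))] = True
            fdrs = np.where(
                sig,
                rng.uniform(0, 0.05, size=len(regions)),
                rng.uniform(0.05, 1, size=len(regions)),
            )
        elif kind == "planted":  # zeroed effect: null calibration
            fdrs = rng.uniform(0, 1, size=len(regions))
        else:
            fdrs = rng.uniform(0.05, 1, size=len(regions))
        for region, fdr in zip(regions, fdrs):
            scale = rng.uniform(0.8, 1.2)
            rows.append(
                {
                    "variant_id": vr.variant_id,
                    "contig": vr.contig,
                    "pos": int(vr.pos),
                    "ref": vr.ref,
                    "alt": vr.alt,
                    "gene": g,
                    "region": region,
                    "beta": beta * scale if beta != 0 else float(rng.normal(0, 0.05)),
                    "se": float(rng.uniform(0.05, 0.15)),
                    "fdr": float(fdr),
                }
            )
    return pd.DataFrame(rows)


def simulate_regulatory_tracks(
    config: SimConfig, genotypes: GenotypeDataset
) -> tuple[dict[str, RegionSet], list[LoopRecord]]:
    """Peak sets per assay and Hi-C loops with controlled eQTL coverage.

    Independently of background peaks/loops, each planted eQTL position is
    covered by at least one peak with probability ``peak_overlap_frac`` and
    by a loop anchor with probability ``loop_overlap_frac``; joint survival
    of the regulatory intersection is therefore their product.
    """
    rng = config.rng("tracks")
    variants = genotypes.variants
    peak_ivs: dict[str, list[tuple[str, int, int]]] = {a: [] for a in PEAK_ASSAYS}
    loops: list[LoopRecord] = []

    # background peaks well away from variant positions are not guaranteed to
    # avoid them; coverage of planted eQTLs is driven by the targeted draws.
    for assay in PEAK_ASSAYS:
        for contig, length in config.contig_lengths.items():
            n_bg = max(1, length // 2_000_000)
            starts = rng.integers(0, length - 1000, size=n_bg)
            widths = rng.integers(200, 1000, size=n_bg)
            peak_ivs[assay].extend(
                (contig, int(s), int(s + w)) for s, w in zip(starts, widths)
            )
    for contig, length in config.contig_lengths.items():
        for _ in range(max(1, length // 5_000_000)):
            a1 = int(rng.integers(0, length - 20_000))
            a2 = int(rng.integers(0, length - 20_000))
            loops.append(
                LoopRecord(contig, a1, a1 + 10_000, contig, a2, a2 + 10_000, "brain")
            )

    planted_vars = sorted({e.variant for e in config.planted_risk})
    for v in planted_vars:
        row = variants.iloc[v]
        pos0 = int(row.pos) - 1
        if rng.random() < config.peak_overlap_frac:
            assay = PEAK_ASSAYS[int(rng.integers(len(PEAK_ASSAYS)))]
            w = int(rng.integers(200, 1000))
            off = int(rng.integers(0, w))
            start = max(0, pos0 - off)
            peak_ivs[assay].append((row.contig, start, start + w))
        if rng.random() < config.loop_overlap_frac:
            w = int(rng.integers(5_000, 10_000))
            off = int(rng.integers(0, w))
            start = max(0, pos0 - off)
            far = int(rng.integers(0, config.contig_lengths[row.contig] - 10_000))
            loops.append(
                LoopRecord(row.contig, start, start + w,
                           row.contig, far, far + 8_000, "brain")
            )

    peaks = {
        assay: RegionSet.from_intervals(ivs, name=assay)
        for assay, ivs in peak_ivs.items()
    }
    return peaks, loops


def simulate_expression(
    config: SimConfig, genotypes: GenotypeDataset
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes x samples expression with eQTL, group-shift and covariate effects.

    Returns ``(expression, metadata)``. Expression is baseline + eQTL beta x
    dosage + configured group shifts + small sex/age/study effects + unit
    Gaussian noise. Metadata carries group, sex, age and study labels.
    """
    rng = config.rng("expression")
    genes = config.gene_ids
    n = genotypes.n_samples
    meta = pd.DataFrame(
        {
            "group": np.where(genotypes.samples["phenotype"] == 1, "case", "control"),
            "sex": genotypes.samples["sex"].to_numpy(),
            "age": genotypes.samples["age"].to_numpy(),
            "study": [
                f"ST{(i % config.n_studies) + 1}" for i in range(n)
            ],
        },
        index=genotypes.samples.index,
    )

    baseline = rng.normal(5, 1, size=config.n_genes)
    expr = np.tile(baseline[:, None], (1, n)) + rng.normal(
        0, 1, size=(config.n_genes, n)
    )
    gene_index = {g: i for i, g in enumerate(genes)}
    for e in config.planted_risk:
        if e.gene not in gene_index:
            raise ValueError(f"planted gene {e.gene} not among configured genes")
        if e.variant >= genotypes.n_variants:
            raise ValueError(
                f"eQTL-driven gene {e.gene} references variant {e.variant} "
                "missing from genotypes"
            )
        dose = genotypes.dosage[:, e.variant]
        expr[gene_index[e.gene]] += e.eqtl_beta * np.nan_to_num(dose)
    for gene, group, shift in config.de_effects:
        if gene not in gene_index:
            raise ValueError(f"DE effect for unknown gene {gene}")
        mask = (meta["group"] == group).to_numpy()
        expr[gene_index[gene], mask] += shift
    expr += 0.1 * meta["sex"].to_numpy()[None, :]
    expr += 0.01 * (meta["age"].to_numpy()[None, :] - 40)
    study_fx = rng.normal(0, 0.2, size=config.n_studies)
    study_idx = np.array([int(s[2:]) - 1 for s in meta["study"]])
    expr += study_fx[study_idx][None, :]

    return pd.DataFrame(expr, index=genes, columns=meta.index), meta


def simulate_ehr(
    config: SimConfig,
    samples: pd.DataFrame,
    carrier_status: pd.Series | None = None,
    carrier_effects: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-sample binary diagnosis flags at the configured prevalences.

    ``carrier_effects`` maps category -> odds ratio applied on the logit
    scale for samples flagged in ``carrier_status``, letting tests plant a
    recoverable carrier/diagnosis contrast.
    """
    rng = config.rng("ehr")
    n = len(samples)
    out = pd.DataFrame(index=samples.index)
    carrier = (
        carrier_status.reindex(samples.index).fillna(False).to_numpy(dtype=bool)
        if carrier_status is not None
        else np.zeros(n, dtype=bool)
    )
    for cat, prev in config.dx_prevalence.items():
        if not 0.0 <= prev <= 1.0:
            raise ValueError(f"prevalence outside [0,1] for {cat}: {prev}")
        if prev in (0.0, 1.0):
            p = np.full(n, prev)
        else:
            shift = np.zeros(n)
            if carrier_effects and cat in carrier_effects:
                or_ = carrier_effects[cat]
                if or_ <= 0:
                    raise ValueError(f"carrier odds ratio must be > 0 for {cat}")
                shift[carrier] = np.log(or_)
            p = expit(logit(prev) + shift)
        out[cat] = (rng.random(n) < p).astype(int)
    if "age" in samples:
        out["age"] = samples["age"]
    if "sex" in samples:
        out["sex"] = samples["sex"]
    return out


def simulate_reference_panel(
    config: SimConfig, n_per_pop: int = 50,
    labels: tuple[str, ...] = ("EUR", "AFR", "EAS", "AMR", "SAS"),
    fst: float = 0.1,
) -> GenotypeDataset:
    """Reference genotypes for 5 continental populations (ancestry panel).

    The first label drifts with the cohort's own population parameters so
    cohort samples project near its centroid; the rest drift independently
    at divergence ``fst``.
    """
    base = _base_afs(config)
    variants = _variant_table(config)
    rng = config.rng("panel")
    dosages, pops = [], []
    for i, lab in enumerate(labels):
        if i == 0:
            afs = _population_afs(base, config.populations[0][1], config.rng("pop0"))
        else:
            afs = _population_afs(base, fst, config.rng(f"panel_pop{i}"))
        g = rng.binomial(2, afs, size=(n_per_pop, config.n_variants))
        dosages.append(g)
        pops.extend([lab] * n_per_pop)
    meta = pd.DataFrame(
        {"population": pops},
        index=pd.Index(
            [f"REF{i:05d}" for i in range(len(pops))], name="sample"
        ),
    )
    return GenotypeDataset(
        samples=meta, variants=variants,
        dosage=np.vstack(dosages).astype(float),
    )


def _case_shifted_af(af: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Allele frequency among cases under a per-allele log-odds effect."""
    num = af * np.exp(beta)
    return num / (1 - af + num)


def simulate_replication_frequencies(
    config: SimConfig,
    n_array_cases: int = 4657,
    aggregate_an: int = 152_312,
    variant_indices: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Array-cohort case ACs and aggregate-database control ACs.

    Emulates replication against an independent genotyping-array case cohort
    plus allele frequencies aggregated over reference genomes (AC/AN/AF per
    variant, no individual genotypes). Planted risk effects shift the case
    allele frequency on the logit scale.
    """
    rng = config.rng("replication")
    variants = _variant_table(config)
    base = _base_afs(config)
    betas = np.zeros(config.n_variants)
    for e in config.planted_risk:
        betas[e.variant] += np.log(e.odds_ratio)
    idx = (
        np.arange(config.n_variants)
        if variant_indices is None
        else np.asarray(variant_indices)
    )
    af_case = _case_shifted_af(base[idx], betas[idx])
    case_an = 2 * n_array_cases
    case_ac = rng.binomial(case_an, af_case)
    ctrl_ac = rng.binomial(aggregate_an, base[idx])
    ids = variants["variant_id"].to_numpy()[idx]
    cases = pd.DataFrame(
        {"variant_id": ids, "ac": case_ac, "an": case_an,
         "af": case_ac / case_an}
    )
    controls = pd.DataFrame(
        {"variant_id": ids, "ac": ctrl_ac, "an": aggregate_an,
         "af": ctrl_ac / aggregate_an, "population": "NFE-NN"}
    )
    return cases, controls
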