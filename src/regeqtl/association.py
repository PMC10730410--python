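"""Per-variant QC, additive logistic association, inflation, clumping, FDR.

The association model is an unconditional logistic regression of case
status on alt-allele dosage (additive coding) plus sex and ancestry PCs,
with Wald tests. Per-call quality masking (DP >= 20 kept, GQ > 30 kept)
happens before call-rate and MAF filters; thresholds follow the printed
inequalities strictly: MAF > 0.05, missing fraction > 0.1 excluded,
r^2 >= 0.6 clump membership, index FDR < 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .io import GenotypeDataset

__all__ = [
    "VariantQCRecord",
    "AssocResult",
    "InflationStat",
    "apply_call_mask",
    "variant_qc",
    "fit_additive_logistic",
    "association_scan",
    "genomic_inflation",
    "bh_fdr",
    "pairwise_r2",
    "ld_clump",
]


@dataclass(frozen=True)
class VariantQCRecord:
    variant_id: str
    maf: float
    call_rate: float
    biallelic: bool
    passed: bool
    reasons: tuple[str, ...] = ()


@dataclass
class AssocResult:
    """One variant's additive logistic association summary."""

    variant_id: str
    beta: float
    se: float
    z: float
    p: float
    converged: bool = True
    separation: bool = False
    clump_id: int = -1
    is_index: bool = False
    q: float = float("nan")

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.beta - 1.96 * self.se)),
            float(np.exp(self.beta + 1.96 * self.se)),
        )


@dataclass(frozen=True)
class InflationStat:
    """Genomic inflation factor: median association chi^2 over the null median."""

    lambda_gc: float


def apply_call_mask(
    genotypes: GenotypeDataset, min_dp: int = 20, min_gq: int = 30
) -> GenotypeDataset:
    """Mask calls failing DP >= min_dp or GQ > min_gq to missing.

    When DP/GQ are absent the dataset passes through unchanged with a
    warning (quality-naive mode).
    """
    if genotypes.dp is None or genotypes.gq is None:
        warnings.warn("no per-call DP/GQ; quality masking skipped")
        return genotypes
    bad = (genotypes.dp < min_dp) | (genotypes.gq <= min_gq)
    dosage = genotypes.dosage.copy()
    dosage[bad] = np.nan
    return GenotypeDataset(
        samples=genotypes.samples,
        variants=genotypes.variants,
        dosage=dosage,
        dp=genotypes.dp,
        gq=genotypes.gq,
    )


def variant_qc(
    genotypes: GenotypeDataset,
    test_set: pd.DataFrame | None = None,
    maf_threshold: float = 0.05,
    max_missing: float = 0.1,
    min_dp: int = 20,
    min_gq: int = 30,
) -> tuple[list[VariantQCRecord], GenotypeDataset]:
    """Quality-mask calls, then filter variants on biallelic/MAF/call rate.

    Failure rules (all strict per the stated inequalities): non-biallelic;
    MAF <= 0.05; missing fraction > 0.1 after masking. Returns the records
    and the masked dataset restricted to test-set variants (when given).
    """
    masked = apply_call_mask(genotypes, min_dp=min_dp, min_gq=min_gq)
    if test_set is not None:
        wanted = set(test_set["variant_id"])
        cols = np.flatnonzero(masked.variants["variant_id"].isin(wanted))
        masked = masked.subset_variants(cols)
    records = []
    n = masked.n_samples
    for j, row in enumerate(masked.variants.itertuples()):
        d = masked.dosage[:, j]
        ok = ~np.isnan(d)
        call_rate = ok.sum() / n
        af = d[ok].mean() / 2 if ok.any() else np.nan
        maf = min(af, 1 - af) if np.isfinite(af) else np.nan
        reasons = []
        if not bool(row.biallelic):
            reasons.append("non_biallelic")
        if not np.isfinite(maf) or maf <= maf_threshold:
            reasons.append("maf")
        if (1 - call_rate) > max_missing:
            reasons.append("call_rate")
        records.append(
            VariantQCRecord(
                variant_id=row.variant_id,
                maf=float(maf) if np.isfinite(maf) else 0.0,
                call_rate=float(call_rate),
                biallelic=bool(row.biallelic),
                passed=not reasons,
                reasons=tuple(reasons),
            )
        )
    return records, masked


def fit_additive_logistic(
    dosage: np.ndarray,
    status: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    variant_id: str = "",
) -> AssocResult:
    """Maximum-likelihood additive logistic fit with a Wald test.

    ``dosage`` may contain NaN (those samples are dropped); ``covariates``
    is an optional (n, c) matrix (sex, ancestry PCs). Perfect separation is
    flagged rather than raised; a constant dosage is an error.
    """
    dosage = np.asarray(dosage, dtype=float)
    status = np.asarray(status, dtype=float)
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    ok = ~np.isnan(dosage)
    y, x = status[ok], dosage[ok]
    if len(np.unique(y)) < 2:
        raise ValueError("need at least one case and one control")
    if np.ptp(x) == 0:
        raise ValueError("constant dosage")
    design = x[:, None] if cov is None else np.column_stack([x, cov[ok]])
    design = sm.add_constant(design, prepend=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return AssocResult(
                variant_id=variant_id, beta=np.nan, se=np.nan, z=np.nan,
                p=np.nan, converged=False, separation=True,
            )
    beta = float(fit.params[0])
    se = float(fit.bse[0])
    separation = not np.isfinite(se) or se > 50 or abs(beta) > 20
    z = beta / se if se > 0 else np.nan
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    p = max(p, np.nextafter(0, 1)) if np.isfinite(p) else p
    return AssocResult(
        variant_id=variant_id, beta=beta, se=se,
        z=float(z), p=p,
        converged=bool(fit.mle_retvals.get("converged", True)),
        separation=bool(separation),
    )


def association_scan(
    genotypes: GenotypeDataset,
    covariate_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Fit every variant in the dataset; returns a tidy results table."""
    status = genotypes.samples["phenotype"].to_numpy(dtype=float)
    cov = (
        genotypes.samples[covariate_cols].to_numpy(dtype=float)
        if covariate_cols
        else None
    )
    rows = []
    for j, vid in enumerate(genotypes.variants["variant_id"]):
        try:
            res = fit_additive_logistic(
                genotypes.dosage[:, j], status, cov, variant_id=vid
            )
        except ValueError:
            continue
        rows.append(
            {
                "variant_id": vid,
                "contig": genotypes.variants["contig"].iloc[j],
                "pos": int(genotypes.variants["pos"].iloc[j]),
                "alt": genotypes.variants["alt"].iloc[j],
                "beta": res.beta,
                "se": res.se,
                "z": res.z,
                "or": res.or_,
                "ci_lo": res.ci95[0],
                "ci_hi": res.ci95[1],
                "p": res.p,
                "converged": res.converged,
                "separation": res.separation,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["neg_log10_p"] = -np.log10(df["p"])
    return df


_NULL_MEDIAN_CHI2 = float(stats.chi2.ppf(0.5, 1))  # 0.45494 to print precision


def genomic_inflation(pvalues: np.ndarray) -> InflationStat:
    """Lambda_GC: median of qchisq(1-p, 1) divided by the null median 0.45494."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        raise ValueError("no p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return InflationStat(lambda_gc=float(np.median(chi2) / _NULL_MEDIAN_CHI2))


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of genotype dosages."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    x, y = a[ok], b[ok]
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("r2 undefined: constant or empty dosage vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_clump(
    results: pd.DataFrame,
    genotypes: GenotypeDataset,
    r2_threshold: float = 0.6,
    fdr_threshold: float = 0.1,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Greedy LD clumping, then BH FDR over index-variant p-values only.

    Variants sorted by p ascending (ties by position then alt allele); the
    best unassigned variant seeds a clump and captures every unassigned
    variant on the same contig within the window with r^2 >= threshold.
    Clump r^2 is computed on mean-imputed standardized dosages (identical
    to :func:`pairwise_r2` when calls are complete). Adds clump_id /
    is_index / q / significant columns; the FDR selection runs after
    clumping, over index variants only.
    """
    df = results.copy()
    if len(df) == 0:
        for c in ("clump_id", "is_index", "q", "significant"):
            df[c] = []
        return df
    col = {vid: j for j, vid in enumerate(genotypes.variants["variant_id"])}
    cols = np.array([col[v] for v in df["variant_id"]], dtype=int)
    dose = genotypes.dosage[:, cols]
    mu = np.nanmean(dose, axis=0)
    z = np.where(np.isnan(dose), mu, dose) - mu
    sd = z.std(axis=0)
    sd[sd == 0] = np.inf  # constant dosage correlates with nothing
    z = z / sd

    order_pos = df.sort_values(["p", "pos", "alt"], kind="mergesort").index
    idx_of = {label: i for i, label in enumerate(df.index)}
    contig_codes = pd.factorize(df["contig"])[0]
    pos = df["pos"].to_numpy(dtype=np.int64)
    n = z.shape[0]
    clump = np.full(len(df), -1, dtype=int)
    is_index = np.zeros(len(df), dtype=bool)
    next_clump = 0
    for label in order_pos:
        i = idx_of[label]
        if clump[i] != -1:
            continue
        clump[i] = next_clump
        is_index[i] = True
        near = np.flatnonzero(
            (clump == -1)
            & (contig_codes == contig_codes[i])
            & (np.abs(pos - pos[i]) <= window)
        )
        if len(near):
            r = z[:, near].T @ z[:, i] / n
            clump[near[r * r >= r2_threshold]] = next_clump
        next_clump += 1
    df["clump_id"] = clump
    df["is_index"] = is_index
    df["q"] = np.nan
    df.loc[is_index, "q"] = bh_fdr(df.loc[is_index, "p"].to_numpy())
    df["significant"] = is_index & (df["q"] < fdr_threshold)
    return df
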