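"""Readers and writers for the standard formats the pipeline touches.

Conventions: VCF positions are 1-based; everything downstream of ingest uses
0-based half-open coordinates (a variant at 1-based position p occupies base
p-1). BED/BEDPE are 0-based half-open on disk and in memory. Genotypes are
held as an (n_samples, n_variants) dosage matrix of alt-allele counts in
{0, 1, 2}, with NaN marking missing calls; per-call read depth (DP) and
genotype quality (GQ) ride along as integer matrices when present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .intervals import LoopRecord, RegionSet

__all__ = [
    "VariantKey",
    "GenotypeDataset",
    "VCFParseError",
    "read_vcf",
    "write_vcf",
    "read_intervals",
    "write_bed",
    "write_bedpe",
    "read_table",
    "write_table",
]


class VCFParseError(ValueError):
    pass


class VariantKey(NamedTuple):
    """Identity of a biallelic variant record."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str

    def validate(self) -> "VariantKey":
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.contig}:{self.pos}")
        return self

    @property
    def id(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class GenotypeDataset:
    """Sample x variant dosages with per-call quality and sample metadata.

    ``samples`` is indexed by sample id and may carry ``phenotype`` (1=case,
    0=control), ``sex`` and covariate columns. ``variants`` has columns
    contig, pos (1-based), ref, alt, biallelic.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    dosage: np.ndarray  # float, NaN = missing
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if len(self.samples) != n or len(self.variants) != m:
            raise ValueError(
                f"dimension mismatch: dosage {self.dosage.shape}, "
                f"{len(self.samples)} samples, {len(self.variants)} variants"
            )
        for q in (self.dp, self.gq):
            if q is not None and q.shape != (n, m):
                raise ValueError("call-quality matrix shape mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_keys(self) -> list[VariantKey]:
        return [
            VariantKey(r.contig, int(r.pos), r.ref, r.alt)
            for r in self.variants.itertuples()
        ]

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeDataset":
        idx = self.samples.index.get_indexer(list(keep))
        if (idx < 0).any():
            missing = [s for s, i in zip(keep, idx) if i < 0]
            raise KeyError(f"unknown samples: {missing[:5]}")
        return GenotypeDataset(
            samples=self.samples.iloc[idx].copy(),
            variants=self.variants,
            dosage=self.dosage[idx],
            dp=None if self.dp is None else self.dp[idx],
            gq=None if self.gq is None else self.gq[idx],
        )

    def concat_samples(self, other: "GenotypeDataset") -> "GenotypeDataset":
        """Stack two datasets over the same variant list (e.g. cohort+panel)."""
        if not self.variants["variant_id"].equals(other.variants["variant_id"]):
            raise ValueError("datasets carry different variant lists")
        return GenotypeDataset(
            samples=pd.concat([self.samples, other.samples]),
            variants=self.variants,
            dosage=np.vstack([self.dosage, other.dosage]),
        )

    def subset_variants(self, cols: Sequence[int]) -> "GenotypeDataset":
        cols = np.asarray(cols)
        return GenotypeDataset(
            samples=self.samples,
            variants=self.variants.iloc[cols].reset_index(drop=True),
            dosage=self.dosage[:, cols],
            dp=None if self.dp is None else self.dp[:, cols],
            gq=None if self.gq is None else self.gq[:, cols],
        )


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(ds: GenotypeDataset, path: str | Path) -> None:
    """Write a GenotypeDataset as VCF 4.2 with FORMAT GT:DP:GQ."""
    path = Path(path)
    contigs = list(dict.fromkeys(ds.variants["contig"]))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.samples.index)
            + "\n"
        )
        have_q = ds.dp is not None and ds.gq is not None
        fmt = "GT:DP:GQ" if have_q else "GT"
        for j, rec in enumerate(ds.variants.itertuples()):
            calls = []
            for i in range(ds.n_samples):
                d = ds.dosage[i, j]
                gt = "./." if np.isnan(d) else _GT_CODE[int(d)]
                if have_q:
                    calls.append(f"{gt}:{int(ds.dp[i, j])}:{int(ds.gq[i, j])}")
                else:
                    calls.append(gt)
            fh.write(
                f"{rec.contig}\t{rec.pos}\t{getattr(rec, 'rsid', '.')}\t"
                f"{rec.ref}\t{rec.alt}\t.\tPASS\t.\t{fmt}\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeDataset:
    """Read a VCF into a GenotypeDataset.

    Multiallelic records are kept but flagged ``biallelic=False`` (dosage then
    counts the first ALT allele only); ``./.`` genotypes become NaN dosages.
    Sample order follows the VCF header.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, dosages, dps, gqs = [], [], [], []
        any_dp = any_gq = False
        for var in vcf:
            alts = var.ALT if var.ALT else ["."]
            biallelic = len(alts) == 1
            rows.append(
                {
                    "contig": var.CHROM,
                    "pos": var.POS,
                    "ref": var.REF,
                    "alt": alts[0],
                    "biallelic": biallelic,
                    "rsid": var.ID or ".",
                }
            )
            gts = var.genotypes  # [a0, a1, phased] per sample
            dose = np.full(len(samples), np.nan)
            for i, g in enumerate(gts):
                alleles = g[:-1]
                if any(a < 0 for a in alleles):
                    continue
                dose[i] = sum(1 for a in alleles if a == 1)
            dosages.append(dose)
            try:
                dp = var.format("DP")
            except KeyError:
                dp = None
            try:
                gq = var.format("GQ")
            except KeyError:
                gq = None
            if dp is not None:
                any_dp = True
                dps.append(np.asarray(dp).reshape(-1))
            else:
                dps.append(np.full(len(samples), -1))
            if gq is not None:
                any_gq = True
                gqs.append(np.asarray(gq).reshape(-1))
            else:
                gqs.append(np.full(len(samples), -1))
    except VCFParseError:
        raise
    except Exception as exc:  # htslib raises plain Exceptions
        raise VCFParseError(f"failed to parse {path}: {exc}") from exc

    variants = pd.DataFrame(
        rows, columns=["contig", "pos", "ref", "alt", "biallelic", "rsid"]
    )
    variants["variant_id"] = [
        f"{c}:{p}:{r}:{a}"
        for c, p, r, a in zip(
            variants.contig, variants.pos, variants.ref, variants.alt
        )
    ]
    dosage = (
        np.asarray(dosages).T if dosages else np.empty((len(samples), 0))
    )
    return GenotypeDataset(
        samples=pd.DataFrame(index=pd.Index(samples, name="sample")),
        variants=variants,
        dosage=dosage,
        dp=np.asarray(dps, dtype=np.int64).T if any_dp else None,
        gq=np.asarray(gqs, dtype=np.int64).T if any_gq else None,
    )


def read_intervals(path: str | Path, format: str = "bed"):
    """Read a BED file into a RegionSet, or a BEDPE file into LoopRecords.

    Coordinates are 0-based half-open on disk and are stored unchanged.
    """
    path = Path(path)
    if format == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 3:
            raise ValueError(f"{path}: BED needs >= 3 columns")
        ivs = [
            (str(r[0]), int(r[1]), int(r[2])) for r in df.itertuples(index=False)
        ]
        return RegionSet.from_intervals(ivs, name=path.stem)
    if format == "bedpe":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 6:
            raise ValueError(f"{path}: BEDPE needs >= 6 columns")
        loops = []
        for r in df.itertuples(index=False):
            loops.append(
                LoopRecord(
                    str(r[0]), int(r[1]), int(r[2]),
                    str(r[3]), int(r[4]), int(r[5]),
                    cell_type=str(r[6]) if len(r) > 6 else "",
                )
            )
        return loops
    raise ValueError(f"unknown interval format: {format!r}")


def write_bed(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, s, e in regions:
            fh.write(f"{contig}\t{s}\t{e}\n")


def write_bedpe(loops: Sequence[LoopRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            fh.write(
                f"{lp.contig1}\t{lp.start1}\t{lp.end1}\t"
                f"{lp.contig2}\t{lp.start2}\t{lp.end2}\t{lp.cell_type}\n"
            )


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a header-bearing TSV (catalogs, frequencies, expression, EHR)."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
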