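"""Construction of the brain-regulatory eQTL test set.

Significant eQTLs (FDR < 0.05 in any of the 13 brain regions, strict) are
restricted to regulatory territory supported by both chromatin-accessibility
peaks (union over histone ChIP-seq / ATAC / DNase assays) and Hi-C loop
anchors; the survival funnel at each stage is reported alongside the set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import LoopRecord, RegionSet, anchor_regions

__all__ = [
    "EQTLRecord",
    "FunnelReport",
    "filter_significant_eqtls",
    "build_regulatory_regions",
    "select_regulatory_eqtls",
]

BRAIN_REGION_COUNT = 13


@dataclass(frozen=True)
class EQTLRecord:
    """One variant-gene-region eQTL summary row."""

    variant_id: str
    gene: str
    region: str
    beta: float
    se: float
    fdr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"fdr outside [0,1]: {self.fdr}")
        if self.se <= 0:
            raise ValueError(f"se must be > 0: {self.se}")


@dataclass
class FunnelReport:
    """Counts of candidate variants surviving each construction stage."""

    significant: int = 0
    in_accessibility: int = 0
    in_regulatory: int = 0  # accessibility AND loop anchors
    post_qc: int = 0
    index_eqtls: int = 0
    replicated_loci: int = 0
    selected_genes: int = 0

    def to_dict(self) -> dict[str, int]:
        return {
            "significant_eqtls": self.significant,
            "in_accessibility": self.in_accessibility,
            "in_regulatory": self.in_regulatory,
            "post_qc": self.post_qc,
            "index_eqtls": self.index_eqtls,
            "replicated_loci": self.replicated_loci,
            "selected_genes": self.selected_genes,
        }


def filter_significant_eqtls(
    catalog: pd.DataFrame,
    fdr_threshold: float = 0.05,
    known_regions: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain (variant, gene, region) rows with FDR strictly below threshold.

    Returns ``(rows, candidates)`` where ``candidates`` is the deduplicated
    variant table (union over genes and regions) used as association
    candidates downstream.
    """
    if known_regions is not None:
        unknown = set(catalog["region"]) - set(known_regions)
        if unknown:
            raise ValueError(f"unknown brain region label(s): {sorted(unknown)}")
    rows = catalog[catalog["fdr"] < fdr_threshold].copy()
    candidates = (
        rows.drop_duplicates("variant_id")[
            [c for c in ("variant_id", "contig", "pos", "ref", "alt")
             if c in rows.columns]
        ]
        .reset_index(drop=True)
    )
    return rows, candidates


def build_regulatory_regions(
    peaks: Iterable[RegionSet],
    loops: Iterable[LoopRecord],
    mode: str = "intersect",
) -> RegionSet:
    """Regulatory territory from accessibility peaks and loop anchors.

    The accessibility union A is the union of every assay's merged peaks;
    the loop territory L is the union of all loop-anchor intervals (anchors
    only, not full loop spans). The default returns the intersection A n L;
    ``mode="union"`` returns A u L for the looser construction.
    """
    peaks = list(peaks)
    loops = list(loops)
    if not peaks or not loops:
        warnings.warn("empty peak or loop input; regulatory territory is empty")
    access = RegionSet(name="accessibility")
    for ps in peaks:
        access = access.union(ps)
    anchors = anchor_regions(loops)
    if mode == "intersect":
        out = access.intersect(anchors)
    elif mode == "union":
        out = access.union(anchors)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out.name = "regulatory"
    return out


def accessibility_union(peaks: Iterable[RegionSet]) -> RegionSet:
    out = RegionSet(name="accessibility")
    for ps in peaks:
        out = out.union(ps)
    return out


def select_regulatory_eqtls(
    candidates: pd.DataFrame,
    regions: RegionSet,
    accessibility: RegionSet | None = None,
    funnel: FunnelReport | None = None,
) -> tuple[pd.DataFrame, FunnelReport]:
    """Restrict candidate variants to the regulatory territory.

    A variant at 1-based position p lies inside a half-open interval [s, e)
    iff s <= p-1 < e. When the accessibility-only union is supplied, the
    funnel additionally reports how many candidates sit in accessible
    chromatin regardless of loop support.
    """
    funnel = funnel or FunnelReport()
    funnel.significant = len(candidates)
    if len(candidates) == 0:
        return candidates.copy(), funnel
    contigs = candidates["contig"].to_numpy()
    pos0 = candidates["pos"].to_numpy(dtype=np.int64) - 1
    if accessibility is not None:
        funnel.in_accessibility = int(
            accessibility.contains_many(contigs, pos0).sum()
        )
    inside = regions.contains_many(contigs, pos0)
    selected = candidates[inside].reset_index(drop=True)
    funnel.in_regulatory = len(selected)
    return selected, funnel
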