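"""Genomic interval algebra on 0-based half-open coordinates.

All interval sets are normalized at construction: per-contig arrays of
``[start, end)`` rows, sorted by start and merged so that no two stored
intervals overlap or abut ambiguously (book-ended intervals are merged).
Set operations (union, intersection) and point-membership queries are
implemented directly on the sorted arrays, which keeps the engine easy to
verify against a per-base oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = ["RegionSet", "LoopRecord"]


def _normalize(intervals: np.ndarray) -> np.ndarray:
    """Sort and merge an (k, 2) interval array; merges book-ended intervals."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = np.asarray(intervals, dtype=np.int64)
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


@dataclass
class RegionSet:
    """Per-contig sorted, merged half-open intervals with an assay label."""

    regions: dict[str, np.ndarray] = field(default_factory=dict)
    name: str = ""

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[str, int, int]], name: str = ""
    ) -> "RegionSet":
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in intervals:
            start, end = int(start), int(end)
            if start < 0:
                raise ValueError(f"negative coordinate: {contig}:{start}-{end}")
            if start >= end:
                raise ValueError(f"start >= end: {contig}:{start}-{end}")
            by_contig.setdefault(str(contig), []).append((start, end))
        return cls(
            regions={c: _normalize(np.asarray(v)) for c, v in by_contig.items()},
            name=name,
        )

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for contig in sorted(self.regions):
            for s, e in self.regions[contig]:
                yield contig, int(s), int(e)

    def __len__(self) -> int:
        return sum(len(v) for v in self.regions.values())

    @property
    def total_bases(self) -> int:
        return int(sum((v[:, 1] - v[:, 0]).sum() for v in self.regions.values()))

    def is_normalized(self) -> bool:
        for iv in self.regions.values():
            if len(iv) > 1 and not np.all(iv[1:, 0] > iv[:-1, 1]):
                return False
        return True

    def union(self, other: "RegionSet") -> "RegionSet":
        merged: dict[str, np.ndarray] = {}
        for contig in set(self.regions) | set(other.regions):
            parts = [
                x.regions[contig] for x in (self, other) if contig in x.regions
            ]
            merged[contig] = _normalize(np.vstack(parts))
        return RegionSet(regions=merged, name=f"union({self.name},{other.name})")

    def intersect(self, other: "RegionSet") -> "RegionSet":
        out: dict[str, np.ndarray] = {}
        for contig in set(self.regions) & set(other.regions):
            a, b = self.regions[contig], other.regions[contig]
            hits = []
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    hits.append((s, e))
                # advance whichever ends first
                if a[i, 1] <= b[j, 1]:
                    i += 1
                else:
                    j += 1
            if hits:
                out[contig] = np.asarray(hits, dtype=np.int64)
        return RegionSet(regions=out, name=f"isect({self.name},{other.name})")

    def contains(self, contig: str, pos0: int) -> bool:
        """Membership of a single 0-based position."""
        iv = self.regions.get(contig)
        if iv is None or len(iv) == 0:
            return False
        i = np.searchsorted(iv[:, 0], pos0, side="right") - 1
        return i >= 0 and pos0 < iv[i, 1]

    def contains_many(self, contigs: np.ndarray, pos0: np.ndarray) -> np.ndarray:
        """Vectorized membership for arrays of contigs and 0-based positions."""
        contigs = np.asarray(contigs)
        pos0 = np.asarray(pos0, dtype=np.int64)
        out = np.zeros(len(pos0), dtype=bool)
        for contig in np.unique(contigs):
            iv = self.regions.get(str(contig))
            if iv is None or len(iv) == 0:
                continue
            mask = contigs == contig
            p = pos0[mask]
            idx = np.searchsorted(iv[:, 0], p, side="right") - 1
            ok = (idx >= 0) & (p < iv[np.clip(idx, 0, None), 1])
            out[mask] = ok
        return out


@dataclass(frozen=True)
class LoopRecord:
    """A chromatin-interaction loop: two half-open anchor intervals."""

    contig1: str
    start1: int
    end1: int
    contig2: str
    start2: int
    end2: int
    cell_type: str = ""

    def __post_init__(self) -> None:
        for s, e in ((self.start1, self.end1), (self.start2, self.end2)):
            if s < 0:
                raise ValueError("negative anchor coordinate")
            if s >= e:
                raise ValueError("anchor start >= end")

    def anchors(self) -> list[tuple[str, int, int]]:
        return [
            (self.contig1, self.start1, self.end1),
            (self.contig2, self.start2, self.end2),
        ]


def anchor_regions(loops: Iterable[LoopRecord]) -> RegionSet:
    """Union of all loop-anchor intervals as a RegionSet."""
    ivs: list[tuple[str, int, int]] = []
    for loop in loops:
        ivs.extend(loop.anchors())
    return RegionSet.from_intervals(ivs, name="loop_anchors")
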