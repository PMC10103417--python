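"""Shared genomic coordinate model.

All coordinates are 0-based half-open internally (BED convention); VCF
positions are converted from 1-based on read and rendered back 1-based
inclusive for display. Chromosome names are matched by exact string
equality throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Gene",
    "GenomeLayout",
    "merge_within_distance",
    "intersect_any",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def display(self) -> str:
        """Render 1-based inclusive, the convention used in genome browsers."""
        return f"{self.chrom}: {self.start + 1:,}–{self.end:,}"


@dataclass
class Gene:
    """A gene with its TSS and per-condition expression (FPKM >= 0)."""

    gene_id: str
    interval: GenomicInterval
    strand: str
    expression: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for cond, fpkm in self.expression.items():
            if fpkm < 0:
                raise ValueError(f"negative FPKM for {self.gene_id}/{cond}")

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    def promoter(self, flank: int = 3000) -> GenomicInterval:
        """TSS +/- flank window, clipped at the chromosome origin."""
        return GenomicInterval(
            self.chrom, max(0, self.tss - flank), self.tss + flank, name=self.gene_id
        )

    def mean_fpkm(self, conditions: Optional[Sequence[str]] = None) -> float:
        conds = list(conditions) if conditions else list(self.expression)
        if not conds:
            return 0.0
        return float(np.mean([self.expression[c] for c in conds]))


class GenomeLayout:
    """Ordered chromosome names with lengths in bp."""

    def __init__(self, chrom_lengths: Mapping[str, int]):
        names = list(chrom_lengths)
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        self._lengths: Dict[str, int] = dict(chrom_lengths)

    @property
    def chroms(self) -> List[str]:
        return list(self._lengths)

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeLayout) and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"GenomeLayout({self._lengths!r})"

    def n_bins(self, chrom: str, resolution: int) -> int:
        return -(-self._lengths[chrom] // resolution)  # ceil division

    def total_length(self) -> int:
        return sum(self._lengths.values())

    def bins(self, resolution: int) -> List[GenomicInterval]:
        """Tile the genome at `resolution`; last bin of each chromosome clipped."""
        out = []
        for chrom, length in self._lengths.items():
            for start in range(0, length, resolution):
                out.append(GenomicInterval(chrom, start, min(start + resolution, length)))
        return out

    def to_dict(self) -> Dict[str, int]:
        return dict(self._lengths)


def _sorted_by_position(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_within_distance(
    intervals: Sequence[GenomicInterval], max_gap: int
) -> List[GenomicInterval]:
    """Merge intervals separated by a gap of at most `max_gap` bp.

    This is the ``bedtools merge -d`` rule: two intervals are merged when
    the distance between them is <= max_gap (overlapping and book-ended
    intervals always merge). Output is position-sorted and pairwise
    separated by gaps > max_gap.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if not intervals:
        return []
    merged: List[GenomicInterval] = []
    for iv in _sorted_by_position(intervals):
        if merged and iv.chrom == merged[-1].chrom and iv.start - merged[-1].end <= max_gap:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def intersect_any(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    check_namespace: bool = True,
) -> np.ndarray:
    """Boolean mask over `query`: True where >= 1 bp overlap with any subject.

    Uses a per-chromosome sorted sweep; O((n+m) log(n+m)).
    """
    if check_namespace and query and subject:
        qchr = {iv.chrom for iv in query}
        schr = {iv.chrom for iv in subject}
        # Disjoint namespaces almost always indicate a naming mismatch
        # (e.g. "chr1" vs "1"); overlap of namespaces is not required to be total.
        if not (qchr & schr):
            raise ValueError(
                f"chromosome namespaces do not intersect: {sorted(qchr)[:3]} vs "
                f"{sorted(schr)[:3]}"
            )
    mask = np.zeros(len(query), dtype=bool)
    if not subject:
        return mask
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in subject:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged = {c: merge_within_distance(ivs, 0) for c, ivs in by_chrom.items()}
    starts = {c: np.array([iv.start for iv in ivs]) for c, ivs in merged.items()}
    ends = {c: np.array([iv.end for iv in ivs]) for c, ivs in merged.items()}
    for i, q in enumerate(query):
        if q.chrom not in merged:
            continue
        s, e = starts[q.chrom], ends[q.chrom]
        # first merged interval with end > q.start; overlap iff its start < q.end
        k = int(np.searchsorted(e, q.start, side="right"))
        mask[i] = k < len(s) and s[k] < q.end
    return mask
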