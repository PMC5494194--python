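"""Genomic interval primitives.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers bases ``start .. end-1``.  These primitives are the
bookkeeping layer for every accessibility computation: interval union
(book-ended intervals merge), overlap counting and nearest-point search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """Half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    @property
    def region_id(self) -> str:
        return f"{self.chrom}_{self.start}_{self.end}"

    def overlaps(self, other: "GenomicRegion") -> bool:
        """Overlap by >=1 bp under half-open coordinates."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class PeakSet:
    """Sorted, non-overlapping peak calls of one sample."""

    sample_id: str
    regions: list[GenomicRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions)
        prev: GenomicRegion | None = None
        for r in self.regions:
            if prev is not None and prev.chrom == r.chrom and r.start < prev.end:
                raise ValueError(
                    f"sample {self.sample_id}: overlapping peaks "
                    f"{prev.region_id} and {r.region_id}"
                )
            prev = r

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self.regions)


def merge_intervals(regions: Iterable[GenomicRegion]) -> list[GenomicRegion]:
    """Interval union; book-ended (touching) intervals merge.

    Sweep over sorted intervals per chromosome.  Two intervals land in the
    same merged region iff they overlap or touch (gap of 0), matching the
    default behaviour of standard BED merge tools.
    """
    out: list[GenomicRegion] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    for r in sorted(regions):
        if r.chrom != cur_chrom or r.start > cur_end:
            if cur_chrom is not None:
                out.append(GenomicRegion(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = r.chrom, r.start, r.end
        else:
            cur_end = max(cur_end, r.end)
    if cur_chrom is not None:
        out.append(GenomicRegion(cur_chrom, cur_start, cur_end))
    return out


def _by_chrom(regions: Sequence[GenomicRegion]) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Index regions per chromosome as (starts, ends, original indices), start-sorted."""
    idx: dict[str, list[int]] = {}
    for i, r in enumerate(regions):
        idx.setdefault(r.chrom, []).append(i)
    out = {}
    for chrom, ii in idx.items():
        ii = sorted(ii, key=lambda i: (regions[i].start, regions[i].end))
        starts = np.array([regions[i].start for i in ii], dtype=np.int64)
        ends = np.array([regions[i].end for i in ii], dtype=np.int64)
        out[chrom] = (starts, ends, np.array(ii, dtype=np.int64))
    return out


def count_overlaps(
    targets: Sequence[GenomicRegion], queries: Iterable[GenomicRegion]
) -> np.ndarray:
    """Number of query intervals overlapping each target by >=1 bp.

    Targets within a chromosome must be non-overlapping (consensus regions
    are, by construction); each query is counted once per target it touches.
    """
    counts = np.zeros(len(targets), dtype=np.int64)
    index = _by_chrom(targets)
    for q in queries:
        if q.chrom not in index:
            continue
        starts, ends, orig = index[q.chrom]
        # overlapping targets: start < q.end and end > q.start
        lo = int(np.searchsorted(ends, q.start, side="right"))
        hi = int(np.searchsorted(starts, q.end, side="left"))
        if lo < hi:
            counts[orig[lo:hi]] += 1
    return counts


def overlapping_target_indices(
    targets: Sequence[GenomicRegion], query: GenomicRegion
) -> list[int]:
    """Indices of (non-overlapping, per-chromosome sorted) targets hit by query."""
    index = _by_chrom(targets)
    if query.chrom not in index:
        return []
    starts, ends, orig = index[query.chrom]
    lo = int(np.searchsorted(ends, query.start, side="right"))
    hi = int(np.searchsorted(starts, query.end, side="left"))
    return [int(i) for i in orig[lo:hi]]
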