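"""Exact genomic-interval arithmetic.

All coordinates are 0-based half-open: an interval covering exactly one
base ``b`` is stored as ``[b, b+1)``.  These primitives underlie every
peak-overlap statistic in the pipeline, in particular the two-set Venn
decomposition used to compare peak calls between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "VennCounts",
    "overlaps",
    "merge_set",
    "venn_stats",
    "nearest_point",
    "UNASSIGNED",
]

#: Sentinel gene/point id returned when no anchor shares the query chromosome.
UNASSIGNED = "unassigned"

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic region, optionally stranded/named/scored."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"degenerate interval {self.chrom}:[{self.start},{self.end}): "
                "start must be < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Integer midpoint, rounded down."""
        return (self.start + self.end) // 2


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff ``a`` and ``b`` share >= ``min_bp`` bases on the same chromosome."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_bp


class IntervalSet:
    """A collection of intervals kept per-chromosome, sorted by (start, end)."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
        self._by_chrom = by_chrom
        # per-chrom start arrays and max member length bound the candidate
        # window for overlap queries to O(log n + hits)
        self._starts = {c: [iv.start for iv in ivs] for c, ivs in by_chrom.items()}
        self._max_len = {
            c: max(len(iv) for iv in ivs) for c, ivs in by_chrom.items() if ivs
        }

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def on(self, chrom: str) -> Sequence[GenomicInterval]:
        return self._by_chrom.get(chrom, ())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            yield from self._by_chrom[chrom]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    @property
    def total_count(self) -> int:
        return len(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return list(self) == list(other)

    def overlapping(self, query: GenomicInterval, min_bp: int = 1) -> list[GenomicInterval]:
        """All members sharing >= min_bp bases with ``query`` (binary search)."""
        import bisect

        ivs = self._by_chrom.get(query.chrom)
        if not ivs:
            return []
        starts = self._starts[query.chrom]
        # members with start >= query.end cannot overlap; members starting
        # more than max_len before query.start already ended before it
        hi = bisect.bisect_left(starts, query.end)
        lo = bisect.bisect_left(starts, query.start - self._max_len[query.chrom])
        out = []
        for iv in ivs[lo:hi]:
            if min(iv.end, query.end) - max(iv.start, query.start) >= min_bp:
                out.append(iv)
        return out


def merge_set(s: IntervalSet, gap: int = 0) -> IntervalSet:
    """Merge intervals closer than or touching within ``gap`` bases.

    With ``gap=0`` touching intervals (``[0,5)`` and ``[5,8)``) merge, and the
    union of covered bases is preserved exactly.  Output intervals are pairwise
    separated by more than ``gap``.  Idempotent.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    merged: list[GenomicInterval] = []
    for chrom in s.chroms:
        cur_start = cur_end = None
        for iv in s.on(chrom):
            if cur_start is None:
                cur_start, cur_end = iv.start, iv.end
            elif iv.start <= cur_end + gap:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        if cur_start is not None:
            merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return IntervalSet(merged)


@dataclass(frozen=True)
class VennCounts:
    """Two-set peak-overlap decomposition.

    ``shared_clusters`` counts connected components of the cross-set overlap
    graph that contain at least one member of each set — the single "shared"
    number a two-circle Venn diagram prints.  ``a_in_shared``/``b_in_shared``
    retain the per-set member counts, which differ from ``shared_clusters``
    when overlaps are many-to-many.
    """

    a_total: int
    b_total: int
    a_only: int
    b_only: int
    shared_clusters: int
    a_in_shared: int
    b_in_shared: int

    def __post_init__(self) -> None:
        if self.a_only + self.a_in_shared != self.a_total:
            raise ValueError("a_only + a_in_shared must equal a_total")
        if self.b_only + self.b_in_shared != self.b_total:
            raise ValueError("b_only + b_in_shared must equal b_total")
        if min(
            self.a_total, self.b_total, self.a_only, self.b_only,
            self.shared_clusters, self.a_in_shared, self.b_in_shared,
        ) < 0:
            raise ValueError("all Venn counts must be >= 0")

    def swapped(self) -> "VennCounts":
        return VennCounts(
            a_total=self.b_total, b_total=self.a_total,
            a_only=self.b_only, b_only=self.a_only,
            shared_clusters=self.shared_clusters,
            a_in_shared=self.b_in_shared, b_in_shared=self.a_in_shared,
        )


def venn_stats(a: IntervalSet, b: IntervalSet, min_bp: int = 1) -> VennCounts:
    """Decompose two peak sets into condition-unique and shared members.

    A member of ``a`` is "shared" if it overlaps (>= ``min_bp`` bases) any
    member of ``b``, and vice versa.  ``shared_clusters`` is the number of
    connected components of the bipartite overlap graph, i.e. the one number
    printed in the middle of a two-circle Venn diagram.
    """
    a_list = list(a)
    b_list = list(b)
    n_a, n_b = len(a_list), len(b_list)
    # union-find over a-members [0, n_a) and b-members [n_a, n_a + n_b)
    parent = list(range(n_a + n_b))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    a_hit = [False] * n_a
    b_hit = [False] * n_b
    b_index = {id(iv): n_a + j for j, iv in enumerate(b_list)}
    for i, iv in enumerate(a_list):
        for other in b.overlapping(iv, min_bp=min_bp):
            j = b_index[id(other)]
            a_hit[i] = True
            b_hit[j - n_a] = True
            union(i, j)

    roots = set()
    for i in range(n_a):
        if a_hit[i]:
            roots.add(find(i))
    shared_clusters = len(roots)
    a_in_shared = sum(a_hit)
    b_in_shared = sum(b_hit)
    return VennCounts(
        a_total=n_a, b_total=n_b,
        a_only=n_a - a_in_shared, b_only=n_b - b_in_shared,
        shared_clusters=shared_clusters,
        a_in_shared=a_in_shared, b_in_shared=b_in_shared,
    )


def nearest_point(
    x: GenomicInterval,
    points: Sequence[tuple[str, int, str, str]],
) -> tuple[str, Optional[int]]:
    """Nearest anchor (e.g. TSS) to the interval midpoint, with signed distance.

    ``points`` are ``(chrom, position, strand, id)`` tuples.  Distance is
    signed by the anchor's strand: negative means the midpoint lies upstream
    of the anchor.  Ties break on smaller anchor coordinate, then on
    lexicographically smaller id.  Returns ``(UNASSIGNED, None)`` when no
    anchor shares the interval's chromosome.
    """
    mid = x.midpoint
    best: Optional[tuple[int, int, str]] = None  # (|d|, position, id)
    best_signed: Optional[int] = None
    for chrom, pos, strand, pid in points:
        if chrom != x.chrom:
            continue
        raw = mid - pos
        signed = raw if strand != "-" else -raw
        key = (abs(signed), pos, pid)
        if best is None or key < best:
            best = key
            best_signed = signed
    if best is None:
        return UNASSIGNED, None
    return best[2], best_signed
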