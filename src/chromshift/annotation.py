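"""Peak-to-feature annotation and anchor-centered signal profiles.

Assigns each peak to exactly one genomic category (promoter, UTR, exon,
intron, downstream, distal intergenic) using the peak midpoint and a fixed
priority order, summarizes category distributions, and builds TSS/TES-
centered binned signal profiles of the kind shown as average-density
metagene plots.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .intervals import UNASSIGNED, GenomicInterval, IntervalSet, nearest_point

__all__ = [
    "GeneModel",
    "AnnotationRecord",
    "ProfileMatrix",
    "CATEGORIES",
    "annotate_peak",
    "annotate_peaks",
    "distribution_histogram",
    "profile_matrix",
    "mean_profile",
]

#: Annotation categories in priority order (first match wins).
CATEGORIES = (
    "Promoter",
    "5'UTR",
    "3'UTR",
    "Exon",
    "Intron",
    "Downstream",
    "DistalIntergenic",
)


@dataclass
class GeneModel:
    """A gene span with strand, TSS/TES, exons and optional UTRs.

    Coordinates are 0-based half-open.  The TSS is ``start`` for a
    "+"-strand gene and ``end - 1`` for a "-"-strand gene; the TES is the
    opposite extremity.  Exons must be sorted, non-overlapping and within
    the span.  UTR intervals are optional (GTF-lite carries none) and are
    only used by the 5'UTR/3'UTR annotation branches.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene span [{self.start},{self.end})")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        prev_end = None
        for es, ee in self.exons:
            if not (self.start <= es < ee <= self.end):
                raise ValueError(f"exon [{es},{ee}) outside gene span")
            if prev_end is not None and es < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = ee

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class AnnotationRecord:
    peak: GenomicInterval
    category: str
    gene_id: str
    tss_distance: Optional[int]


def _in_any(pos: int, blocks: Sequence[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in blocks)


def annotate_peak(
    peak: GenomicInterval,
    models: Sequence[GeneModel],
    promoter_window: tuple[int, int] = (2000, 500),
    downstream_len: int = 3000,
) -> AnnotationRecord:
    """Assign one category to ``peak`` by its midpoint.

    Category priority: Promoter > 5'UTR > 3'UTR > Exon > Intron >
    Downstream > DistalIntergenic.  "Promoter" means the midpoint lies in
    ``[TSS - up, TSS + down]`` in strand-oriented coordinates (upstream is
    5' of the gene).  "Downstream" means within ``downstream_len`` bases
    past the TES on the gene's strand.  ``tss_distance`` is the signed
    midpoint-to-nearest-TSS distance (negative = upstream).
    """
    up, down = promoter_window
    mid = peak.midpoint
    tss_points = [(gm.chrom, gm.tss, gm.strand, gm.gene_id) for gm in models]
    nearest_id, nearest_d = nearest_point(peak, tss_points) if models else (UNASSIGNED, None)

    same_chrom = [gm for gm in models if gm.chrom == peak.chrom]

    def match(category: str) -> Optional[GeneModel]:
        best: Optional[tuple[int, str, GeneModel]] = None
        for gm in same_chrom:
            # strand-oriented offset of the midpoint from the TSS
            offset = mid - gm.tss if gm.strand == "+" else gm.tss - mid
            hit = False
            if category == "Promoter":
                hit = -up <= offset <= down
            elif category == "5'UTR":
                hit = _in_any(mid, gm.utr5)
            elif category == "3'UTR":
                hit = _in_any(mid, gm.utr3)
            elif category == "Exon":
                hit = _in_any(mid, gm.exons)
            elif category == "Intron":
                hit = gm.contains(mid)
            elif category == "Downstream":
                past = mid - gm.tes if gm.strand == "+" else gm.tes - mid
                hit = 0 < past <= downstream_len
            if hit:
                key = (abs(offset), gm.gene_id, gm)
                if best is None or key[:2] < best[:2]:
                    best = key
        return best[2] if best else None

    for category in CATEGORIES[:-1]:
        gm = match(category)
        if gm is not None:
            return AnnotationRecord(peak=peak, category=category, gene_id=gm.gene_id,
                                    tss_distance=nearest_d)
    return AnnotationRecord(peak=peak, category="DistalIntergenic",
                            gene_id=nearest_id, tss_distance=nearest_d)


def annotate_peaks(
    peaks: Sequence[GenomicInterval] | IntervalSet,
    models: Sequence[GeneModel],
    promoter_window: tuple[int, int] = (2000, 500),
    downstream_len: int = 3000,
) -> list[AnnotationRecord]:
    return [
        annotate_peak(p, models, promoter_window=promoter_window, downstream_len=downstream_len)
        for p in peaks
    ]


def distribution_histogram(
    annotations: Sequence[AnnotationRecord],
) -> dict[str, tuple[int, float]]:
    """Per-category ``(count, fraction)``; fractions sum to 1 over non-empty input."""
    if not annotations:
        return {}
    counts = Counter(rec.category for rec in annotations)
    n = len(annotations)
    return {cat: (counts[cat], counts[cat] / n) for cat in CATEGORIES if counts[cat]}


@dataclass
class ProfileMatrix:
    """Anchor x bin matrix of peak-base coverage around anchors (e.g. TSSs)."""

    region_ids: list[str]
    window: tuple[int, int]  # (upstream bp, downstream bp)
    n_bins: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region_ids), self.n_bins):
            raise ValueError("profile matrix shape mismatch")

    @property
    def bin_width(self) -> float:
        return (self.window[0] + self.window[1]) / self.n_bins


def profile_matrix(
    signal_peaks: IntervalSet,
    anchors: Sequence[tuple[str, int, str]],
    window: tuple[int, int] = (5000, 5000),
    n_bins: int = 100,
) -> ProfileMatrix:
    """Count peak-bases in each bin of a window around each anchor.

    Cell (r, j) is the number of bases of bin j of anchor r covered by any
    peak (peaks are counted per-base, overlapping peaks independently).
    Minus-strand anchors are flipped so upstream is always on the left.
    """
    up, down = window
    if n_bins < 1 or up + down <= 0:
        raise ValueError("need n_bins >= 1 and a positive window")
    total = up + down
    edges = np.linspace(0, total, n_bins + 1)
    values = np.zeros((len(anchors), n_bins))
    ids = []
    for r, (chrom, pos, strand) in enumerate(anchors):
        ids.append(f"{chrom}:{pos}:{strand}")
        lo = pos - up if strand != "-" else pos - down
        hi = lo + total
        query_lo = max(lo, 0)
        if query_lo >= hi:
            continue
        query = GenomicInterval(chrom, query_lo, hi)
        for peak in signal_peaks.overlapping(query):
            s = max(peak.start, lo) - lo
            e = min(peak.end, hi) - lo
            if strand == "-":
                s, e = total - e, total - s
            # distribute [s, e) over bins by clipped overlap with each bin
            ov = np.clip(np.minimum(edges[1:], e) - np.maximum(edges[:-1], s), 0, None)
            values[r] += ov
    return ProfileMatrix(region_ids=ids, window=window, n_bins=n_bins, values=values)


def mean_profile(pm: ProfileMatrix) -> np.ndarray:
    """Column means of a profile matrix: the average metagene signal."""
    return pm.values.mean(axis=0)
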