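"""Known-motif scanning and per-condition motif containment.

A position frequency matrix (PFM) is converted to a log-odds position
weight matrix (PWM), peaks are scanned on both strands at a score
threshold expressed as a fraction of the PWM's min-max score range, and
the per-condition fraction of peaks containing at least one hit is
tabulated — the statistic behind "percentage of the binding motif in the
overall accessible regions" comparisons.  Enrichment of a motif in a
foreground peak set against a background is tested with the
hypergeometric upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, IntervalSet
from .io import PfmRecord, ValidationError

__all__ = [
    "PWM",
    "MotifHit",
    "pwm_from_pfm",
    "scan_sequence",
    "motif_containment",
    "motif_proportion_shift",
    "motif_enrichment_test",
    "synthetic_pfm",
    "builtin_motifs",
]

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Log-odds scoring matrix (4 x w, rows A,C,G,T) with its background."""

    motif_id: str
    logodds: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        self.logodds = np.asarray(self.logodds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.logodds.shape[0] != 4 or self.logodds.ndim != 2:
            raise ValidationError("PWM log-odds must be 4 x w")
        if self.background.shape != (4,) or not np.isclose(self.background.sum(), 1.0):
            raise ValidationError("background must be 4 probabilities summing to 1")

    @property
    def width(self) -> int:
        return self.logodds.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.logodds.min(axis=0).sum())

    def threshold(self, threshold_fraction: float) -> float:
        if not 0 < threshold_fraction <= 1:
            raise ValidationError("threshold_fraction must be in (0, 1]")
        return self.min_score + threshold_fraction * (self.max_score - self.min_score)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.logodds.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    pos: int  # 0-based start on the forward strand
    strand: str
    score: float


def pwm_from_pfm(
    pfm: PfmRecord,
    pseudocount: float = 1.0,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> PWM:
    """Standard log2-odds PWM from a count PFM.

    ``logodds[b][j] = log2(((pfm[b][j] + pc * bg[b]) / (col_total + pc)) / bg[b])``
    """
    bg = np.asarray(background, dtype=float)
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    counts = np.asarray(pfm.matrix, dtype=float)
    col_totals = counts.sum(axis=0)
    probs = (counts + pseudocount * bg[:, None]) / (col_totals + pseudocount)
    logodds = np.log2(probs / bg[:, None])
    return PWM(motif_id=pfm.motif_id, logodds=logodds, background=bg)


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to row indices; N (or any non-ACGT) maps to 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, i in _IDX.items():
        out[arr == ord(base)] = i
    return out


def _window_scores(idx: np.ndarray, logodds: np.ndarray) -> np.ndarray:
    """Score every forward window; N positions contribute 0 (background-equal)."""
    w = logodds.shape[1]
    if idx.size < w:
        return np.empty(0)
    lo = np.vstack([logodds, np.zeros(w)])  # row 4 = N
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    return lo[windows, np.arange(w)].sum(axis=1)


def scan_sequence(seq: str, pwm: PWM, threshold_fraction: float = 0.8) -> list[MotifHit]:
    """All windows on both strands scoring >= the fractional threshold.

    Minus-strand windows are scored on the reverse complement; their ``pos``
    is reported on the forward coordinate system.  A sequence shorter than
    the motif yields an empty list.
    """
    thr = pwm.threshold(threshold_fraction)
    idx = _encode(seq)
    fwd = _window_scores(idx, pwm.logodds)
    # scoring the reverse complement of each forward window == scoring the
    # forward window with the reverse-complemented PWM
    rc_logodds = pwm.logodds[::-1, ::-1]
    rev = _window_scores(idx, rc_logodds)
    hits = [
        MotifHit(chrom="", pos=int(p), strand="+", score=float(s))
        for p, s in zip(np.nonzero(fwd >= thr)[0], fwd[fwd >= thr])
    ]
    hits += [
        MotifHit(chrom="", pos=int(p), strand="-", score=float(s))
        for p, s in zip(np.nonzero(rev >= thr)[0], rev[rev >= thr])
    ]
    hits.sort(key=lambda h: (h.pos, h.strand))
    return hits


def _peak_sequence(peak: GenomicInterval, genome: dict[str, str]) -> str:
    if peak.chrom not in genome:
        raise ValidationError(f"peak chromosome {peak.chrom!r} absent from genome")
    seq = genome[peak.chrom]
    if peak.end > len(seq):
        raise ValidationError(
            f"peak {peak.chrom}:[{peak.start},{peak.end}) beyond chromosome end ({len(seq)})"
        )
    return seq[peak.start : peak.end]


def motif_containment(
    peaks: IntervalSet | Sequence[GenomicInterval],
    genome: dict[str, str],
    pwm: PWM,
    threshold_fraction: float = 0.8,
) -> tuple[int, float]:
    """(number, fraction) of peaks containing >= 1 motif hit.

    A peak counts once regardless of how many hits it contains; the result
    is invariant to peak order.
    """
    peaks = list(peaks)
    if not peaks:
        return 0, 0.0
    n_with = sum(
        1
        for p in peaks
        if scan_sequence(_peak_sequence(p, genome), pwm, threshold_fraction)
    )
    return n_with, n_with / len(peaks)


def motif_proportion_shift(
    peaks_a: IntervalSet | Sequence[GenomicInterval],
    peaks_b: IntervalSet | Sequence[GenomicInterval],
    genome: dict[str, str],
    pwms: Sequence[PWM],
    threshold_fraction: float = 0.8,
):
    """Per-motif containment fractions in two conditions and their shift.

    Returns a DataFrame indexed by motif id with columns ``fraction_a``,
    ``fraction_b`` and ``delta = fraction_b - fraction_a`` — the table
    behind "the percentage of the binding motif increased from X% to Y%".
    """
    import pandas as pd

    if not pwms:
        raise ValidationError("need >= 1 PWM")
    rows = []
    for pwm in pwms:
        _, fa = motif_containment(peaks_a, genome, pwm, threshold_fraction)
        _, fb = motif_containment(peaks_b, genome, pwm, threshold_fraction)
        rows.append({"motif_id": pwm.motif_id, "fraction_a": fa, "fraction_b": fb,
                     "delta": fb - fa})
    return pd.DataFrame(rows).set_index("motif_id")


def motif_enrichment_test(fg_with: int, fg_total: int, bg_with: int, bg_total: int) -> float:
    """Upper-tail hypergeometric p: >= ``fg_with`` motif-positive peaks in a
    foreground of ``fg_total`` drawn from a background with ``bg_with`` of
    ``bg_total`` positive."""
    if not (0 <= fg_with <= fg_total and 0 <= bg_with <= bg_total):
        raise ValidationError("inconsistent counts")
    if fg_total > bg_total or fg_with > bg_with:
        raise ValidationError("foreground must be drawable from background")
    return float(stats.hypergeom.sf(fg_with - 1, bg_total, bg_with, fg_total))


def synthetic_pfm(motif_id: str, consensus: str, match_count: int = 97, other_count: int = 1) -> PfmRecord:
    """A sharp synthetic PFM whose argmax path spells ``consensus``.

    These are synthetic motif models, not measured matrices: each column
    gives ``match_count`` observations to the consensus base and
    ``other_count`` to each alternative, which makes planted-consensus
    recovery deterministic at any reasonable scan threshold.
    """
    mat = np.full((4, len(consensus)), float(other_count))
    for j, base in enumerate(consensus.upper()):
        mat[_IDX[base], j] = float(match_count)
    return PfmRecord(motif_id=motif_id, matrix=mat)


#: Synthetic stand-in consensus sequences for the transcription factors whose
#: containment shifts the pipeline tabulates.  Widths (28 bp) and sharpness are
#: chosen so a random 200 bp peak has < 1e-6 probability of a chance hit at the
#: default 0.8 threshold; they are NOT the measured JASPAR matrices.
_SYNTHETIC_CONSENSUS = {
    "CTCF_like": "CCACCAGGTGGCAGCTGTCCATCACGTG",
    "BORIS_like": "GTACGGACCTCCAGAAGGCATCCTAACC",
    "Fra2_like": "ATTGACTCATCGGAAGTCACTCGATTGG",
    "Fosl2_like": "CGTGACGTCATTACGCCTAAGTTCGACA",
    "JunB_like": "TTACGCAATCGGTTGACTAACGGGATCC",
}


def builtin_motifs() -> list[PfmRecord]:
    """Synthetic PFMs for the factors tracked by the condition-shift table."""
    return [synthetic_pfm(mid, cons) for mid, cons in _SYNTHETIC_CONSENSUS.items()]
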