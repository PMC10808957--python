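"""Cross-stage statistics: gene-set intersections, percent-excess
arithmetic, replication-fork rate conversion, and the Mann-Whitney U test.

The gene-set Venn intersects differentially expressed genes with genes
whose promoters gained accessibility peaks; the fork-rate helpers convert
stretched-DNA-fiber track lengths (micrometers, at 2.59 kb per um) into
kb/min replication speeds compared between conditions by a rank test.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io import ValidationError

__all__ = [
    "GeneSetVenn",
    "FiberMeasurement",
    "KB_PER_UM",
    "gene_set_venn",
    "percent_excess",
    "fork_rate",
    "fork_rates",
    "mann_whitney_u",
]

#: Stretched-fiber length conversion constant: 1 um of fiber = 2.59 kb.
KB_PER_UM = 2.59


@dataclass(frozen=True)
class GeneSetVenn:
    set_a_name: str
    set_b_name: str
    a_total: int
    b_total: int
    shared: int
    shared_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.shared != len(self.shared_ids):
            raise ValidationError("shared must equal |shared_ids|")
        if self.shared > min(self.a_total, self.b_total):
            raise ValidationError("shared exceeds a set total")


def gene_set_venn(
    a: Iterable[str],
    b: Iterable[str],
    a_name: str = "A",
    b_name: str = "B",
) -> GeneSetVenn:
    """Exact, order-independent intersection of two gene-id sets."""
    sa, sb = set(a), set(b)
    shared = tuple(sorted(sa & sb))
    return GeneSetVenn(
        set_a_name=a_name, set_b_name=b_name,
        a_total=len(sa), b_total=len(sb),
        shared=len(shared), shared_ids=shared,
    )


def percent_excess(a: int, b: int) -> float:
    """How many percent larger ``a`` is than ``b``: ``100 * (a - b) / b``."""
    if b == 0:
        raise ValidationError("reference count must be > 0")
    return 100.0 * (a - b) / b


@dataclass(frozen=True)
class FiberMeasurement:
    """One stretched DNA fiber: track length (um), pulse time (min), condition."""

    fiber_id: str
    length_um: float
    label_minutes: float
    condition: str  # WT | KO

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.label_minutes <= 0:
            raise ValidationError("fiber length and label time must be > 0")


def fork_rate(m: FiberMeasurement, kb_per_um: float = KB_PER_UM) -> float:
    """Replication fork rate in kb/min: length x conversion / pulse time."""
    if kb_per_um <= 0:
        raise ValidationError("kb_per_um must be > 0")
    return m.length_um * kb_per_um / m.label_minutes


def fork_rates(
    measurements: Sequence[FiberMeasurement], kb_per_um: float = KB_PER_UM
) -> dict[str, np.ndarray]:
    """Per-condition arrays of fork rates (kb/min)."""
    out: dict[str, list[float]] = {}
    for m in measurements:
        out.setdefault(m.condition, []).append(fork_rate(m, kb_per_um))
    return {k: np.array(v) for k, v in out.items()}


def _exact_u_pvalue(ranks: np.ndarray, n1: int, u: float) -> float:
    """Two-sided p by full enumeration of rank-subset assignments.

    Enumerates every choice of ``n1`` of the (midrank-tied) pooled ranks,
    so ties are handled exactly.  The null U distribution is symmetric
    about ``n1 * n2 / 2`` under label exchange, and the reported p is
    ``P(|U - mu| >= |u - mu|)``.
    """
    n = len(ranks)
    n2 = n - n1
    offset = n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    dev = abs(u - mu)
    total = hits = 0
    for combo in itertools.combinations(range(n), n1):
        u_null = ranks[list(combo)].sum() - offset
        total += 1
        if abs(u_null - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = 20,
) -> tuple[float, float]:
    """Mann-Whitney U of ``x`` vs ``y`` with a two-sided p value.

    U uses midrank tie handling.  When the combined sample size is at most
    ``exact_max_n`` the p value comes from full enumeration of rank
    assignments (exact even under ties); above it, from the normal
    approximation with tie correction.  ``U(x, y) + U(y, x) = |x| * |y|``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValidationError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if n1 + n2 <= exact_max_n:
        p = _exact_u_pvalue(ranks, n1, u)
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return u, min(p, 1.0)
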