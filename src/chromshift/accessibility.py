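"""Per-peak coverage-density normalization and two-condition comparison.

The central quantities are per-peak read densities normalized to counts
per million (CPM) of the peak-count library, compared between two
conditions on the log2 scale: an ordinary least-squares fit of KO on WT
(the "best linear fitting line" of a log2 density scatter), a global
percent change estimated from the mean of per-peak log2 ratios, and
per-assay log2-ratio distribution summaries for multi-assay boxplots.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DensityTable",
    "DensityFit",
    "normalize_density",
    "log2_density_fit",
    "global_fold_change",
    "density_ratio_table",
]


@dataclass
class DensityTable:
    """Per-interval signal for one assay across samples.

    ``raw`` holds per-peak read counts (non-negative reals; fractional
    expected coverage is allowed), ``normalized`` holds counts per million
    of each sample's library.  ``pseudocount`` is the value added before
    any log2 transform downstream.
    """

    interval_ids: list[str]
    samples: list[str]
    raw: np.ndarray
    normalized: np.ndarray
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        shape = (len(self.interval_ids), len(self.samples))
        if self.raw.shape != shape or self.normalized.shape != shape:
            raise ValueError("raw/normalized shape must be (intervals, samples)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")

    def column(self, sample: str, normalized: bool = True) -> np.ndarray:
        j = self.samples.index(sample)
        return (self.normalized if normalized else self.raw)[:, j]


def normalize_density(
    raw: np.ndarray,
    library_sizes: np.ndarray,
    interval_ids: list[str] | None = None,
    samples: list[str] | None = None,
    pseudocount: float = 1.0,
) -> DensityTable:
    """CPM-normalize a per-peak count table: ``raw / library_size * 1e6``."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw must be 2-D (intervals x samples)")
    libs = np.asarray(library_sizes, dtype=float)
    if libs.shape != (raw.shape[1],):
        raise ValueError("need one library size per sample")
    if (libs <= 0).any():
        raise ValueError("library sizes must be > 0")
    if (raw < 0).any():
        raise ValueError("raw densities must be >= 0")
    normalized = raw / libs * 1e6
    return DensityTable(
        interval_ids=interval_ids or [f"peak_{i}" for i in range(raw.shape[0])],
        samples=samples or [f"sample_{j}" for j in range(raw.shape[1])],
        raw=raw,
        normalized=normalized,
        pseudocount=pseudocount,
    )


@dataclass(frozen=True)
class DensityFit:
    """OLS fit of log2 density in one sample on another, with correlation."""

    slope: float
    intercept: float
    r: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0000001 <= self.r <= 1.0000001:
            raise ValueError("correlation out of range")
        if self.n < 2:
            raise ValueError("fit needs >= 2 points")


def _logged(table: DensityTable, sample: str) -> np.ndarray:
    return np.log2(table.column(sample) + table.pseudocount)


def log2_density_fit(x_sample: str, y_sample: str, table: DensityTable) -> DensityFit:
    """Ordinary least squares of log2(y + pc) on log2(x + pc) over peaks."""
    x = _logged(table, x_sample)
    y = _logged(table, y_sample)
    if len(x) < 2:
        raise ValueError("degenerate fit: need >= 2 intervals")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: zero variance in x")
    res = stats.linregress(x, y)
    return DensityFit(slope=res.slope, intercept=res.intercept, r=res.rvalue, n=len(x))


def global_fold_change(
    x_sample: str,
    y_sample: str,
    table: DensityTable,
    method: str = "mean_log_ratio",
) -> float:
    """Global percent change of y vs x over all peaks.

    ``mean_log_ratio`` (default) returns ``100 * (2**m - 1)`` where ``m`` is
    the mean per-peak ``log2((y + pc) / (x + pc))`` — robust to peak-length
    composition.  ``ratio_of_means`` returns the percent change of the
    summed normalized signal instead.  Antisymmetric in log space: swapping
    the samples negates ``m``.
    """
    pc = table.pseudocount
    x = table.column(x_sample) + pc
    y = table.column(y_sample) + pc
    if method == "mean_log_ratio":
        m = float(np.mean(np.log2(y / x)))
        return 100.0 * (2.0**m - 1.0)
    if method == "ratio_of_means":
        return 100.0 * (float(y.sum()) / float(x.sum()) - 1.0)
    raise ValueError(f"unknown method {method!r}")


def density_ratio_table(
    assay_tables: dict[str, DensityTable],
    x_sample: str,
    y_sample: str,
) -> pd.DataFrame:
    """Per-assay distribution summary of per-interval log2 ratios (y vs x).

    One row per assay with the median, quartiles and mean of
    ``log2((y + pc) / (x + pc))`` — the numbers a multi-assay density-ratio
    boxplot draws.  Assays with no intervals are skipped with a warning.
    """
    rows = []
    for assay, table in assay_tables.items():
        if len(table.interval_ids) < 1:
            warnings.warn(f"assay {assay!r} has no intervals; skipped", stacklevel=2)
            continue
        pc = table.pseudocount
        ratios = np.log2((table.column(y_sample) + pc) / (table.column(x_sample) + pc))
        q1, med, q3 = np.percentile(ratios, [25, 50, 75])
        rows.append(
            {
                "assay": assay,
                "n": len(ratios),
                "median_log2_ratio": med,
                "q1_log2_ratio": q1,
                "q3_log2_ratio": q3,
                "mean_log2_ratio": float(ratios.mean()),
            }
        )
    return pd.DataFrame(rows).set_index("assay") if rows else pd.DataFrame()
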