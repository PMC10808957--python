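"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its spec (which carries the seed):
re-running with the same spec is byte-identical.  Generators plant known
parameters — Venn structure, motif-containment fractions, a global
density ratio, differential-expression labels, a variance-compression
factor — that the corresponding analysis stages must recover.  Defaults
encode the reference conditions the pipeline is validated against: a
two-condition comparison with the reference peak-set Venn structure (17,134 / 34,263 peaks, 16,550 shared),
motif planting at 8.49% / 31.31%, a 1.25x global density ratio, four
RNA-seq replicates per group, and 2,214 up- / 1,717 down-regulated genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .accessibility import DensityTable
from .annotation import GeneModel
from .intervals import GenomicInterval
from .io import CountsTable, PeakFile, PfmRecord, ValidationError

__all__ = [
    "GenomeSpec",
    "GeneSpec",
    "PeakSpec",
    "MotifSpec",
    "CountsSpec",
    "DensitySpec",
    "SimSpec",
    "Genome",
    "SimulatedCounts",
    "PlantedMotifs",
    "make_genome",
    "make_peak_sets",
    "plant_motifs",
    "make_counts",
    "make_density",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GenomeSpec:
    n_chroms: int = 4
    chrom_length: int = 10_000_000


@dataclass(frozen=True)
class GeneSpec:
    n_genes: int = 200
    gene_length: int = 5_000
    n_exons: int = 3


@dataclass(frozen=True)
class PeakSpec:
    """Two-condition peak structure; defaults are the reference Venn counts."""

    a_total: int = 17_134
    b_total: int = 34_263
    shared: int = 16_550
    length: int = 200
    promoter_fraction: float = 0.0
    promoter_window: tuple[int, int] = (2000, 500)


@dataclass(frozen=True)
class MotifSpec:
    plant_fraction_a: float = 0.0849
    plant_fraction_b: float = 0.3131


@dataclass(frozen=True)
class CountsSpec:
    """Negative-binomial RNA-seq counts with planted DE and compression.

    ``de_up``/``de_down`` genes get a +/- ``lfc_mean`` log2 shift in KO;
    DE labels are planted only among genes whose baseline mean is at least
    ``min_de_baseline`` (an undetectably expressed gene cannot carry a
    recoverable fold change).  ``compression_gamma`` shrinks KO log-means
    toward their median, emulating dynamic-range compression; 1.0 = none.
    ``ko_only`` appends genes expressed in KO but silent in WT.
    """

    n_genes: int = 15_000
    n_reps: int = 4
    nb_dispersion: float = 0.05
    de_up: int = 2_214
    de_down: int = 1_717
    lfc_mean: float = 2.0
    compression_gamma: float = 1.0
    ko_only: int = 0
    baseline_meanlog: float = math.log(50.0)
    baseline_sdlog: float = 1.2
    min_de_baseline: float = 10.0


@dataclass(frozen=True)
class DensitySpec:
    """Paired per-peak densities with a planted global ratio.

    ``x`` is log-normal; ``y = global_ratio * x * exp(eps)`` with
    ``eps ~ N(0, lognormal_sd^2)``.  Values are already-normalized
    densities (never zero), so the table carries a near-zero pseudocount.
    """

    n_peaks: int = 20_000
    global_ratio: float = 1.25
    lognormal_sd: float = 0.25
    meanlog: float = math.log(50.0)
    sdlog: float = 1.0
    pseudocount: float = 0.01


@dataclass(frozen=True)
class SimSpec:
    seed: int = 0
    genome: GenomeSpec = GenomeSpec()
    genes: GeneSpec = GeneSpec()
    peaks: PeakSpec = PeakSpec()
    motifs: MotifSpec = MotifSpec()
    counts: CountsSpec = CountsSpec()
    density: DensitySpec = DensitySpec()


def _rng(spec: SimSpec, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator
    return np.random.default_rng([spec.seed, stream])


@dataclass
class Genome:
    sequences: dict[str, str]
    genes: list[GeneModel]

    @property
    def sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def chrom_sizes(spec: SimSpec) -> dict[str, int]:
    """Chromosome size map implied by the genome spec (no sequence needed)."""
    return {f"chr{i + 1}": spec.genome.chrom_length for i in range(spec.genome.n_chroms)}


def make_genome(spec: SimSpec) -> Genome:
    """Uniform-background genome plus non-overlapping, strand-alternating genes.

    Each chromosome gets an even share of genes on a regular pitch with a
    seeded jitter; each gene has ``n_exons`` equal exons separated by equal
    introns.  Infeasible packing (genes cannot fit) is an error.
    """
    rng = _rng(spec, 1)
    g, gn = spec.genome, spec.genes
    sizes = chrom_sizes(spec)
    seqs = {}
    for chrom, size in sizes.items():
        idx = rng.integers(0, 4, size=size, dtype=np.uint8)
        seqs[chrom] = _BASES[idx].tobytes().decode("ascii")

    genes: list[GeneModel] = []
    if gn.n_genes:
        per = [gn.n_genes // g.n_chroms] * g.n_chroms
        for i in range(gn.n_genes % g.n_chroms):
            per[i] += 1
        gi = 0
        for ci, (chrom, size) in enumerate(sizes.items()):
            k = per[ci]
            if k == 0:
                continue
            if k * gn.gene_length > size:
                raise ValidationError(
                    f"cannot pack {k} genes of {gn.gene_length} bp into {chrom} ({size} bp)"
                )
            pitch = size // (k + 1)
            jitter_max = max(1, min(pitch - gn.gene_length, pitch // 4))
            for j in range(k):
                start = (j + 1) * pitch - gn.gene_length // 2
                start += int(rng.integers(0, jitter_max)) - jitter_max // 2
                start = max(0, min(start, size - gn.gene_length))
                end = start + gn.gene_length
                strand = "+" if gi % 2 == 0 else "-"
                seg = gn.gene_length // (2 * gn.n_exons - 1)
                exons = [
                    (start + 2 * e * seg, start + (2 * e + 1) * seg)
                    for e in range(gn.n_exons)
                ]
                genes.append(
                    GeneModel(
                        gene_id=f"gene_{gi:05d}", chrom=chrom, strand=strand,
                        start=start, end=end, exons=exons,
                    )
                )
                gi += 1
    return Genome(sequences=seqs, genes=genes)


def make_peak_sets(
    spec: SimSpec,
    sizes: Optional[dict[str, int]] = None,
    gene_models: Optional[Sequence[GeneModel]] = None,
) -> tuple[PeakFile, PeakFile]:
    """Two peak sets with an exact, planted Venn structure.

    Exactly ``shared`` one-to-one overlapping A/B pairs (offset by half a
    peak length) plus ``a_total - shared`` A-only and ``b_total - shared``
    B-only peaks, all placed in disjoint genomic slots so no other overlap
    can occur.  With ``promoter_fraction > 0`` and gene models supplied,
    that fraction of slots is centered on gene TSSs (one slot per gene);
    grid slots falling inside any promoter window are excluded so the
    planted promoter fraction is clean.
    """
    rng = _rng(spec, 2)
    p = spec.peaks
    if p.shared > min(p.a_total, p.b_total):
        raise ValidationError("shared exceeds a set total")
    if sizes is None:
        sizes = chrom_sizes(spec)
    L = p.length
    pitch = 3 * L
    n_pairs = p.shared
    n_a_only = p.a_total - p.shared
    n_b_only = p.b_total - p.shared
    n_slots = n_pairs + n_a_only + n_b_only

    slots: list[tuple[str, int]] = []
    exclusion: dict[str, list[tuple[int, int]]] = {}
    n_prom = round(p.promoter_fraction * n_slots)
    if n_prom:
        if not gene_models:
            raise ValidationError("promoter_fraction > 0 requires gene models")
        up, down = p.promoter_window
        usable = [
            gm for gm in gene_models
            if gm.chrom in sizes and gm.tss - L >= 0 and gm.tss + 2 * L <= sizes[gm.chrom]
        ]
        if n_prom > len(usable):
            raise ValidationError(
                f"need {n_prom} promoter slots but only {len(usable)} usable genes"
            )
        chosen = rng.choice(len(usable), size=n_prom, replace=False)
        for i in chosen:
            gm = usable[int(i)]
            slots.append((gm.chrom, gm.tss - L // 2))
    if gene_models:
        up, down = p.promoter_window
        for gm in gene_models:
            lo = (gm.tss - up if gm.strand == "+" else gm.tss - down) - 2 * L
            hi = (gm.tss + down if gm.strand == "+" else gm.tss + up) + 2 * L
            exclusion.setdefault(gm.chrom, []).append((lo, hi))

    n_grid_needed = n_slots - len(slots)
    grid: list[tuple[str, int]] = []
    for chrom, size in sizes.items():
        zones = sorted(exclusion.get(chrom, []))
        zi = 0
        pos = L
        while pos + 2 * L <= size:
            while zi < len(zones) and zones[zi][1] <= pos:
                zi += 1
            if zi < len(zones) and zones[zi][0] < pos + 2 * L:
                pos += pitch
                continue
            grid.append((chrom, pos))
            pos += pitch
    if len(grid) < n_grid_needed:
        raise ValidationError(
            f"genome too small: {n_grid_needed} grid slots needed, {len(grid)} available"
        )
    grid_idx = rng.choice(len(grid), size=n_grid_needed, replace=False)
    slots.extend(grid[int(i)] for i in grid_idx)
    order = rng.permutation(n_slots)
    slots = [slots[int(i)] for i in order]

    a_records: list[GenomicInterval] = []
    b_records: list[GenomicInterval] = []
    for k, (chrom, s) in enumerate(slots[:n_pairs]):
        a_records.append(GenomicInterval(chrom, s, s + L, name=f"A_shared_{k:06d}"))
        b_records.append(
            GenomicInterval(chrom, s + L // 2, s + L // 2 + L, name=f"B_shared_{k:06d}")
        )
    for k, (chrom, s) in enumerate(slots[n_pairs : n_pairs + n_a_only]):
        a_records.append(GenomicInterval(chrom, s, s + L, name=f"A_only_{k:06d}"))
    for k, (chrom, s) in enumerate(slots[n_pairs + n_a_only :]):
        b_records.append(GenomicInterval(chrom, s, s + L, name=f"B_only_{k:06d}"))
    return (
        PeakFile(path=None, dialect="BED6", records=a_records),
        PeakFile(path=None, dialect="BED6", records=b_records),
    )


@dataclass
class PlantedMotifs:
    """Edited genome plus the exact planted truth per peak set."""

    genome: dict[str, str]
    planted_a: list[str]  # names of A peaks carrying the consensus
    planted_b: list[str]

    @property
    def n_a(self) -> int:
        return len(self.planted_a)

    @property
    def n_b(self) -> int:
        return len(self.planted_b)


def plant_motifs(
    spec: SimSpec,
    genome: dict[str, str],
    peaks_a: PeakFile,
    peaks_b: PeakFile,
    pfm: PfmRecord,
) -> PlantedMotifs:
    """Write the motif consensus at the center of a planted fraction of peaks.

    Exactly ``round(plant_fraction * n)`` peaks per set, chosen by the
    seeded stream, receive the consensus; all other peaks keep the
    background sequence.  Planting writes the consensus (not a PFM sample)
    so detection is certain at any reasonable threshold.  Peak sets
    sharing genomic slots would cross-contaminate; use disjoint sets
    (``shared = 0``) for exact containment bookkeeping.
    """
    rng = _rng(spec, 3)
    consensus = pfm.consensus() if hasattr(pfm, "consensus") else str(pfm)
    w = len(consensus)
    if w >= spec.peaks.length:
        raise ValidationError("motif width must be smaller than peak length")
    edits = {c: bytearray(s, "ascii") for c, s in genome.items()}
    planted: dict[str, list[str]] = {"a": [], "b": []}
    for key, peaks, frac in (
        ("a", peaks_a, spec.motifs.plant_fraction_a),
        ("b", peaks_b, spec.motifs.plant_fraction_b),
    ):
        n = len(peaks.records)
        k = round(frac * n)
        if k == 0:
            continue
        chosen = rng.choice(n, size=k, replace=False)
        for i in sorted(int(j) for j in chosen):
            iv = peaks.records[i]
            pos = iv.start + (len(iv) - w) // 2
            if iv.chrom not in edits or pos + w > len(edits[iv.chrom]):
                raise ValidationError(f"peak {iv.name} outside genome")
            edits[iv.chrom][pos : pos + w] = consensus.encode("ascii")
            planted[key].append(iv.name or f"{key}_{i}")
    return PlantedMotifs(
        genome={c: b.decode("ascii") for c, b in edits.items()},
        planted_a=planted["a"],
        planted_b=planted["b"],
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion > 0:
        size = 1.0 / dispersion
        p = size / (size + mean[pos])
        out[pos] = rng.negative_binomial(size, p)
    else:
        out[pos] = rng.poisson(mean[pos])
    return out


@dataclass
class SimulatedCounts:
    table: CountsTable
    group_of: dict[str, str]
    truth: pd.DataFrame  # index gene_id; true_class, true_lfc, baseline_mean


def make_counts(spec: SimSpec) -> SimulatedCounts:
    """RNA-seq-like counts with planted DE, compression, and KO-only genes.

    Baseline means are log-normal; WT counts are NB around the baseline;
    KO means apply the planted log2 shifts, then the whole KO log-mean
    vector is shrunk toward its median by ``compression_gamma``.  Truth
    labels (up / down / null / ko_only) are returned for recovery tests.
    """
    rng = _rng(spec, 4)
    c = spec.counts
    if c.n_reps < 2:
        raise ValidationError("need >= 2 replicates per group")
    log_mu = rng.normal(c.baseline_meanlog, c.baseline_sdlog, size=c.n_genes)
    mu = np.exp(log_mu)
    true_lfc = np.zeros(c.n_genes)
    true_class = np.array(["null"] * c.n_genes, dtype=object)
    eligible = np.nonzero(mu >= c.min_de_baseline)[0]
    n_de = c.de_up + c.de_down
    if n_de > len(eligible):
        raise ValidationError(
            f"cannot plant {n_de} DE genes among {len(eligible)} sufficiently expressed"
        )
    if n_de:
        chosen = rng.choice(eligible, size=n_de, replace=False)
        up_idx, down_idx = chosen[: c.de_up], chosen[c.de_up :]
        true_lfc[up_idx] = c.lfc_mean
        true_lfc[down_idx] = -c.lfc_mean
        true_class[up_idx] = "up"
        true_class[down_idx] = "down"

    ko_log_mu = log_mu + true_lfc * math.log(2.0)
    if c.compression_gamma < 1.0:
        # shrink log-means toward the center that preserves the library size
        # (sum of means): c* = [lse(v) - lse(g*v)] / (1 - g).  Shrinking
        # toward the median instead would shrink the library and CPM
        # renormalization would shift the whole KO profile upward.
        from scipy.special import logsumexp

        g = c.compression_gamma
        center = (logsumexp(ko_log_mu) - logsumexp(g * ko_log_mu)) / (1.0 - g)
        ko_log_mu = center + g * (ko_log_mu - center)
    mu_wt = mu
    mu_ko = np.exp(ko_log_mu)
    gene_ids = [f"gene_{i:05d}" for i in range(c.n_genes)]

    if c.ko_only:
        gene_ids += [f"koonly_{i:04d}" for i in range(c.ko_only)]
        extra = np.exp(rng.normal(c.baseline_meanlog + 1.0, 0.25, size=c.ko_only))
        mu_wt = np.concatenate([mu_wt, np.zeros(c.ko_only)])
        mu_ko = np.concatenate([mu_ko, extra])
        true_lfc = np.concatenate([true_lfc, np.full(c.ko_only, np.inf)])
        true_class = np.concatenate([true_class, np.array(["ko_only"] * c.ko_only, dtype=object)])

    n_total = len(gene_ids)
    counts = np.zeros((n_total, 2 * c.n_reps), dtype=np.int64)
    sample_ids = [f"WT_{r + 1}" for r in range(c.n_reps)] + [
        f"KO_{r + 1}" for r in range(c.n_reps)
    ]
    for r in range(c.n_reps):
        counts[:, r] = _nb_draw(rng, mu_wt, c.nb_dispersion)
    for r in range(c.n_reps):
        counts[:, c.n_reps + r] = _nb_draw(rng, mu_ko, c.nb_dispersion)
    group_of = {s: ("WT" if s.startswith("WT") else "KO") for s in sample_ids}
    truth = pd.DataFrame(
        {
            "true_class": true_class,
            "true_lfc": true_lfc,
            "baseline_mean": np.concatenate([mu, np.zeros(n_total - c.n_genes)])
            if n_total > c.n_genes
            else mu,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return SimulatedCounts(
        table=CountsTable(gene_ids=gene_ids, sample_ids=sample_ids, counts=counts),
        group_of=group_of,
        truth=truth,
    )


def make_density(spec: SimSpec, interval_ids: Optional[Sequence[str]] = None) -> DensityTable:
    """Paired per-peak densities with a planted global KO/WT ratio.

    Columns are named WT and KO; values are already-normalized densities
    (library sizes of 1e6), never zero, so the table carries the spec's
    near-zero pseudocount and ``global_fold_change`` recovers the planted
    ratio without pseudocount shrinkage.
    """
    rng = _rng(spec, 5)
    d = spec.density
    if d.global_ratio <= 0:
        raise ValidationError("global_ratio must be > 0")
    n = len(interval_ids) if interval_ids is not None else d.n_peaks
    x = rng.lognormal(d.meanlog, d.sdlog, size=n)
    eps = rng.normal(0.0, d.lognormal_sd, size=n)
    y = d.global_ratio * x * np.exp(eps)
    ids = list(interval_ids) if interval_ids is not None else [f"peak_{i:06d}" for i in range(n)]
    raw = np.column_stack([x, y])
    return DensityTable(
        interval_ids=ids,
        samples=["WT", "KO"],
        raw=raw,
        normalized=raw.copy(),
        pseudocount=d.pseudocount,
    )
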