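"""Readers and writers for every on-disk format the pipeline touches.

Formats: BED3/BED6/narrowPeak (UCSC conventions, 0-based half-open),
FASTA, GTF-lite (a 9-column GTF subset where only ``gene`` and ``exon``
features are consumed; 1-based inclusive coordinates converted on read),
JASPAR-style PFM text, and gene x sample counts TSV.

Chromosome names are compared by exact string match; no "chr" aliasing.
Every writer/reader pair round-trips valid inputs field-for-field.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .annotation import GeneModel

__all__ = [
    "ParseError",
    "ValidationError",
    "PeakFile",
    "CountsTable",
    "PfmRecord",
    "NarrowPeakExtra",
    "read_bed",
    "write_bed",
    "read_counts",
    "write_counts",
    "read_pfm",
    "write_pfm",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gene_models",
]

PathLike = Union[str, Path]

DIALECTS = ("BED3", "BED6", "narrowPeak")

BASES = "ACGT"
_SEQ_OK = re.compile(r"^[ACGTN]*$")


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed content violates a documented invariant."""


@dataclass(frozen=True)
class NarrowPeakExtra:
    """Columns 7-10 of a narrowPeak record: signal, -log10(p), -log10(q), summit offset."""

    signal_value: float = 0.0
    p_value: float = -1.0
    q_value: float = -1.0
    peak: int = -1


@dataclass
class PeakFile:
    """An ordered peak list with its on-disk dialect.

    For ``narrowPeak`` files, ``extras[i]`` carries the four columns beyond
    BED6 for ``records[i]``; for BED3/BED6 it is ``None``.
    """

    path: Optional[Path]
    dialect: str
    records: list[GenomicInterval]
    extras: Optional[list[NarrowPeakExtra]] = None

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValidationError(f"unknown dialect {self.dialect!r}")
        if self.dialect == "narrowPeak":
            if self.extras is None:
                self.extras = [NarrowPeakExtra() for _ in self.records]
            if len(self.extras) != len(self.records):
                raise ValidationError("extras must align with records")

    def __len__(self) -> int:
        return len(self.records)


def _num(s: str) -> str:
    """Serialize a score: integral values print without a decimal point."""
    f = float(s) if not isinstance(s, (int, float)) else s
    return str(int(f)) if float(f).is_integer() else repr(float(f))


def read_bed(path: PathLike, dialect: str = "BED6") -> PeakFile:
    """Read a BED3/BED6/narrowPeak file into an ordered :class:`PeakFile`.

    Coordinates are taken as 0-based half-open.  A record with
    ``start >= end`` raises :class:`ValidationError`; a malformed line
    raises :class:`ParseError` naming the line number.
    """
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}")
    min_cols = {"BED3": 3, "BED6": 6, "narrowPeak": 10}[dialect]
    records: list[GenomicInterval] = []
    extras: list[NarrowPeakExtra] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {min_cols} tab-separated "
                    f"fields for {dialect}, got {len(fields)}"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates: {exc}") from None
            name = score = None
            strand = "."
            if dialect != "BED3" and len(fields) >= 6:
                name = fields[3] if fields[3] != "." else None
                try:
                    score = float(fields[4]) if fields[4] != "." else None
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: bad score {fields[4]!r}") from None
                strand = fields[5]
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: degenerate interval [{start},{end})"
                )
            try:
                records.append(
                    GenomicInterval(chrom, start, end, strand=strand, name=name, score=score)
                )
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
            if dialect == "narrowPeak":
                try:
                    extras.append(
                        NarrowPeakExtra(
                            signal_value=float(fields[6]),
                            p_value=float(fields[7]),
                            q_value=float(fields[8]),
                            peak=int(fields[9]),
                        )
                    )
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad narrowPeak column: {exc}") from None
    return PeakFile(
        path=Path(path),
        dialect=dialect,
        records=records,
        extras=extras if dialect == "narrowPeak" else None,
    )


def write_bed(peaks: PeakFile, path: PathLike, dialect: Optional[str] = None) -> Path:
    """Write a :class:`PeakFile`; ``read_bed(write_bed(x))`` reproduces ``x``."""
    dialect = dialect or peaks.dialect
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks.records):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if dialect != "BED3":
                cols += [
                    iv.name if iv.name is not None else ".",
                    _num(iv.score) if iv.score is not None else ".",
                    iv.strand,
                ]
            if dialect == "narrowPeak":
                ex = peaks.extras[i] if peaks.extras else NarrowPeakExtra()
                cols += [_num(ex.signal_value), _num(ex.p_value), _num(ex.q_value), str(ex.peak)]
            fh.write("\t".join(cols) + "\n")
    return path


@dataclass
class CountsTable:
    """A gene x sample matrix of non-negative integer read counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_genes, n_samples) integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("counts shape does not match gene/sample ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValidationError("counts must be integers")
        if (self.counts < 0).any():
            raise ValidationError("counts must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


def read_counts(path: PathLike) -> CountsTable:
    """Read a counts TSV: sample ids on the first row, gene ids in the first column.

    The header cell (0,0) is ignored.  Non-integer cells raise
    :class:`ParseError`; duplicate gene ids raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids: {dups[:5]}")
    try:
        mat = df.astype(np.int64)
    except ValueError:
        raise ParseError(f"{path}: counts must be integers") from None
    if (mat.values < 0).any():
        raise ValidationError(f"{path}: counts must be >= 0")
    return CountsTable(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        counts=mat.values,
    )


def write_counts(table: CountsTable, path: PathLike) -> Path:
    path = Path(path)
    table.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    return path


@dataclass
class PfmRecord:
    """A position frequency matrix: 4 x w non-negative counts, rows A, C, G, T."""

    motif_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.ndim != 2 or self.matrix.shape[1] < 1:
            raise ValidationError(f"PFM must be 4 x w with w >= 1, got {self.matrix.shape}")
        if (self.matrix < 0).any():
            raise ValidationError("PFM counts must be >= 0")
        if (self.matrix.sum(axis=0) == 0).any():
            raise ValidationError("PFM has an all-zero column")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))


_PFM_ROW = re.compile(r"^([ACGT])\s*\[?\s*([0-9.\s]+?)\s*\]?\s*$")


def read_pfm(path: PathLike) -> list[PfmRecord]:
    """Parse JASPAR-style PFM text: ``>id name`` headers, then four base rows.

    Rows may be bracketed (``A [ 3 10 2 ]``) or bare whitespace-separated
    numbers in A, C, G, T order.
    """
    records: list[PfmRecord] = []
    motif_id: Optional[str] = None
    rows: dict[str, list[float]] = {}
    bare: list[list[float]] = []

    def flush(lineno: int) -> None:
        nonlocal rows, bare
        if motif_id is None:
            return
        if rows:
            if set(rows) != set(BASES):
                raise ParseError(f"{path}:{lineno}: motif {motif_id} missing base rows")
            mat = [rows[b] for b in BASES]
        elif bare:
            if len(bare) != 4:
                raise ParseError(f"{path}:{lineno}: motif {motif_id} needs 4 rows, got {len(bare)}")
            mat = bare
        else:
            raise ParseError(f"{path}:{lineno}: motif {motif_id} has no matrix rows")
        records.append(PfmRecord(motif_id=motif_id, matrix=np.array(mat)))
        rows, bare = {}, []

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                motif_id = line[1:].split()[0]
                continue
            m = _PFM_ROW.match(line)
            if m:
                rows[m.group(1)] = [float(x) for x in m.group(2).split()]
            else:
                try:
                    bare.append([float(x) for x in line.split()])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: unparseable PFM row {line!r}") from None
        flush(lineno)
    return records


def write_pfm(records: Sequence[PfmRecord], path: PathLike) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.motif_id}\n")
            for i, base in enumerate(BASES):
                vals = " ".join(_num(v) for v in rec.matrix[i])
                fh.write(f"{base} [ {vals} ]\n")
    return path


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read FASTA into ``{chrom: uppercase sequence}``.

    Symbols outside A/C/G/T/N raise :class:`ValidationError`.
    """
    seqs: dict[str, str] = {}
    name: Optional[str] = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
        if name is not None:
            seqs[name] = "".join(chunks)
    for chrom, seq in seqs.items():
        if not _SEQ_OK.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValidationError(f"{path}: chromosome {chrom} has symbols {bad} outside ACGTN")
    return seqs


def write_fasta(seqs: dict[str, str], path: PathLike, width: int = 60) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def read_gene_models(path: PathLike) -> list[GeneModel]:
    """Read gene models from GTF-lite (9-column GTF; only gene/exon consumed).

    GTF coordinates are 1-based inclusive and converted to 0-based half-open
    on read.  A gene with no exon lines is treated as single-exon over its
    whole span.
    """
    spans: dict[str, tuple[str, int, int, str]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = fields
            if feature not in ("gene", "exon"):
                continue
            m = _GENE_ID.search(attrs)
            if not m:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            gid = m.group(1)
            try:
                start, end = int(start1) - 1, int(end1)  # 1-based inclusive -> half-open
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates: {exc}") from None
            if strand not in ("+", "-"):
                raise ValidationError(f"{path}:{lineno}: gene strand must be + or -")
            if feature == "gene":
                if gid in spans:
                    raise ValidationError(f"{path}:{lineno}: duplicate gene {gid}")
                spans[gid] = (chrom, start, end, strand)
                order.append(gid)
            else:
                exons.setdefault(gid, []).append((start, end))
    models = []
    for gid in order:
        chrom, start, end, strand = spans[gid]
        ex = sorted(exons.get(gid, [(start, end)]))
        models.append(
            GeneModel(gene_id=gid, chrom=chrom, strand=strand, start=start, end=end, exons=ex)
        )
    return models


def write_gene_models(models: Sequence[GeneModel], path: PathLike, source: str = "chromshift") -> Path:
    """Write gene models as GTF-lite (1-based inclusive, gene + exon lines)."""
    path = Path(path)
    with open(path, "w") as fh:
        for gm in models:
            attrs = f'gene_id "{gm.gene_id}";'
            fh.write(
                "\t".join(
                    [gm.chrom, source, "gene", str(gm.start + 1), str(gm.end), ".", gm.strand, ".", attrs]
                )
                + "\n"
            )
            for es, ee in gm.exons:
                fh.write(
                    "\t".join(
                        [gm.chrom, source, "exon", str(es + 1), str(ee), ".", gm.strand, ".", attrs]
                    )
                    + "\n"
                )
    return path
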