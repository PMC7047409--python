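"""Readers and writers for the on-disk formats used across the pipeline.

One strict dialect per format:

* methylC text: ``chrom  start  end  context  ratio  strand  coverage``
  (tab-separated, 0-based half-open, ratio in [0, 1]).  Only ``CG`` context
  is retained and symmetric-strand records of one CpG dyad are collapsed
  into a single record anchored at the + strand cytosine.
* BED3/BED6 and bedGraph, 0-based half-open.
* GTF, 1-based closed on disk, converted to 0-based half-open on read;
  only ``gene`` features and the ``gene_id``/``gene_name`` attributes are
  interpreted.
* MEME-like PWM text (``MOTIF`` blocks with a letter-probability matrix).
* TSV count matrices: genes x samples with a header row of sample names.

All in-memory coordinates are 0-based half-open; conversions happen only
here, at the I/O boundary.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "CpGRecord",
    "Gene",
    "Pwm",
    "FormatError",
    "read_methylc",
    "write_methylc",
    "read_intervals",
    "write_bed",
    "read_genes_gtf",
    "write_gtf",
    "read_pwm",
    "write_pwm",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_fasta",
    "write_fasta",
]

_BASES = "ACGT"


class FormatError(ValueError):
    """Raised on malformed input; carries the file location in the message."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must be > start, got [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class CpGRecord:
    """Strand-collapsed methylation counts for one CpG dyad.

    ``pos`` is the 0-based position of the cytosine on the + strand;
    counts from the symmetric - strand cytosine at ``pos + 1`` are summed
    into the same record.
    """

    chrom: str
    pos: int
    meth: int
    total: int

    def __post_init__(self) -> None:
        if self.meth < 0 or self.total < 0:
            raise ValueError("counts must be non-negative")
        if self.meth > self.total:
            raise ValueError(f"meth {self.meth} exceeds total {self.total}")

    @property
    def ratio(self) -> float:
        return self.meth / self.total if self.total else math.nan


@dataclass(frozen=True)
class Gene:
    gene_id: str
    interval: GenomicInterval
    gene_name: str = ""

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (0-based)."""
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start


@dataclass
class Pwm:
    """Position probability matrix over A, C, G, T with a background model."""

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if len(self) < 4:
            raise ValueError("PWM must have length >= 4")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        return Pwm(
            name=self.name,
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
        )


# ---------------------------------------------------------------------------
# methylC
# ---------------------------------------------------------------------------

def read_methylc(path: str | Path, contexts: frozenset[str] = frozenset({"CG"})) -> list[CpGRecord]:
    """Read a methylC text file, keeping CG context and collapsing dyads.

    A + strand record at position ``p`` and a - strand record at ``p + 1``
    describe the same CpG dyad; their counts are summed into one record
    anchored at ``p``.  A lone - strand record is anchored at ``p - 1``.
    """
    counts: dict[tuple[str, int], list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise FormatError(
                    f"{path}:{lineno}: expected 7 tab-separated fields, got {len(fields)}"
                )
            chrom, start_s, end_s, context, ratio_s, strand, cov_s = fields
            try:
                start = int(start_s)
                end = int(end_s)
                ratio = float(ratio_s)
                cov = int(cov_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if end != start + 1:
                raise FormatError(f"{path}:{lineno}: end must equal start + 1")
            if not 0.0 <= ratio <= 1.0:
                raise FormatError(f"{path}:{lineno}: ratio {ratio} outside [0, 1]")
            if cov < 0:
                raise FormatError(f"{path}:{lineno}: negative coverage")
            if strand not in {"+", "-", "."}:
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            if context not in contexts:
                continue
            pos = start - 1 if strand == "-" else start
            if pos < 0:
                raise FormatError(f"{path}:{lineno}: - strand record at position 0")
            meth = int(round(ratio * cov))
            key = (chrom, pos)
            if key in counts:
                counts[key][0] += meth
                counts[key][1] += cov
            else:
                counts[key] = [meth, cov]
    return [
        CpGRecord(chrom, pos, m, t)
        for (chrom, pos), (m, t) in sorted(counts.items())
    ]


def write_methylc(records: Iterable[CpGRecord], path: str | Path) -> None:
    """Write strand-collapsed records as single + strand methylC lines."""
    with open(path, "w") as fh:
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
            ratio = rec.meth / rec.total if rec.total else 0.0
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.pos + 1}\tCG\t{ratio:.10g}\t+\t{rec.total}\n"
            )


# ---------------------------------------------------------------------------
# BED / bedGraph / GTF
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path, format: str = "BED") -> list[tuple[GenomicInterval, dict]]:
    """Read intervals from BED/bedGraph/GTF, sorted by (chrom, start).

    Returns ``(interval, extras)`` pairs.  Extras hold ``name``/``score``
    for BED6, ``value`` for bedGraph, and ``gene_id``/``gene_name``/``tss``
    for GTF gene records.
    """
    fmt = format.upper()
    if fmt == "GTF":
        return [
            (g.interval, {"gene_id": g.gene_id, "gene_name": g.gene_name, "tss": g.tss})
            for g in read_genes_gtf(path)
        ]
    out: list[tuple[GenomicInterval, dict]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 fields")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if end <= start or start < 0:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            extras: dict = {}
            strand = "."
            if fmt == "BEDGRAPH":
                if len(fields) < 4:
                    raise FormatError(f"{path}:{lineno}: bedGraph needs a value column")
                extras["value"] = float(fields[3])
            else:
                if len(fields) >= 4:
                    extras["name"] = fields[3]
                if len(fields) >= 5 and fields[4] != ".":
                    extras["score"] = float(fields[4])
                if len(fields) >= 6:
                    strand = fields[5]
            out.append((GenomicInterval(chrom, start, end, strand), extras))
    out.sort(key=lambda pair: (pair[0].chrom, pair[0].start, pair[0].end))
    return out


def write_bed(intervals: Iterable[tuple[GenomicInterval, dict]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, extras in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            name = extras.get("name")
            score = extras.get("score")
            if name is not None or score is not None or iv.strand != ".":
                cols.append(str(name if name is not None else "."))
                cols.append("." if score is None else f"{score:.6g}")
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_genes_gtf(path: str | Path) -> list[Gene]:
    """Read gene features from a GTF file (1-based closed -> half-open)."""
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "gene":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            start, end = start1 - 1, end1
            if end <= start or start < 0:
                raise FormatError(f"{path}:{lineno}: invalid interval {start1}..{end1}")
            attr = dict(_ATTR_RE.findall(attrs))
            if "gene_id" not in attr:
                raise FormatError(f"{path}:{lineno}: gene feature without gene_id")
            genes.append(
                Gene(
                    gene_id=attr["gene_id"],
                    gene_name=attr.get("gene_name", attr["gene_id"]),
                    interval=GenomicInterval(chrom, start, end, strand),
                )
            )
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start))
    return genes


def write_gtf(genes: Iterable[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            fh.write(
                f"{iv.chrom}\tepikit\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# MEME-like PWM
# ---------------------------------------------------------------------------

def read_pwm(path: str | Path, pseudocount: float = 0.0) -> list[Pwm]:
    """Read MEME-style probability matrices.

    Each row gets ``pseudocount`` added to every entry and is renormalized,
    so zero-probability bases never produce -inf log-odds downstream.
    """
    motifs: list[Pwm] = []
    background = np.full(4, 0.25)
    name: str | None = None
    rows: list[list[float]] = []
    in_matrix = False

    def _flush(lineno: int) -> None:
        nonlocal name, rows, in_matrix
        if name is None:
            return
        if not rows:
            raise FormatError(f"{path}:{lineno}: motif {name} has no matrix rows")
        mat = np.asarray(rows, dtype=float)
        if np.any(mat.sum(axis=1) <= 0):
            raise FormatError(f"{path}:{lineno}: motif {name} has a zero-sum row")
        mat = mat + pseudocount
        mat = mat / mat.sum(axis=1, keepdims=True)
        motifs.append(Pwm(name=name, matrix=mat, background=background.copy(), pseudocount=pseudocount))
        name, rows, in_matrix = None, [], False

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith("MOTIF"):
                _flush(lineno)
                parts = stripped.split()
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: MOTIF line without a name")
                name = parts[1]
            elif stripped.startswith("Background letter frequencies"):
                in_matrix = False
            elif stripped.startswith("letter-probability matrix"):
                in_matrix = True
            elif name is not None and (in_matrix or _looks_numeric(stripped)):
                if not stripped:
                    continue
                try:
                    row = [float(x) for x in stripped.split()]
                except ValueError:
                    continue
                if len(row) == 4:
                    rows.append(row)
            elif name is None and _looks_numeric(stripped):
                row = [float(x) for x in stripped.split()]
                if len(row) == 4:
                    background = np.asarray(row, dtype=float)
                    background = background / background.sum()
        _flush(lineno)
    return motifs


def _looks_numeric(s: str) -> bool:
    if not s:
        return False
    try:
        [float(x) for x in s.split()]
        return True
    except ValueError:
        return False


def write_pwm(motifs: Sequence[Pwm], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        for pwm in motifs:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)}\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.8f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Count matrices / FASTA
# ---------------------------------------------------------------------------

def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes-x-samples count matrix with a header of sample names."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    return df


def write_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a name -> uppercase-sequence mapping."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
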