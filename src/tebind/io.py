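"""Shared genomic domain types and flat-file readers/writers.

All coordinates are 0-based half-open (BED convention). GTF input/output is
converted at the boundary. Every downstream stage consumes these types; no
other module re-parses files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "TECopy",
    "PeakRecord",
    "GeneRecord",
    "DEGRecord",
    "overlaps",
    "read_bed",
    "write_bed",
    "read_gtf_genes",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "ParseError",
]

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

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
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class TECopy:
    """One genomic copy of a transposable-element subfamily.

    ``consensus_length`` is the length of the subfamily's reference
    (consensus) sequence; it may be unset (None) at read time and attached
    later from a consensus table before filtering.
    """

    interval: GenomicInterval
    subfamily: str
    family: str
    te_class: str
    copy_id: str
    consensus_length: int | None = None

    def __post_init__(self) -> None:
        if self.consensus_length is not None and self.consensus_length <= 0:
            raise ValueError(
                f"copy {self.copy_id}: consensus_length must be > 0, "
                f"got {self.consensus_length}"
            )

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class PeakRecord:
    """A ChIP-seq peak with its summit (bp of maximal signal)."""

    interval: GenomicInterval
    summit: int
    peak_id: str
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.interval.start <= self.summit < self.interval.end:
            raise ValueError(
                f"peak {self.peak_id}: summit {self.summit} outside "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.score is not None and self.score < 0:
            raise ValueError(f"peak {self.peak_id}: score must be nonnegative")


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its transcription start site (5' end by strand)."""

    gene_id: str
    gene_name: str
    interval: GenomicInterval
    tss: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.tss == -1:
            tss = (
                self.interval.end - 1
                if self.interval.strand == "-"
                else self.interval.start
            )
            object.__setattr__(self, "tss", tss)
        expected = (
            self.interval.end - 1
            if self.interval.strand == "-"
            else self.interval.start
        )
        if self.tss != expected:
            raise ValueError(
                f"gene {self.gene_id}: tss {self.tss} inconsistent with "
                f"strand {self.interval.strand} (expected {expected})"
            )


@dataclass(frozen=True)
class DEGRecord:
    """A differentially expressed gene call for one contrast."""

    gene_id: str
    contrast: str
    log2_fold_change: float
    adjusted_p: float
    direction: Literal["up", "down"] = "up"

    def __post_init__(self) -> None:
        if not 0.0 <= self.adjusted_p <= 1.0:
            raise ValueError(f"adjusted_p must be in [0,1], got {self.adjusted_p}")
        if self.direction == "up" and self.log2_fold_change < 0:
            raise ValueError("direction 'up' requires log2_fold_change >= 0")
        if self.direction == "down" and self.log2_fold_change > 0:
            raise ValueError("direction 'down' requires log2_fold_change <= 0")


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one basepair."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


# ---------------------------------------------------------------------------
# BED / narrowPeak


def _parse_int(token: str, path: str, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer {what}: {token!r}") from None


def read_bed(
    path: str | Path, kind: Literal["te", "peak", "plain"] = "plain"
) -> list[TECopy] | list[PeakRecord] | list[GenomicInterval]:
    """Read a BED-family file into domain records.

    kind='plain'  -> BED3+ as GenomicInterval (strand from column 6 if present)
    kind='te'     -> BED6+ whose name column encodes subfamily:family:class
                     (an optional 4th field gives the copy_id; otherwise
                     ``<subfamily>.<line-index>`` is assigned)
    kind='peak'   -> ENCODE narrowPeak (10 columns; summit = start + col 10)
                     or BED6+ (summit = interval midpoint, rounded down)
    """
    path = Path(path)
    out: list = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            chrom = cols[0]
            start = _parse_int(cols[1], str(path), lineno, "start")
            end = _parse_int(cols[2], str(path), lineno, "end")
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end {end} <= start {start}")
            strand = cols[5] if len(cols) > 5 and cols[5] in STRANDS else "."
            iv = GenomicInterval(chrom, start, end, strand)
            if kind == "plain":
                out.append(iv)
            elif kind == "te":
                if len(cols) < 6:
                    raise ParseError(f"{path}:{lineno}: te BED needs >=6 columns")
                name_parts = cols[3].split(":")
                if len(name_parts) < 3:
                    raise ParseError(
                        f"{path}:{lineno}: name column must be "
                        f"subfamily:family:class, got {cols[3]!r}"
                    )
                subfam, fam, te_class = name_parts[:3]
                copy_id = (
                    name_parts[3] if len(name_parts) > 3 else f"{subfam}.{len(out)}"
                )
                out.append(TECopy(iv, subfam, fam, te_class, copy_id))
            elif kind == "peak":
                peak_id = cols[3] if len(cols) > 3 and cols[3] != "." else f"peak{len(out)}"
                score = None
                if len(cols) > 4 and cols[4] not in (".", ""):
                    score = float(cols[4])
                offset = -1
                if len(cols) >= 10:
                    offset = _parse_int(cols[9], str(path), lineno, "summit offset")
                summit = start + offset if offset >= 0 else (start + end) // 2
                out.append(PeakRecord(iv, summit, peak_id, score))
            else:
                raise ValueError(f"unknown kind {kind!r}")
    return out


def write_bed(records: Iterable, path: str | Path) -> None:
    """Write TECopy / PeakRecord / GenomicInterval records as BED/narrowPeak.

    TECopy -> BED6 with name subfamily:family:class:copy_id; PeakRecord ->
    10-column narrowPeak with the summit offset in column 10; plain intervals
    -> BED6. Round-trips losslessly through :func:`read_bed` for the fields
    each type defines.
    """
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            if isinstance(rec, TECopy):
                iv = rec.interval
                name = f"{rec.subfamily}:{rec.family}:{rec.te_class}:{rec.copy_id}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
                )
            elif isinstance(rec, PeakRecord):
                iv = rec.interval
                score = 0 if rec.score is None else rec.score
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.peak_id}\t{score}\t"
                    f"{iv.strand}\t0\t-1\t-1\t{rec.summit - iv.start}\n"
                )
            elif isinstance(rec, GenomicInterval):
                fh.write(
                    f"{rec.chrom}\t{rec.start}\t{rec.end}\t.\t0\t{rec.strand}\n"
                )
            else:
                raise TypeError(f"cannot write record of type {type(rec).__name__}")


# ---------------------------------------------------------------------------
# GTF

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_genes(path: str | Path) -> tuple[list[GeneRecord], int]:
    """Read gene features from an Ensembl-dialect GTF.

    GTF is 1-based closed; records are converted to 0-based half-open.
    One record per gene_id: the first gene feature wins, later duplicates
    are counted and dropped. Returns ``(genes, n_duplicates_dropped)``.
    """
    path = Path(path)
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    dups = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            if cols[2] != "gene":
                continue
            start1 = _parse_int(cols[3], str(path), lineno, "start")
            end1 = _parse_int(cols[4], str(path), lineno, "end")
            strand = cols[6] if cols[6] in STRANDS else "."
            attrs = dict(_GTF_ATTR.findall(cols[8]))
            if "gene_id" not in attrs:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            gid = attrs["gene_id"]
            if gid in seen:
                dups += 1
                continue
            seen.add(gid)
            iv = GenomicInterval(cols[0], start1 - 1, end1, strand)
            genes.append(GeneRecord(gid, attrs.get("gene_name", gid), iv))
    return genes, dups


def write_gtf_genes(records: Iterable[tuple[str, str, GenomicInterval]],
                    path: str | Path, source: str = "tebind") -> None:
    """Write (gene_id, gene_name, interval) triples as GTF gene features.

    Coordinates are converted back to 1-based closed on write.
    """
    with open(path, "w", newline="\n") as fh:
        for gene_id, gene_name, iv in records:
            attrs = f'gene_id "{gene_id}"; gene_name "{gene_name}";'
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into chrom -> uppercase sequence (non-ACGT kept as given)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"{path}: duplicate FASTA header {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def attach_consensus_lengths(
    copies: Iterable[TECopy], consensus: dict[str, int]
) -> list[TECopy]:
    """Return copies with consensus_length filled in from a subfamily table."""
    out = []
    for c in copies:
        if c.subfamily not in consensus:
            raise KeyError(f"no consensus length for subfamily {c.subfamily!r}")
        out.append(replace(c, consensus_length=int(consensus[c.subfamily])))
    return out


def read_consensus_table(path: str | Path) -> dict[str, int]:
    """Read a 2-column TSV (subfamily, consensus length in bp)."""
    table: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            if parts[0] == "subfamily":  # header
                continue
            table[parts[0]] = int(parts[1])
    return table


def write_consensus_table(table: dict[str, int], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("subfamily\tconsensus_length\n")
        for sub, length in table.items():
            fh.write(f"{sub}\t{length}\n")
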