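"""Consensus-length filtering of repeat copies and the subfamily registry.

Individual genomic copies of a TE subfamily accumulate indels; copies whose
genomic length deviates from the subfamily consensus by more than a tolerance
(default 20%) are treated as degenerate and removed before any enrichment
statistics. The registry aggregates, per subfamily, the copy count, mean copy
length and consensus length over the *filtered* universe, plus the genome
size — the quantities every expected-count null needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .io import GeneRecord, TECopy, write_gtf_genes

__all__ = ["SubfamilyInfo", "SubfamilyRegistry", "filter_te_copies", "build_registry"]

_REL_EPS = 1e-9  # guards exact-boundary integer lengths against float rounding


@dataclass(frozen=True)
class SubfamilyInfo:
    subfamily: str
    family: str
    te_class: str
    n_copies: int
    mean_length: float
    consensus_length: int

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ValueError(f"{self.subfamily}: registry requires >=1 copy")
        if self.mean_length <= 0:
            raise ValueError(f"{self.subfamily}: mean_length must be > 0")


@dataclass(frozen=True)
class SubfamilyRegistry:
    """Per-subfamily summary over the filtered copy universe."""

    subfamilies: dict[str, SubfamilyInfo]
    chrom_sizes: dict[str, int]

    @property
    def genome_size(self) -> int:
        """G: sum of chromosome lengths in bp."""
        return int(sum(self.chrom_sizes.values()))

    @property
    def total_copies(self) -> int:
        return sum(info.n_copies for info in self.subfamilies.values())

    def __contains__(self, subfamily: str) -> bool:
        return subfamily in self.subfamilies

    def __getitem__(self, subfamily: str) -> SubfamilyInfo:
        return self.subfamilies[subfamily]


def filter_te_copies(
    copies: Iterable[TECopy], tolerance: float = 0.20
) -> tuple[list[TECopy], list[TECopy]]:
    """Split copies into (kept, removed) by the consensus-length filter.

    A copy is kept iff (1-tolerance)*consensus <= length <= (1+tolerance)*
    consensus, boundaries inclusive. Input order is preserved in both lists.
    """
    if not 0 <= tolerance < 1:
        raise ValueError(f"tolerance must be in [0, 1), got {tolerance}")
    kept: list[TECopy] = []
    removed: list[TECopy] = []
    for copy in copies:
        c = copy.consensus_length
        if c is None or c <= 0:
            raise ValueError(
                f"copy {copy.copy_id}: missing or non-positive consensus_length"
            )
        lo = (1.0 - tolerance) * c
        hi = (1.0 + tolerance) * c
        eps = _REL_EPS * c
        if lo - eps <= copy.length <= hi + eps:
            kept.append(copy)
        else:
            removed.append(copy)
    return kept, removed


def build_registry(
    kept: Iterable[TECopy], chrom_sizes: Mapping[str, int]
) -> SubfamilyRegistry:
    """Aggregate filtered copies into the per-subfamily registry.

    Validates that every copy lies within its chromosome and that each
    subfamily maps to a single (family, class) pair.
    """
    kept = list(kept)
    if not kept:
        raise ValueError("cannot build a registry from zero copies")
    groups: dict[str, list[TECopy]] = {}
    for copy in kept:
        iv = copy.interval
        if iv.chrom not in chrom_sizes:
            raise ValueError(f"copy {copy.copy_id}: unknown chromosome {iv.chrom}")
        if iv.end > chrom_sizes[iv.chrom]:
            raise ValueError(
                f"copy {copy.copy_id}: end {iv.end} beyond chromosome "
                f"{iv.chrom} ({chrom_sizes[iv.chrom]} bp)"
            )
        groups.setdefault(copy.subfamily, []).append(copy)

    infos: dict[str, SubfamilyInfo] = {}
    for sub, members in groups.items():
        fams = {(c.family, c.te_class) for c in members}
        if len(fams) > 1:
            raise ValueError(f"subfamily {sub} maps to multiple (family, class): {fams}")
        consensus = {c.consensus_length for c in members}
        if len(consensus) > 1:
            raise ValueError(f"subfamily {sub} has inconsistent consensus lengths")
        (family, te_class), = fams
        infos[sub] = SubfamilyInfo(
            subfamily=sub,
            family=family,
            te_class=te_class,
            n_copies=len(members),
            mean_length=sum(c.length for c in members) / len(members),
            consensus_length=next(iter(consensus)) or 0,
        )
    return SubfamilyRegistry(infos, chrom_sizes=dict(chrom_sizes))


def write_combined_annotation(
    genes: Iterable[GeneRecord], kept_tes: Iterable[TECopy], path: str | Path
) -> None:
    """Write genes plus filtered TE copies as a single GTF-dialect file.

    TE entries carry gene_id = copy_id and gene_name = subfamily, so a
    downstream quantifier treats each copy as a feature alongside genes.
    """
    rows = [(g.gene_id, g.gene_name, g.interval) for g in genes]
    rows += [(t.copy_id, t.subfamily, t.interval) for t in kept_tes]
    write_gtf_genes(rows, path)
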