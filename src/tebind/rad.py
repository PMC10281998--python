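"""Region-associated DEG (RAD) enrichment across a distance ladder.

For a region set (typically ChIP-seq peaks or TE loci) and a query gene list
(typically DEGs), count how many query genes have their anchor within d bp of
a region summit, compare with the background-gene frequency at the same d,
and test with a one-sided hypergeometric. Scanning d over a decreasing ladder
(default 1000, 500, 200, 100, 50, 25, 20, 15, 10, 5, 0 kb) shows whether the
association is proximal: enrichment well above 1 at short range that decays
toward 1 as the window engulfs the genome.

Also here: the fixed-window labelling of up-regulated DEGs as targets of
peaks that sit on a given TE subfamily (±5 kb for SINE B1 subfamilies,
±50 kb for MT2_Mm by default — the wider MT2 window compensates for its far
lower copy number).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import DEGRecord, GeneRecord, PeakRecord, TECopy
from .stats import hypergeom_upper_tail

__all__ = [
    "RadResult",
    "DEFAULT_LADDER_KB",
    "DEFAULT_CLASS_WINDOWS",
    "genes_near_regions",
    "rad_scan",
    "annotate_te_target_genes",
]

DEFAULT_LADDER_KB = (1000, 500, 200, 100, 50, 25, 20, 15, 10, 5, 0)

#: summit-to-gene windows by subfamily name or TE class, bp
DEFAULT_CLASS_WINDOWS: dict[str, int] = {"SINE": 5_000, "MT2_Mm": 50_000}

_STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class RadResult:
    distance: int  # extension distance d, bp
    observed: int
    expected: float
    enrichment: float  # observed/expected; nan when expected == 0
    p_raw: float
    stars: str


def _stars(p: float) -> str:
    for thr, mark in _STAR_THRESHOLDS:
        if p < thr:
            return mark
    return ""


def _region_summits(regions: Iterable) -> dict[str, list[int]]:
    """Sorted summit positions per chromosome.

    PeakRecords contribute their summit; plain intervals their midpoint.
    """
    by_chrom: dict[str, list[int]] = {}
    for r in regions:
        if isinstance(r, PeakRecord):
            by_chrom.setdefault(r.interval.chrom, []).append(r.summit)
        else:
            by_chrom.setdefault(r.chrom, []).append(r.midpoint)
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    return by_chrom


def _min_distance(summits: Mapping[str, Sequence[int]], gene: GeneRecord,
                  anchor: str) -> float:
    """Minimum summit distance for one gene (inf if no summit on its chrom)."""
    positions = summits.get(gene.interval.chrom)
    if not positions:
        return float("inf")
    if anchor == "tss":
        lo, hi = gene.tss, gene.tss
    elif anchor == "body":
        lo, hi = gene.interval.start, gene.interval.end - 1
    else:
        raise ValueError(f"anchor must be 'tss' or 'body', got {anchor!r}")
    i = bisect.bisect_left(positions, lo)
    if i < len(positions) and positions[i] <= hi:
        return 0.0  # a summit inside the anchor span
    best = float("inf")
    if i > 0:
        best = lo - positions[i - 1]
    if i < len(positions):
        best = min(best, positions[i] - hi)
    return best


def genes_near_regions(
    genes: Iterable[GeneRecord],
    regions: Iterable,
    d: int,
    anchor: str = "tss",
) -> set[str]:
    """Gene ids whose anchor lies within d bp (inclusive) of a region summit."""
    if d < 0:
        raise ValueError(f"d must be >= 0, got {d}")
    summits = _region_summits(regions)
    return {
        g.gene_id for g in genes if _min_distance(summits, g, anchor) <= d
    }


def rad_scan(
    query_gene_ids: Iterable[str],
    background_genes: Sequence[GeneRecord],
    regions: Iterable,
    ladder_bp: Sequence[int] | None = None,
    anchor: str = "tss",
) -> list[RadResult]:
    """Observed/expected query-gene enrichment at each ladder distance.

    Hypergeometric margins at distance d: population = background genes,
    successes = background genes within d, draws = query genes, observed =
    query genes within d. Results are ordered by d descending.
    """
    query = set(query_gene_ids)
    bg_ids = {g.gene_id for g in background_genes}
    missing = query - bg_ids
    if missing:
        raise ValueError(
            f"query genes missing from background: {sorted(missing)[:10]}"
        )
    if ladder_bp is None:
        ladder_bp = [d * 1000 for d in DEFAULT_LADDER_KB]
    ladder_bp = [int(d) for d in ladder_bp]
    if len(set(ladder_bp)) != len(ladder_bp) or any(d < 0 for d in ladder_bp):
        raise ValueError("ladder distances must be distinct and >= 0")
    ladder = sorted(ladder_bp, reverse=True)

    summits = _region_summits(regions)
    dist = {
        g.gene_id: _min_distance(summits, g, anchor) for g in background_genes
    }
    N, n = len(bg_ids), len(query)
    out = []
    for d in ladder:
        K = sum(v <= d for v in dist.values())
        k = sum(dist[q] <= d for q in query)
        expected = n * K / N if N else 0.0
        p = hypergeom_upper_tail(N, K, n, k)
        out.append(
            RadResult(
                distance=d,
                observed=k,
                expected=expected,
                enrichment=(k / expected) if expected > 0 else float("nan"),
                p_raw=p,
                stars=_stars(p),
            )
        )
    return out


def annotate_te_target_genes(
    genes: Sequence[GeneRecord],
    degs_up: Iterable[DEGRecord],
    peaks: Sequence[PeakRecord],
    te_copies: Sequence[TECopy],
    windows: Mapping[str, int] | None = None,
    anchor: str = "tss",
) -> dict[str, set[str]]:
    """Label up-regulated DEGs as targets of peaks sitting on TE subfamilies.

    A gene is a <subfamily> target iff it is an up-DEG and its anchor lies
    within the subfamily's window of the summit of a peak that overlaps a
    copy of that subfamily. The window is looked up by subfamily name first,
    then TE class (defaults: SINE 5 kb, MT2_Mm 50 kb, else 5 kb). Gene sets
    may overlap between subfamilies.
    """
    from .enrichment import merge_intervals, _MergedIndex

    windows = dict(DEFAULT_CLASS_WINDOWS if windows is None else windows)
    up_ids = {d.gene_id for d in degs_up if d.direction == "up"}
    up_genes = [g for g in genes if g.gene_id in up_ids]

    by_sub: dict[str, list[TECopy]] = {}
    class_of: dict[str, str] = {}
    for c in te_copies:
        by_sub.setdefault(c.subfamily, []).append(c)
        class_of[c.subfamily] = c.te_class

    out: dict[str, set[str]] = {}
    for sub, copies in by_sub.items():
        window = windows.get(sub, windows.get(class_of[sub], 5_000))
        index = _MergedIndex(
            merge_intervals(
                (c.interval.chrom, c.interval.start, c.interval.end) for c in copies
            )
        )
        sub_peaks = [
            p
            for p in peaks
            if index.overlaps(p.interval.chrom, p.interval.start, p.interval.end)
        ]
        out[sub] = genes_near_regions(up_genes, sub_peaks, window, anchor)
    return out
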