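"""Observed vs expected TE-subfamily copies at ChIP-seq peaks.

The central statistic: for each TE subfamily, count the copies overlapping
the peak set (observed O_s) and compare against the count expected if copies
of that subfamily were placed uniformly at random on the genome (E_s), with
one-sided significance testing and Benjamini-Hochberg correction across
subfamilies.

Two null models are provided:

``length_aware`` (default)
    A copy of mean length l is dropped uniformly on the genome; its chance of
    touching a merged peak of length L is (L + l - 1) / (G - l + 1). Summing
    over merged peaks gives the per-copy overlap probability q_s, and
    E_s = n_s * q_s with a Binomial(n_s, q_s) upper tail for significance.
    This is the reading of a random-placement null that "takes the average
    length of each TE sub-family into account".

``copy_universe``
    All filtered copies form the population; the D copies (any subfamily)
    overlapping peaks are the draw. E_s = D * n_s / N and the p-value is the
    hypergeometric upper tail at O_s.

Also here: summit-distance co-binding classification of two peak sets
(pairs of summits within ±delta bp, greedy nearest-first matching) and the
peak-centric overlap enrichment of a peak set with a subfamily's copies
against a binned-genome hypergeometric null.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from math import log10
from typing import Iterable, Mapping, Sequence

from .io import GenomicInterval, PeakRecord, TECopy
from .stats import bh_adjust, binom_upper_tail, hypergeom_upper_tail
from .te import SubfamilyRegistry

__all__ = [
    "EnrichmentRecord",
    "PeakClassification",
    "observed_te_counts",
    "expected_te_count",
    "te_enrichment_table",
    "classify_peaks",
    "peak_te_overlap_enrichment",
    "peak_te_overlap_table",
    "merge_intervals",
]

NEG_LOG10_CAP = 100.0  # -log10(p_adj) values beyond this are reported as 100


@dataclass(frozen=True)
class EnrichmentRecord:
    subfamily: str
    observed: int
    expected: float
    enrichment: float  # observed/expected; nan when expected == 0
    p_raw: float
    p_adj: float
    mode: str


@dataclass(frozen=True)
class PeakClassification:
    """Summit-distance co-binding labels for two peak sets."""

    labels_a: dict[str, str]  # peak_id -> co_bound | A_only
    labels_b: dict[str, str]  # peak_id -> co_bound | B_only
    pairs: tuple[tuple[str, str], ...]  # matched (A peak_id, B peak_id)
    delta: int

    @property
    def n_co_bound(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# interval machinery


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> dict[str, list[tuple[int, int]]]:
    """Union of intervals per chromosome, sorted, disjoint."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = [(s, e) for s, e in out]
    return merged


def _extended_peak_intervals(
    peaks: Iterable[PeakRecord], window: int
) -> list[tuple[str, int, int]]:
    return [
        (p.interval.chrom, max(0, p.interval.start - window), p.interval.end + window)
        for p in peaks
    ]


class _MergedIndex:
    """Overlap queries against merged, per-chromosome sorted intervals."""

    def __init__(self, merged: Mapping[str, Sequence[tuple[int, int]]]):
        self._starts = {c: [s for s, _ in ivs] for c, ivs in merged.items()}
        self._ivs = {c: list(ivs) for c, ivs in merged.items()}

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self._ivs:
            return False
        starts, ivs = self._starts[chrom], self._ivs[chrom]
        i = bisect.bisect_right(starts, start)
        if i > 0 and ivs[i - 1][1] > start:
            return True
        return i < len(ivs) and ivs[i][0] < end


# ---------------------------------------------------------------------------
# observed / expected


def observed_te_counts(
    peaks: Iterable[PeakRecord], kept_tes: Iterable[TECopy], window: int = 0
) -> dict[str, int]:
    """Per-subfamily count of distinct TE copies overlapping any peak.

    Peaks are extended by ±window bp before testing; each copy is counted at
    most once regardless of how many peaks it touches.
    """
    if window < 0:
        raise ValueError(f"window must be >= 0, got {window}")
    index = _MergedIndex(merge_intervals(_extended_peak_intervals(peaks, window)))
    counts: dict[str, int] = {}
    for copy in kept_tes:
        iv = copy.interval
        if index.overlaps(iv.chrom, iv.start, iv.end):
            counts[copy.subfamily] = counts.get(copy.subfamily, 0) + 1
    return counts


def _overlap_probability(
    merged: Mapping[str, Sequence[tuple[int, int]]], mean_len: float, genome_size: int
) -> float:
    """Chance that one uniformly placed copy of length mean_len hits a peak."""
    denom = genome_size - mean_len + 1.0
    if denom <= 0:
        return 1.0
    q = sum(
        (e - s) + mean_len - 1.0 for ivs in merged.values() for s, e in ivs
    ) / denom
    return min(q, 1.0)


def expected_te_count(
    registry: SubfamilyRegistry,
    peaks: Iterable[PeakRecord],
    subfamily: str,
    mode: str = "length_aware",
    kept_tes: Iterable[TECopy] | None = None,
    window: int = 0,
) -> float:
    """Expected copies of ``subfamily`` at peaks under the chosen null.

    copy_universe mode needs the full filtered copy list (``kept_tes``) to
    count the draw size D.
    """
    if subfamily not in registry:
        raise KeyError(f"unknown subfamily {subfamily!r}")
    peaks = list(peaks)
    info = registry[subfamily]
    if not peaks:
        return 0.0
    if mode == "length_aware":
        merged = merge_intervals(_extended_peak_intervals(peaks, window))
        return info.n_copies * _overlap_probability(
            merged, info.mean_length, registry.genome_size
        )
    if mode == "copy_universe":
        if kept_tes is None:
            raise ValueError("copy_universe mode requires kept_tes")
        observed = observed_te_counts(peaks, kept_tes, window)
        D = sum(observed.values())
        return D * info.n_copies / registry.total_copies
    raise ValueError(f"unknown mode {mode!r}")


def te_enrichment_table(
    peaks: Iterable[PeakRecord],
    kept_tes: Iterable[TECopy],
    registry: SubfamilyRegistry,
    mode: str = "length_aware",
    window: int = 0,
) -> list[EnrichmentRecord]:
    """One EnrichmentRecord per registry subfamily, BH-adjusted, sorted by
    (p_adj ascending, enrichment descending)."""
    if mode not in ("length_aware", "copy_universe"):
        raise ValueError(f"unknown mode {mode!r}")
    if not registry.subfamilies:
        raise ValueError("empty registry")
    peaks = list(peaks)
    kept_tes = list(kept_tes)
    observed = observed_te_counts(peaks, kept_tes, window)
    merged = merge_intervals(_extended_peak_intervals(peaks, window))
    D = sum(observed.values())
    N = registry.total_copies

    subs = sorted(registry.subfamilies)
    rows = []
    for sub in subs:
        info = registry[sub]
        O = observed.get(sub, 0)
        if mode == "length_aware":
            q = (
                _overlap_probability(merged, info.mean_length, registry.genome_size)
                if peaks
                else 0.0
            )
            E = info.n_copies * q
            p = binom_upper_tail(info.n_copies, q, O)
        else:
            E = D * info.n_copies / N
            p = hypergeom_upper_tail(N, info.n_copies, D, O)
        rows.append((sub, O, E, p))

    p_adj = bh_adjust([r[3] for r in rows])
    records = [
        EnrichmentRecord(
            subfamily=sub,
            observed=O,
            expected=E,
            enrichment=(O / E) if E > 0 else float("nan"),
            p_raw=p,
            p_adj=pa,
            mode=mode,
        )
        for (sub, O, E, p), pa in zip(rows, p_adj)
    ]
    records.sort(
        key=lambda r: (
            r.p_adj,
            -(r.enrichment if r.enrichment == r.enrichment else -1.0),
            r.subfamily,
        )
    )
    return records


# ---------------------------------------------------------------------------
# co-binding classification


def classify_peaks(
    peaks_a: Sequence[PeakRecord],
    peaks_b: Sequence[PeakRecord],
    delta: int = 500,
) -> PeakClassification:
    """Label peaks of two factors by summit proximity.

    A peak is co-bound iff a summit of the other set lies within ±delta bp on
    the same chromosome; co-bound pairs are matched greedily nearest-first,
    each peak at most once. Unmatched peaks are A_only / B_only.
    """
    candidates: list[tuple[int, int, int]] = []
    b_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for j, pb in enumerate(peaks_b):
        b_by_chrom.setdefault(pb.interval.chrom, []).append((pb.summit, j))
    for chrom in b_by_chrom:
        b_by_chrom[chrom].sort()
    for i, pa in enumerate(peaks_a):
        entries = b_by_chrom.get(pa.interval.chrom, [])
        summits = [s for s, _ in entries]
        lo = bisect.bisect_left(summits, pa.summit - delta)
        hi = bisect.bisect_right(summits, pa.summit + delta)
        for s, j in entries[lo:hi]:
            candidates.append((abs(s - pa.summit), i, j))
    candidates.sort()

    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[str, str]] = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((peaks_a[i].peak_id, peaks_b[j].peak_id))

    labels_a = {
        p.peak_id: ("co_bound" if i in used_a else "A_only")
        for i, p in enumerate(peaks_a)
    }
    labels_b = {
        p.peak_id: ("co_bound" if j in used_b else "B_only")
        for j, p in enumerate(peaks_b)
    }
    return PeakClassification(labels_a, labels_b, tuple(pairs), delta)


# ---------------------------------------------------------------------------
# peak-centric overlap enrichment (binned-genome null)


def _binned_null(
    registry: SubfamilyRegistry,
    copies: Sequence[TECopy],
    bin_size: int,
) -> tuple[int, int]:
    """(N bins in genome, K bins touched by the copies)."""
    n_bins = sum(-(-size // bin_size) for size in registry.chrom_sizes.values())
    hit: set[tuple[str, int]] = set()
    for c in copies:
        iv = c.interval
        for b in range(iv.start // bin_size, (iv.end - 1) // bin_size + 1):
            hit.add((iv.chrom, b))
    return n_bins, len(hit)


def peak_te_overlap_enrichment(
    peaks: Sequence[PeakRecord],
    te_subfamily_copies: Sequence[TECopy],
    registry: SubfamilyRegistry,
    bin_size: int = 1000,
) -> EnrichmentRecord:
    """Enrichment of a peak set over one subfamily's copies.

    The genome is partitioned into fixed-size bins; the subfamily's copies
    mark K of the N bins, the n peaks are the draw, and the number of peaks
    overlapping a copy is the observed success count, tested with the
    hypergeometric upper tail. p_adj equals p_raw here (single test); use
    :func:`peak_te_overlap_table` for BH across subfamilies.
    """
    subs = {c.subfamily for c in te_subfamily_copies}
    if len(subs) != 1:
        raise ValueError(f"expected copies of one subfamily, got {subs or 'none'}")
    (sub,) = subs
    index = _MergedIndex(
        merge_intervals(
            (c.interval.chrom, c.interval.start, c.interval.end)
            for c in te_subfamily_copies
        )
    )
    k = sum(
        index.overlaps(p.interval.chrom, p.interval.start, p.interval.end)
        for p in peaks
    )
    N, K = _binned_null(registry, te_subfamily_copies, bin_size)
    n = len(peaks)
    expected = n * K / N if N else 0.0
    p = hypergeom_upper_tail(N, K, min(n, N), min(k, K, n))
    return EnrichmentRecord(
        subfamily=sub,
        observed=k,
        expected=expected,
        enrichment=(k / expected) if expected > 0 else float("nan"),
        p_raw=p,
        p_adj=p,
        mode="binned_genome",
    )


def peak_te_overlap_table(
    peaks: Sequence[PeakRecord],
    kept_tes: Sequence[TECopy],
    registry: SubfamilyRegistry,
    bin_size: int = 1000,
) -> list[EnrichmentRecord]:
    """Per-subfamily peak-overlap enrichment with BH across subfamilies."""
    by_sub: dict[str, list[TECopy]] = {}
    for c in kept_tes:
        by_sub.setdefault(c.subfamily, []).append(c)
    subs = sorted(by_sub)
    raw = [
        peak_te_overlap_enrichment(peaks, by_sub[s], registry, bin_size) for s in subs
    ]
    p_adj = bh_adjust([r.p_raw for r in raw])
    return [
        EnrichmentRecord(r.subfamily, r.observed, r.expected, r.enrichment, r.p_raw, pa, r.mode)
        for r, pa in zip(raw, p_adj)
    ]


def neg_log10_capped(p: float, cap: float = NEG_LOG10_CAP) -> float:
    """-log10(p) with values beyond ``cap`` (or p == 0) reported as the cap."""
    if p <= 0:
        return cap
    return min(-log10(p), cap)
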