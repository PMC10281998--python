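"""Hexamer enrichment profiles and shared-motif chain assembly.

Workflow mirrored here: take the genomic sequences of TE copies that are
"bound" (a peak summit within a class-specific window of the copy), count
all overlapping hexamers per subfamily, convert to within-set percentages,
rank, intersect the top-K lists of two subfamilies, and join the shared
hexamers whose (k-1)-suffix/prefix overlap into longer consensus strings.
Four overlapping hexamers chaining into a single 9-mer is the signature of a
shared binding motif such as CCTTTAATC.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PeakRecord, TECopy, reverse_complement
from .rad import DEFAULT_CLASS_WINDOWS

__all__ = [
    "MotifChain",
    "extract_bound_copy_sequences",
    "kmer_percentages",
    "kmer_zscores",
    "top_k_shared",
    "assemble_chains",
]

_ACGT = frozenset("ACGT")
MAX_CHAIN_MEMBERS = 64  # termination cap for pathological overlap graphs


@dataclass(frozen=True)
class MotifChain:
    """An ordered run of k-mers overlapping by k-1, with its consensus."""

    members: tuple[str, ...]
    consensus: str

    def __post_init__(self) -> None:
        k = len(self.members[0])
        for a, b in zip(self.members, self.members[1:]):
            if a[1:] != b[:-1]:
                raise ValueError(f"members {a} and {b} do not overlap by k-1")
        if len(self.consensus) != k + len(self.members) - 1:
            raise ValueError("consensus length inconsistent with member count")
        for i, m in enumerate(self.members):
            if self.consensus[i : i + k] != m:
                raise ValueError(f"consensus does not reconstruct member {m}")

    def __len__(self) -> int:
        return len(self.consensus)


def _chain_from_members(members: Sequence[str]) -> MotifChain:
    consensus = members[0] + "".join(m[-1] for m in members[1:])
    return MotifChain(tuple(members), consensus)


def extract_bound_copy_sequences(
    te_copies: Sequence[TECopy],
    peaks: Sequence[PeakRecord],
    genome: Mapping[str, str],
    windows: Mapping[str, int] | None = None,
) -> dict[str, list[str]]:
    """Per-subfamily sequences of copies with a peak summit in their window.

    A copy is bound iff some summit lies within the window of the copy's
    interval (distance zero inside the copy); windows resolve by subfamily
    name then TE class as in :data:`~tebind.rad.DEFAULT_CLASS_WINDOWS`.
    Copies on the minus strand are reverse-complemented so sequences are in
    the element's own orientation.
    """
    import bisect

    windows = dict(DEFAULT_CLASS_WINDOWS if windows is None else windows)
    summits: dict[str, list[int]] = {}
    for p in peaks:
        summits.setdefault(p.interval.chrom, []).append(p.summit)
    for chrom in summits:
        summits[chrom].sort()

    out: dict[str, list[str]] = {}
    for copy in te_copies:
        iv = copy.interval
        if iv.chrom not in genome:
            raise KeyError(f"copy {copy.copy_id}: chromosome {iv.chrom} not in genome")
        if iv.end > len(genome[iv.chrom]):
            raise ValueError(
                f"copy {copy.copy_id}: interval extends beyond chromosome end"
            )
        window = windows.get(copy.subfamily, windows.get(copy.te_class, 5_000))
        positions = summits.get(iv.chrom, [])
        lo = bisect.bisect_left(positions, iv.start - window)
        bound = lo < len(positions) and positions[lo] <= iv.end - 1 + window
        if not bound:
            continue
        seq = genome[iv.chrom][iv.start : iv.end]
        if iv.strand == "-":
            seq = reverse_complement(seq)
        out.setdefault(copy.subfamily, []).append(seq)
    return out


def kmer_percentages(sequences: Iterable[str], k: int = 6) -> dict[str, float]:
    """Percentage of each k-mer among all overlapping k-mer windows.

    Windows containing a non-ACGT character are skipped; percentages sum
    to 100 over the returned keys.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    counts: Counter[str] = Counter()
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if set(window) <= _ACGT:
                counts[window] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no countable k-mer windows in the input sequences")
    return {kmer: 100.0 * c / total for kmer, c in counts.items()}


def kmer_zscores(profiles: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Row-wise Z-scores of k-mer percentages across subfamily columns.

    ``profiles`` maps subfamily -> {k-mer: percentage}. K-mers absent from a
    subfamily count as 0%. Each row is standardized to mean 0 and population
    SD 1 across columns; constant rows become all zeros.
    """
    if len(profiles) < 2:
        raise ValueError("Z-scores require at least two subfamilies")
    df = pd.DataFrame(profiles).fillna(0.0).sort_index()
    values = df.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population SD (ddof=0)
    with np.errstate(invalid="ignore"):
        z = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=df.index, columns=df.columns)


def top_k_shared(
    profile_a: Mapping[str, float],
    profile_b: Mapping[str, float],
    top: int = 50,
) -> tuple[list[str], list[str], set[str]]:
    """Top-K k-mers of each profile by percentage, and their intersection.

    Ties at the boundary break lexicographically, so the selection is
    deterministic. Profiles with fewer than K k-mers return everything.
    """
    if top < 1:
        raise ValueError(f"top must be >= 1, got {top}")

    def select(profile: Mapping[str, float]) -> list[str]:
        ranked = sorted(profile, key=lambda h: (-profile[h], h))
        return ranked[:top]

    top_a, top_b = select(profile_a), select(profile_b)
    return top_a, top_b, set(top_a) & set(top_b)


def assemble_chains(kmers: Iterable[str]) -> list[MotifChain]:
    """Join k-mers overlapping by k-1 into maximal simple chains.

    Directed edge u -> v iff suffix(u, k-1) == prefix(v, k-1) and u != v.
    All maximal simple paths (extendable at neither end without revisiting a
    node) are emitted, isolated k-mers as singletons. Output is sorted by
    consensus length descending, then consensus lexicographically. Member
    count per chain is capped at MAX_CHAIN_MEMBERS to terminate on cyclic
    graphs.
    """
    nodes = sorted(set(kmers))
    if not nodes:
        return []
    ks = {len(n) for n in nodes}
    if len(ks) != 1:
        raise ValueError(f"k-mers of mixed lengths: {sorted(ks)}")
    for n in nodes:
        if not set(n) <= _ACGT:
            raise ValueError(f"non-ACGT k-mer: {n!r}")

    succ = {u: [v for v in nodes if v != u and u[1:] == v[:-1]] for u in nodes}
    pred = {u: [v for v in nodes if v != u and v[1:] == u[:-1]] for u in nodes}

    chains: set[tuple[str, ...]] = set()

    def dfs(path: list[str], in_path: set[str]) -> None:
        capped = len(path) >= MAX_CHAIN_MEMBERS
        nexts = [] if capped else [v for v in succ[path[-1]] if v not in in_path]
        if not nexts:  # back end not extendable (or capped)
            front_open = any(u not in in_path for u in pred[path[0]])
            if capped or not front_open:
                chains.add(tuple(path))
            return
        for v in nexts:
            path.append(v)
            in_path.add(v)
            dfs(path, in_path)
            in_path.remove(v)
            path.pop()

    # every maximal path is discovered by the DFS rooted at its first node
    for start in nodes:
        dfs([start], {start})

    out = [_chain_from_members(c) for c in chains]
    out.sort(key=lambda ch: (-len(ch.consensus), ch.consensus))
    return out
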