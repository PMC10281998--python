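import itertools

import pytest
from hypothesis import given, settings, strategies as st

from tebind.io import GenomicInterval, PeakRecord, TECopy
from tebind.kmer import (
    MotifChain,
    assemble_chains,
    extract_bound_copy_sequences,
    kmer_percentages,
    kmer_zscores,
    top_k_shared,
)

MOTIF_TILES = {"CCTTTA", "CTTTAA", "TTTAAT", "TTAATC"}


def copy(start, end, sub="X", strand="+", i=0, chrom="chr1"):
    return TECopy(
        GenomicInterval(chrom, start, end, strand), sub, "f", "SINE",
        f"{sub}.{i}", 100,
    )


def peak_at(summit, chrom="chr1", width=100):
    start = max(0, summit - width // 2)
    return PeakRecord(
        GenomicInterval(chrom, start, start + width), summit, f"p{summit}"
    )


class TestExtractBound:
    def test_minus_strand_reverse_complemented(self):
        genome = {"chr1": "T" * 100 + "AAACCC" + "T" * 100}
        minus = copy(100, 106, strand="-")
        out = extract_bound_copy_sequences([minus], [peak_at(103)], genome)
        assert out == {"X": ["GGGTTT"]}

    def test_window_boundary_exclusive_beyond(self):
        genome = {"chr1": "A" * 20_000}
        c = copy(1_000, 1_100)
        windows = {"SINE": 5_000}
        inside = extract_bound_copy_sequences(
            [c], [peak_at(6_099)], genome, windows
        )
        beyond = extract_bound_copy_sequences(
            [c], [peak_at(6_100)], genome, windows
        )
        assert "X" in inside and beyond == {}

    def test_copy_beyond_chromosome_errors(self):
        with pytest.raises(ValueError, match="beyond"):
            extract_bound_copy_sequences(
                [copy(90, 120)], [peak_at(50)], {"chr1": "A" * 100}
            )

    def test_matches_brute_force_distance_scan(self, rng):
        genome = {"chr1": "ACGT" * 25_000, "chr2": "TTGCA" * 20_000}
        copies = [
            copy(int(s), int(s) + 50, chrom=ch, i=i,
                 strand="+-"[int(rng.integers(0, 2))])
            for i, (s, ch) in enumerate(
                zip(rng.integers(0, 99_000, 300),
                    rng.choice(["chr1", "chr2"], 300))
            )
        ]
        peaks = [
            peak_at(int(s), chrom=ch)
            for s, ch in zip(rng.integers(100, 99_000, 40),
                             rng.choice(["chr1", "chr2"], 40))
        ]
        window = 2_000
        out = extract_bound_copy_sequences(copies, peaks, genome,
                                           {"SINE": window})
        expected = sum(
            any(
                p.interval.chrom == c.interval.chrom
                and c.interval.start - window <= p.summit <= c.interval.end - 1 + window
                for p in peaks
            )
            for c in copies
        )
        assert sum(len(v) for v in out.values()) == expected


class TestPercentages:
    def test_hand_enumerated_windows(self):
        p = kmer_percentages(["ACGTACGT"])
        assert p == pytest.approx(
            {"ACGTAC": 100 / 3, "CGTACG": 100 / 3, "GTACGT": 100 / 3}
        )

    def test_single_repeated_hexamer(self):
        assert kmer_percentages(["AAAAAA"]) == {"AAAAAA": 100.0}

    def test_windows_spanning_n_skipped(self):
        # ACGNACGTAC: of 5 windows only ACGTAC (offset 4) is N-free
        assert kmer_percentages(["ACGNACGTAC"]) == {"ACGTAC": 100.0}

    def test_percentages_sum_to_100_and_order_invariant(self, rng):
        seqs = [
            "".join(rng.choice(list("ACGT"), size=int(rng.integers(6, 60))))
            for _ in range(30)
        ]
        p = kmer_percentages(seqs)
        assert sum(p.values()) == pytest.approx(100.0, abs=1e-9)
        assert kmer_percentages(list(reversed(seqs))) == p

    def test_no_countable_windows_errors(self):
        with pytest.raises(ValueError):
            kmer_percentages(["ACG", "NNNNNNNN"])


class TestZscores:
    def test_closed_form_row(self):
        z = kmer_zscores(
            {"s1": {"AAAAAA": 10.0}, "s2": {"AAAAAA": 20.0}, "s3": {"AAAAAA": 30.0}}
        )
        assert z.loc["AAAAAA"].tolist() == pytest.approx(
            [-1.224744871, 0.0, 1.224744871]
        )

    def test_constant_row_and_absent_kmer(self):
        z = kmer_zscores({"s1": {"AAAAAA": 5.0}, "s2": {"AAAAAA": 5.0}})
        assert z.loc["AAAAAA"].tolist() == [0.0, 0.0]
        z2 = kmer_zscores({"s1": {"CCCCCC": 4.0}, "s2": {}})
        assert z2.loc["CCCCCC", "s2"] == pytest.approx(-1.0)

    def test_matches_reference_routine(self, rng):
        from scipy.stats import zscore

        profiles = {
            f"s{j}": {f"k{i}": float(rng.uniform(0, 10)) for i in range(100)}
            for j in range(5)
        }
        z = kmer_zscores(profiles)
        import numpy as np

        raw = np.array(
            [[profiles[f"s{j}"][f"k{i}"] for j in range(5)] for i in range(100)]
        )
        ref = zscore(raw, axis=1, ddof=0)
        got = z.loc[[f"k{i}" for i in range(100)], [f"s{j}" for j in range(5)]]
        assert got.to_numpy() == pytest.approx(ref, abs=1e-12)

    def test_single_subfamily_rejected(self):
        with pytest.raises(ValueError):
            kmer_zscores({"s1": {"AAAAAA": 1.0}})


class TestTopKShared:
    def test_disjoint_and_identical_profiles(self):
        a = {"AAAAAA": 60.0, "CCCCCC": 40.0}
        b = {"GGGGGG": 70.0, "TTTTTT": 30.0}
        _, _, shared = top_k_shared(a, b, top=2)
        assert shared == set()
        ta, tb, shared = top_k_shared(a, a, top=2)
        assert shared == set(a) and len(ta) == 2

    def test_tie_break_lexicographic_then_truncate(self):
        profile = {"TTTTTT": 10.0, "AAAAAA": 10.0, "CCCCCC": 10.0}
        top_a, _, _ = top_k_shared(profile, profile, top=2)
        assert top_a == ["AAAAAA", "CCCCCC"]

    def test_fewer_than_k_returns_all(self):
        a = {"AAAAAA": 100.0}
        top_a, _, _ = top_k_shared(a, a, top=50)
        assert top_a == ["AAAAAA"]


def oracle_maximal_paths(kmers):
    """Independent exhaustive enumeration over all orderings of all subsets."""
    kmers = sorted(kmers)
    edges = {
        (u, v) for u in kmers for v in kmers
        if u != v and u[1:] == v[:-1]
    }
    paths = set()
    for r in range(1, len(kmers) + 1):
        for perm in itertools.permutations(kmers, r):
            if all((a, b) in edges for a, b in zip(perm, perm[1:])):
                paths.add(perm)
    maximal = set()
    for p in paths:
        in_p = set(p)
        front = any((u, p[0]) in edges and u not in in_p for u in kmers)
        back = any((p[-1], v) in edges and v not in in_p for v in kmers)
        if not front and not back:
            maximal.add(p)
    return maximal


class TestAssembleChains:
    def test_motif_tiles_assemble_to_nine_mer(self):
        chains = assemble_chains(MOTIF_TILES)
        assert len(chains) == 1
        assert chains[0].consensus == "CCTTTAATC"
        assert len(chains[0]) == 9
        assert chains[0].members == ("CCTTTA", "CTTTAA", "TTTAAT", "TTAATC")

    def test_isolated_kmer_is_singleton(self):
        (chain,) = assemble_chains({"ACGTAC"})
        assert chain.consensus == "ACGTAC" and chain.members == ("ACGTAC",)

    def test_branching_gives_two_maximal_paths(self):
        chains = assemble_chains({"ACGTAC", "CGTACG", "CGTACT"})
        assert {c.consensus for c in chains} == {"ACGTACG", "ACGTACT"}

    def test_mixed_k_rejected(self):
        with pytest.raises(ValueError):
            assemble_chains({"ACGT", "ACGTA"})

    def test_cycle_terminates(self):
        # AAATTT -> AATTTA -> ATTTAA -> TTTAAA -> TTAAAT -> TAAATT -> AAATTT
        cyc = {"AAATTT", "AATTTA", "ATTTAA", "TTTAAA", "TTAAAT", "TAAATT"}
        chains = assemble_chains(cyc)
        assert chains and all(len(c.members) <= 64 for c in chains)

    @settings(max_examples=150, deadline=None)
    @given(
        st.sets(
            st.text(alphabet="ACGT", min_size=3, max_size=3),
            min_size=1,
            max_size=6,
        )
    )
    def test_matches_exhaustive_path_enumeration(self, kmers):
        got = {c.members for c in assemble_chains(kmers)}
        assert got == oracle_maximal_paths(kmers)

    def test_chain_invariants_enforced(self):
        with pytest.raises(ValueError):
            MotifChain(("ACGTAC", "ACGTAC"), "ACGTACC")
        with pytest.raises(ValueError):
            MotifChain(("CCTTTA", "CTTTAA"), "CCTTTAX")
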