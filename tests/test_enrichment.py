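from fractions import Fraction
from math import comb, isnan

import numpy as np
import pytest

from tebind.io import GenomicInterval, PeakRecord, TECopy, overlaps
from tebind.enrichment import (
    classify_peaks,
    expected_te_count,
    neg_log10_capped,
    observed_te_counts,
    peak_te_overlap_enrichment,
    te_enrichment_table,
)
from tebind.stats import bh_adjust, hypergeom_upper_tail
from tebind.te import build_registry
from conftest import random_peak, random_te_copy


def peak(chrom, start, end, summit=None, pid="p"):
    return PeakRecord(
        GenomicInterval(chrom, start, end),
        (start + end) // 2 if summit is None else summit,
        pid,
    )


def copy_at(start, end, sub="X", i=0, consensus=100, chrom="chr1"):
    return TECopy(
        GenomicInterval(chrom, start, end), sub, "f", "c", f"{sub}.{i}", consensus
    )


def hypergeom_enum(N, K, n, k):
    """Exact P(X >= k) by summing the closed-form composition counts."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    return total


class TestObservedCounts:
    def test_containment_and_window_extension(self):
        p = [peak("chr1", 100, 200)]
        assert observed_te_counts(p, [copy_at(150, 180)]) == {"X": 1}
        assert observed_te_counts(p, [copy_at(200, 300)]) == {}
        assert observed_te_counts(p, [copy_at(200, 300)], window=1) == {"X": 1}

    def test_matches_all_pairs_overlap_oracle(self, rng):
        peaks = [random_peak(rng, i) for i in range(200)]
        copies = [random_te_copy(rng, i) for i in range(200)]
        got = observed_te_counts(peaks, copies)
        expected = {}
        for c in copies:
            if any(overlaps(c.interval, p.interval) for p in peaks):
                expected[c.subfamily] = expected.get(c.subfamily, 0) + 1
        assert got == expected

    def test_each_copy_counted_once_and_window_monotone(self, rng):
        peaks = [random_peak(rng, i) for i in range(50)]
        copies = [random_te_copy(rng, i) for i in range(100)]
        by_sub = {}
        for c in copies:
            by_sub[c.subfamily] = by_sub.get(c.subfamily, 0) + 1
        prev = {}
        for w in (0, 100, 1000, 10_000):
            counts = observed_te_counts(peaks, copies, window=w)
            for s, n in counts.items():
                assert n <= by_sub[s]
                assert n >= prev.get(s, 0)
            prev = counts


class TestExpectedCount:
    def test_length_aware_closed_form_matches_monte_carlo(self):
        # G = 10,000; one 1,000 bp peak; n_s = 10 copies of mean length 100.
        # Closed form: 10 * (1000 + 100 - 1) / (10000 - 100 + 1) = 1.10998...
        copies = [copy_at(i * 150, i * 150 + 100, i=i) for i in range(10)]
        reg = build_registry(copies, {"chr1": 10_000})
        peaks = [peak("chr1", 5_000, 6_000)]
        e = expected_te_count(reg, peaks, "X", mode="length_aware")
        assert e == pytest.approx(10 * 1099 / 9901, rel=1e-12)
        # Monte-Carlo oracle: uniform placements of a 100 bp copy
        mc_rng = np.random.default_rng(7)
        starts = mc_rng.integers(0, 10_000 - 100 + 1, size=100_000)
        frac = np.mean((starts < 6_000) & (starts + 100 > 5_000))
        se = np.sqrt(frac * (1 - frac) / 100_000)
        assert abs(e / 10 - frac) < 3 * se + 1e-4

    def test_no_peaks_gives_zero(self):
        copies = [copy_at(0, 100)]
        reg = build_registry(copies, {"chr1": 10_000})
        assert expected_te_count(reg, [], "X") == 0.0
        assert expected_te_count(reg, [], "X", mode="copy_universe",
                                 kept_tes=copies) == 0.0

    def test_copy_universe_saturated_draw(self):
        copies = [copy_at(0, 100, i=0), copy_at(200, 300, i=1)]
        reg = build_registry(copies, {"chr1": 10_000})
        # one peak covering everything: D = N, so E_s = n_s
        peaks = [peak("chr1", 0, 9_000)]
        e = expected_te_count(reg, peaks, "X", mode="copy_universe",
                              kept_tes=copies)
        assert e == 2.0

    def test_unknown_subfamily_errors(self):
        reg = build_registry([copy_at(0, 100)], {"chr1": 10_000})
        with pytest.raises(KeyError):
            expected_te_count(reg, [], "nope")


class TestHypergeom:
    def test_worked_example(self):
        assert hypergeom_upper_tail(10, 4, 5, 3) == pytest.approx(66 / 252)

    def test_certain_and_forced_events(self):
        assert hypergeom_upper_tail(20, 5, 7, 0) == 1.0
        assert hypergeom_upper_tail(8, 8, 3, 3) == pytest.approx(1.0)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(10, 11, 5, 3)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(10, 4, 5, 6)

    def test_matches_enumeration_small_population(self):
        for N in (5, 9, 12):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert hypergeom_upper_tail(N, K, n, k) == pytest.approx(
                            float(hypergeom_enum(N, K, n, k)), abs=1e-12
                        )


class TestBH:
    def test_hand_applied_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.04, 0.01]) == pytest.approx([0.04, 0.02])
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=50).tolist()
        adj = bh_adjust(p)
        assert all(a >= r - 1e-12 and a <= 1.0 for a, r in zip(adj, p))


class TestEnrichmentTable:
    @pytest.mark.parametrize("mode", ["length_aware", "copy_universe"])
    def test_planted_subfamily_ranks_first(self, rng, mode):
        # subfamily X hosts 90% of the peaks
        sizes = {"chr1": 500_000}
        copies = []
        pos = 0
        for i in range(40):
            copies.append(copy_at(pos, pos + 100, "X", i))
            pos += 2_000
        for i in range(40):
            copies.append(copy_at(pos, pos + 100, "Y", i))
            pos += 2_000
        x_copies = [c for c in copies if c.subfamily == "X"]
        peaks = [
            peak("chr1", c.interval.start, c.interval.end, pid=f"px{i}")
            for i, c in enumerate(x_copies[:36])
        ]
        for i in range(4):
            s = 300_000 + i * 10_000 + 500
            peaks.append(peak("chr1", s, s + 100, pid=f"pb{i}"))
        reg = build_registry(copies, sizes)
        table = te_enrichment_table(peaks, copies, reg, mode=mode)
        assert table[0].subfamily == "X"
        assert table[0].enrichment > 1
        assert table[0].p_adj < 0.05

    def test_single_subfamily_adjustment_is_identity(self):
        copies = [copy_at(0, 100)]
        reg = build_registry(copies, {"chr1": 10_000})
        (rec,) = te_enrichment_table([peak("chr1", 0, 200)], copies, reg)
        assert rec.p_adj == rec.p_raw

    def test_record_invariants(self, sim_data):
        from tebind.te import filter_te_copies

        kept, _ = filter_te_copies(sim_data.te_copies)
        reg = build_registry(kept, sim_data.config.chrom_sizes)
        for mode in ("length_aware", "copy_universe"):
            for rec in te_enrichment_table(sim_data.peaks, kept, reg, mode=mode):
                assert rec.observed <= reg[rec.subfamily].n_copies
                assert rec.p_adj >= rec.p_raw - 1e-12
                assert isnan(rec.enrichment) or rec.enrichment >= 0


class TestClassifyPeaks:
    def test_delta_boundary(self):
        a = [peak("chr1", 500, 1500, summit=1000, pid="a")]
        near = [peak("chr1", 900, 1900, summit=1400, pid="b")]
        far = [peak("chr1", 1100, 2100, summit=1600, pid="b")]
        assert classify_peaks(a, near).labels_a["a"] == "co_bound"
        res = classify_peaks(a, far)
        assert res.labels_a["a"] == "A_only" and res.labels_b["b"] == "B_only"

    def test_empty_b_all_a_only(self):
        a = [peak("chr1", 0, 100, pid=f"a{i}") for i in range(3)]
        res = classify_peaks(a, [])
        assert set(res.labels_a.values()) == {"A_only"} and res.n_co_bound == 0

    def test_greedy_nearest_first_matching(self):
        # one B summit between two A summits: matched to the nearer A
        a = [peak("chr1", 0, 2000, summit=1000, pid="a1"),
             peak("chr1", 0, 2000, summit=1300, pid="a2")]
        b = [peak("chr1", 0, 2000, summit=1250, pid="b1")]
        res = classify_peaks(a, b)
        assert res.pairs == (("a2", "b1"),)
        assert res.labels_a == {"a1": "A_only", "a2": "co_bound"}

    def test_order_invariance_and_pair_bound(self, rng):
        a = [random_peak(rng, i) for i in range(60)]
        b = [random_peak(rng, 100 + i) for i in range(40)]
        res = classify_peaks(a, b)
        res2 = classify_peaks(list(reversed(a)), list(reversed(b)))
        assert res.n_co_bound == res2.n_co_bound
        assert sorted(res.labels_a.values()) == sorted(res2.labels_a.values())
        assert res.n_co_bound <= min(len(a), len(b))


class TestPeakOverlapEnrichment:
    def test_all_peaks_inside_copies_is_extreme(self):
        copies = [copy_at(i * 5_000, i * 5_000 + 1_000, "X", i) for i in range(20)]
        reg = build_registry(copies, {"chr1": 200_000})
        peaks = [
            peak("chr1", c.interval.start + 100, c.interval.start + 400,
                 pid=f"p{i}")
            for i, c in enumerate(copies)
        ]
        rec = peak_te_overlap_enrichment(peaks, copies, reg)
        assert rec.observed == len(peaks)
        assert rec.enrichment > 1
        assert rec.p_raw < 1e-6

    def test_neg_log10_cap(self):
        assert neg_log10_capped(1e-150) == 100.0
        assert neg_log10_capped(0.0) == 100.0
        assert neg_log10_capped(0.01) == pytest.approx(2.0)
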