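# Methods

This note records the models, parameter choices and numerical conventions
behind `tebind`, and what the synthetic benchmarks do and do not establish
about real data.

## Coordinates and input conventions

All internal coordinates are 0-based half-open (BED convention); GTF input
(1-based closed) is converted at read time and converted back on write.
Overlap means ≥ 1 shared bp — no minimum-overlap fraction is imposed.
TE identity travels in the BED name column as `subfamily:family:class[:id]`;
consensus lengths come from a separate two-column TSV, since BED carries no
such field. A narrowPeak summit is `start + column 10`; when the offset is
absent or −1 the interval midpoint (rounded down) is used, a deterministic
and conventional fallback. TSS is the 5′ end by strand: `start` on +/.,
`end − 1` on −.

## Consensus-length filter

A TE copy is kept iff

(1 − t)·c ≤ ℓ ≤ (1 + t)·c,  t = 0.20 default,

with ℓ the genomic interval length and c the subfamily consensus length.
Boundaries are inclusive: copies exactly 20% longer or shorter survive,
since only copies *more than* 20% off are treated as degenerate. Because
(1 − t)·c is not exactly representable in binary floating point for most
integer c, the comparison carries a relative epsilon of 1e−9 so that
integer boundary lengths (80 vs consensus 100) are never dropped by a
rounding artifact. Genomic length is used, not alignment length with gaps;
no CIGAR/alignment parsing is performed. Subfamily mean lengths ℓ̄_s are
computed on the *filtered* universe, because that is the universe every
downstream null refers to.

## Expected TE counts at peaks

The observed count O_s is the number of distinct copies of subfamily s
overlapping any peak (each copy counted once; peaks may first be extended
by ±window, default 0 — direct overlap). Two explicit nulls are provided
because the notion of "random distribution taking average TE length into
account" admits more than one formalization:

* **length_aware** (default). Peaks are merged to disjoint intervals first
  (so overlapping peaks are not double counted). A copy of length ℓ̄_s with
  uniform start on [0, G − ℓ̄_s] touches a merged peak of length L with
  probability (L + ℓ̄_s − 1)/(G − ℓ̄_s + 1); summing over merged peaks and
  capping at 1 gives q_s, E_s = n_s·q_s, and the p-value is the
  Binomial(n_s, q_s) upper tail at O_s. The sum over peaks is exact when
  the merged peaks are separated by more than ℓ̄_s (the overlap events are
  then disjoint) and a slight overcount otherwise; the Monte-Carlo
  benchmark (1e5 uniform placements, 10 random configurations, agreement
  within 3 SE) covers the separated regime, which is the realistic one
  after merging. The placement model is whole-genome (no per-chromosome
  stratification); with chromosomes of similar composition the difference
  is an edge effect of order ℓ̄_s/G.
* **copy_universe**. All N filtered copies form the population, the D
  copies overlapping peaks (any subfamily) are the draw, K = n_s; E_s =
  D·n_s/N with a hypergeometric upper tail. This ignores length
  differences between subfamilies and is offered as the simpler,
  assumption-light alternative.

BH adjustment is applied across subfamilies within a table; tables sort by
adjusted p then enrichment descending. The peak-centric variant
(enrichment of a *peak set* in a subfamily's copies) needs a notion of how
many placements a peak has: the genome is partitioned into fixed-size bins
(1 kb default), N = bin count, K = bins touched by the subfamily's copies,
the peaks are the draw and peaks overlapping a copy the successes.
Reported −log10(adjusted p) is capped at 100 (p = 0 maps to the cap).

## Co-binding classification

Peaks of two factors are paired when their summits lie within ±δ (500 bp
default) on the same chromosome, greedily nearest-first, each peak at most
once; unpaired peaks are factor-specific. This is an interval surrogate for
signal-based clustering of coverage heatmaps: it needs no read pileups,
is order-invariant and yields co-bound counts bounded by min(|A|, |B|).
It will split a broad region containing two summits of one factor into two
pairings where a signal-based method might call one, so absolute co-bound
counts are comparable only between runs of this same rule.

## RAD scan

Distance is summit-to-anchor, inclusive, unstranded. The anchor defaults
to the TSS; `body` (nearest gene-interval edge, 0 inside) is available
because published scans built on whole gene bodies are common and the
choice changes counts for long genes. The test at distance d is one-sided
hypergeometric with population = background genes, successes = background
genes within d, draws = query genes. The background defaults to all
supplied genes (optionally those passing the TPM filter when an expression
table is given). Observed counts are monotone non-decreasing in d by
construction, and enrichment converges to 1 as d saturates the genome.
Target-gene labelling windows are ±5 kb for SINE B1 subfamilies and
±50 kb for MT2_Mm; the wider MT2 window compensates for its far lower
copy number (hundreds of SINE copies would be hit at 50 kb by chance).

## Hexamer profiles and chain assembly

All overlapping 6-mer windows are counted on the annotation strand (minus
copies reverse-complemented first); windows containing non-ACGT characters
are skipped; percentages are within-set (each set sums to 100). Ranking
for top-50 selection is by within-set percentage — no background ratio —
with lexicographic tie-breaks so selection is deterministic; ranking by
Z-score is available as an option. Z-scores are per hexamer across
subfamily columns with population SD; constant rows map to 0; a hexamer
absent from a set enters as 0%. A strand-collapsed (canonical k-mer) mode
exists but is off by default, since element-oriented counting matches how
bound-copy sequences are extracted.

Chain assembly builds the directed overlap graph (u → v iff the 5-bp
suffix of u equals the 5-bp prefix of v) and enumerates all maximal simple
paths — paths extendable at neither end without revisiting a node —
emitting isolated k-mers as singletons. Enumeration is exhaustive DFS from
every node, correct for the small shared sets this stage sees (≤ 50);
member count per chain is capped at 64 so cyclic graphs terminate. Output
order: consensus length descending, then lexicographic.

## Temporal clustering and overlap tests

Retention: mean TPM strictly > 1 in either control or treatment. The
built-in DEG caller (pseudocount 0.5, Welch t on log2(TPM + 0.5), BH) is a
deliberately simple path so synthetic end-to-end runs need no external
differential-expression machinery; published negative-binomial fits are
ingested as external DEG tables instead, and the NB model is not
re-implemented here. The fold-change cutoff is a parameter (default 2,
with 1.5 a common alternative preset for published DEG lists).
Cluster assignment: earliest time point attaining the maximum TPM, assigned
only when the maximum strictly exceeds the arithmetic mean of the other
time points, with a 1e−9 relative guard so exactly flat profiles are never
assigned through float rounding of the mean. Assignment is scale-invariant
per gene. Overlap tests are one-sided hypergeometric upper tails with the
2×2 odds ratio ad/bc (∞ when bc = 0 and ad > 0), BH across stages.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, at
desk scale: a 2 Mb, two-chromosome genome (two chromosomes so boundary
handling is always exercised); six TE subfamilies mirroring the real cast —
MT2_Mm (LTR/ERVL, 500 bp consensus, 60 copies), three B1 SINE subfamilies
(150 bp, 120–150 copies each), two LTR background subfamilies — placed
without overlap by rejection sampling (attempt cap 10,000, then an error
suggesting smaller counts; simplicity over exact uniformity among
non-overlapping configurations). Copy lengths are jittered uniformly
(±10% default), and each copy diverges from its subfamily consensus by
independent per-base substitution (15% default). The divergence is what
makes motif recovery meaningful: without it every consensus hexamer is
present in 100% of copies and outranks a motif planted in 90%, whereas
with 15% divergence a consensus hexamer survives intact in ~0.85^6 ≈ 38%
of copies and the conserved planted motif dominates both top-50 lists —
the same conservation-against-background contrast the real analysis
exploits. The 9-bp motif (CCTTTAATC default) is substituted at a random
internal offset into 90% of MT2_Mm and B1_Mm copies, reverse-complemented
on minus strands.

Peaks are 300 bp, summit on the planted motif midpoint, plus 12 uniform
background peaks (so ~94% of default peaks sit on motif instances); genes
number 300 with 30% of TSSs planted within 500 bp of a summit; expression
is a 6-time-point (0–72 h), duplicate-replicate TPM matrix with lognormal
baseline (median 10 TPM, log-sd 1), a 4-fold elevation at the planted time
point for 50% of genes, and multiplicative lognormal noise σ = 0.25 —
effect and noise scales chosen so a clearly responsive gene is
unambiguous, as in a strong induction series. All draws pass through one
integer-seeded generator in fixed order, so outputs are byte-reproducible.

What the generator does *not* emulate: mappability and GC structure,
clustered/nested TE insertions, indel divergence, peak-width and signal
variation, replicate-specific library effects, and count-based expression
noise. Passing benchmarks therefore demonstrate correctness of the
statistics and recovery under the stated generative model, not robustness
to those real-data complications.

## Benchmark configurations and problem sizes

Exact-test agreement is checked against Fraction-arithmetic enumeration
over every hypergeometric instance with population ≤ 30 (87,296 instances,
agreement ~3e−16). Null calibration uses 200 replicates of uniformly
random peaks over a fixed five-subfamily layout with 300–400 copies per
subfamily, and 200 random 150-gene queries from a 1,000-gene background
with a 1–10 kb ladder; copy counts, query size and ladder were sized so
that expected overlap counts are large enough for the discrete one-sided
p-values to approach their nominal level — with small counts the tests are
conservative (fractions below 0.05, not above), which is the expected
direction of the discreteness bias, and the degenerate ladder cells (d = 0
with no coincident summits, or d saturating the genome, where p ≡ 1) are
excluded from calibration by construction. Planted-signal recovery runs
10 seeds for motif and enrichment recovery and 20 for cluster recovery at
the generator defaults above.

## Known limitations

* The length-aware expectation slightly overcounts when merged peaks lie
  closer together than one mean copy length.
* Greedy nearest-first co-binding matching is not guaranteed to maximize
  the number of matched pairs (it is a deterministic, order-invariant
  heuristic).
* The binned-genome null for peak-centric overlap enrichment treats peaks
  as exchangeable bin draws and is sensitive to the bin-size choice
  (1 kb default, roughly a peak footprint).
* The built-in DEG caller is for synthetic/benchmark use; for real count
  data, ingest DEG tables from a dedicated differential-expression tool.
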