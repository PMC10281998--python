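# tebind

Statistical toolkit for asking whether a transcription factor's binding
sites concentrate on particular transposable-element (TE) subfamilies, what
sequence motif those subfamilies share, and how the genes near those sites
behave — the computational core of studies of 2-cell-stage regulators such
as DUX and ZFP352, which act through retrotransposon-derived elements like
the MERVL LTR (MT2_Mm) and SINE B1/Alu.

It is a Python library first: the public API plus the short narrative
scripts in `examples/` are the intended interface, with a thin `tebind`
command-line wrapper for shell use. Every analysis runs end to end on a
seeded synthetic genome with planted signal, so all statistics are testable
against known truth.

## What it computes

**TE copy filtering and registry** (`tebind.te`). RepeatMasker-style copies
whose genomic length deviates more than 20% from the subfamily consensus
length are removed as degenerate (boundaries inclusive). The registry keeps,
per subfamily *s*: copy count *n_s*, mean copy length *ℓ̄_s*, and the genome
size *G*.

**Peak/TE enrichment** (`tebind.enrichment`). For peaks *P* and subfamily
*s*, the observed count *O_s* is the number of distinct copies overlapping
any peak. The default *length-aware* null places a copy of length *ℓ̄_s*
uniformly on the genome; its chance of touching a merged peak of length *L*
is (L + ℓ̄_s − 1)/(G − ℓ̄_s + 1), giving a per-copy overlap probability
*q_s*, expectation E_s = n_s·q_s, and a Binomial(n_s, q_s) upper-tail
p-value, BH-adjusted across subfamilies. A *copy-universe* hypergeometric
null (all copies as population, peak-overlapping copies as the draw) is the
alternative. Co-binding of two factors is classified by summit distance
(±500 bp, greedy nearest-first pairing).

**Region-associated DEG (RAD) scan** (`tebind.rad`). At each extension
distance *d* of a ladder (default 1000, 500, 200, 100, 50, 25, 20, 15, 10,
5, 0 kb), the number of query genes with a summit within *d* of their TSS
is compared with the background-gene frequency: enrichment = observed /
(|query|·K/N) with a one-sided hypergeometric test on (N, K, |query|,
observed). Fixed-window target labelling uses ±5 kb for SINE B1 subfamilies
and ±50 kb for MT2_Mm.

**Hexamer motif assembly** (`tebind.kmer`). Sequences of peak-bound copies
are profiled as hexamer percentages (all overlapping 6-mer windows,
non-ACGT windows skipped), Z-scored per hexamer across subfamilies, the
top-50 lists of two subfamilies intersected, and shared hexamers whose
5-bp suffix/prefix overlap are chained into maximal consensus strings.

**Temporal clustering** (`tebind.temporal`). Genes are retained at mean
TPM > 1 in either group; DEGs require fold change > 2 and adjusted p <
0.05; each DEG is assigned to the time point (0–72 h) of its maximum TPM
when that maximum strictly exceeds the mean of the other time points.
Cluster/marker relations use one-sided hypergeometric overlap tests with
BH correction.

**Synthetic data** (`tebind.simulate`). A seeded generator of genome, TE
copies (with neutral per-copy divergence), planted motif, peaks, genes and
time-course TPM, with truth tables for every planted label.

## Worked example

```sh
python examples/04_motif_discovery.py
```

prints, for the default simulated genome (seed 42):

```
bound copies: MT2_Mm=60, B1_Mm=144
shared top-50 hexamers (4): ['CCTTTA', 'CTTTAA', 'TTAATC', 'TTTAAT']
chain: CCTTTAATC (9 bp, 4 hexamers)
```

The motif planted into both subfamilies is recovered: its four hexamer
tiles rank in the top 50 of both bound-copy profiles, and chaining their
5-bp overlaps reconstructs the full 9-bp consensus. The companion
`examples/01_te_enrichment.py` shows the corresponding enrichment table —
the two motif-carrying subfamilies at enrichment 20.1 and 11.1 with
adjusted p < 1e-49, background subfamilies near 1 — and
`examples/03_rad_scan.py` shows RAD enrichment decaying from 2.27 at 1 kb
to 1.00 at 50 kb. `tebind demo --seed 7 --out-dir out/` runs everything at
once and writes every table plus a run manifest.

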