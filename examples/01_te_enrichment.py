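"""Which TE subfamilies are over-represented at ChIP-seq peaks?

Simulates a 2 Mb genome where a 9-bp motif is planted into most MT2_Mm and
B1_Mm copies and peaks sit on the planted instances, then filters degenerate
copies by consensus length and compares observed vs expected copy counts
under the length-aware random-placement null.
"""

from tebind import SimConfig, build_registry, filter_te_copies, simulate_dataset
from tebind.enrichment import te_enrichment_table

data = simulate_dataset(SimConfig(seed=42))
kept, removed = filter_te_copies(data.te_copies)
registry = build_registry(kept, data.config.chrom_sizes)

print(f"{len(kept)} copies kept, {len(removed)} removed by the 20% "
      "consensus-length filter")
print(f"{'subfamily':10} {'obs':>4} {'exp':>8} {'enrich':>7} {'p_adj':>9}")
for rec in te_enrichment_table(data.peaks, kept, registry):
    print(f"{rec.subfamily:10} {rec.observed:4d} {rec.expected:8.2f} "
          f"{rec.enrichment:7.2f} {rec.p_adj:9.2e}")

# The two motif-carrying subfamilies (MT2_Mm, B1_Mm) show observed counts
# far above the random-placement expectation with tiny adjusted p-values;
# the background subfamilies sit near enrichment 1.
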