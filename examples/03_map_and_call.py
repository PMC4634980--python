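"""Map one spore's reads and call low-frequency variants.

Runs quality trimming, local alignment with the mismatch-2 / gap-3 cost
scheme and the 0.5/0.8 length/similarity filters, then the quality-screened
threshold caller with the pyro-error (homopolymer indel) filter.
"""

from sporeamp import (call_variants, caller_stats, make_panel, map_all,
                      riaox_model, simulate_reads, trim_reads)
from sporeamp.synthetic_data import ReadSimConfig

model = riaox_model()
panel = make_panel(None, 1, 1, 3, 0, 2,
                   lambda rng: float(rng.uniform(0.05, 0.9)),
                   seed=7, reference=model.sequence, position_margin=80)
spore = panel.spores[0]
# coverage must comfortably exceed 100x: below that, a single error read
# already clears the caller's 1% frequency floor
reads = trim_reads(simulate_reads(panel, spore, ReadSimConfig(
    n_reads=2000, homopolymer_indel_rate=0.005, seed=3)))

records, stats = map_all(reads, model.sequence)
print(f"mapped {stats.n_mapped}/{stats.n_reads} reads "
      f"({stats.percent_mapped}%), mean mapped read length "
      f"{stats.mean_mapped_read_length} nt")

calls = call_variants([r for r in records if r.mapped], model.sequence)
print(f"\n{len(calls)} variant calls (truth has {len(panel.truth)}):")
for c in calls:
    print(f"  pos {c.pos:>4} {c.type:<4} {c.ref or '-'}->{c.alt or '-'} "
          f"{c.count}/{c.coverage} reads = {c.frequency:.1f}%")
cs = caller_stats(calls)
print(f"mean variant coverage {cs['average_variant_coverage']}, "
      f"mean SNV coverage {cs['average_snv_coverage']}")
# Frequencies are read count / read coverage at the site. The truth variants
# stand out at their nuclear frequencies; a few low-frequency singletons
# survive near the amplicon ends where coverage tapers below ~100x and one
# error read already exceeds the 1% frequency floor — the reason the
# original experiment relied on very deep per-spore coverage.
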