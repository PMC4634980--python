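"""Simulate a heterokaryotic spore's amplicon reads with a known truth set.

Allocates variants shared by all spores / unique to one isolate / unique to
one spore, realises them on a 100-nucleus haplotype mixture, and draws
error-bearing reads for one spore.
"""

from sporeamp import make_panel, riaox_model, simulate_reads
from sporeamp.synthetic_data import ReadSimConfig

model = riaox_model()
panel = make_panel(None, n_isolates=3, n_spores_per_isolate=3,
                   n_shared=2, n_isolate_unique=1, n_spore_unique=1,
                   seed=42, reference=model.sequence, position_margin=80)
print(f"truth set: {len(panel.truth)} variants over {len(panel.spores)} spores")
for v in panel.truth[:5]:
    print(f"  pos {v.pos:>4} {v.type:<4} {v.ref or '-'}->{v.alt or '-'} "
          f"scope={v.scope} nuclear freq {v.nuclear_frequency:.1%}")

spore = panel.spores[0]
reads = simulate_reads(panel, spore, ReadSimConfig(n_reads=500, seed=1))
print(f"\n{spore}: {len(reads)} single-end reads, "
      f"mean length {sum(len(r) for r in reads) / len(reads):.0f} nt")
print("first read:", reads[0].id, reads[0].description)
# The description traces each read to its source haplotype, so callers can be
# scored against the truth.
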