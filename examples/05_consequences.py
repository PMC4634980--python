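"""Coding consequences: which variants change the AOX protein?

Classifies a few hand-picked variants against the gene model and flags
changes inside the conserved ferritin-like domain, where the catalytic
glutamate/histidine residues live.
"""

from sporeamp import predict, riaox_model
from sporeamp.gene_model import RIAOX_CONSERVED_E

model = riaox_model()
flip = {"A": "C", "C": "G", "G": "T", "T": "A"}

intron2 = [f for f in model.features if f.kind == "intron"][1]
conserved_glu = model.genomic_of_cds((RIAOX_CONSERVED_E[0] - 1) * 3 + 1)

variants = [
    (intron2.start + 10, "SNV", model.sequence[intron2.start + 9], "A"),
    (30, "SNV", model.sequence[29], flip[model.sequence[29]]),
    (conserved_glu, "SNV", model.sequence[conserved_glu - 1],
     flip[model.sequence[conserved_glu - 1]]),
    (60, "Del", model.sequence[60], ""),          # 1-bp exonic deletion
    (60, "Del", model.sequence[60:63], ""),       # 3-bp exonic deletion
]
for key in variants:
    if key[1] == "SNV" and key[2] == key[3]:
        continue
    rec = predict(key, model)
    aa = rec.aa_change_str or "-"
    print(f"pos {key[0]:>4} {key[1]:<4} {key[2] or '-'}->{key[3] or '-'}: "
          f"{rec.consequence:<16} aa={aa:<7} domain={rec.in_domain} "
          f"n_term={rec.in_n_terminal}")
# Intronic variants never change the protein; a 1-bp exonic deletion shifts
# the frame while a 3-bp one does not; the conserved-glutamate hit reports
# its E residue, the kind of change that matters for enzyme function.
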