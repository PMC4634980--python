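"""Coding-consequence prediction against a gene model.

Each variant key is classified by where it falls and what it does to the
coding sequence: intron-contained variants are ``intronic``; exonic
substitutions are retranslated through the standard genetic code into
``synonymous`` / ``missense`` / ``stop_gained`` / ``stop_lost``; exonic
length-changing events are ``frameshift`` when the net length change is not a
multiple of 3, else ``inframe_indel``; events touching both exon and intron
bases are ``boundary_spanning`` (no splice-site interpretation is attempted).
Exon bases outside the CDS (absent from the bundled gene model, possible in
user-supplied ones) classify as ``noncoding``.

Records carry flags for the conserved (ferritin-like) domain and the
N-terminal targeting region, where an amino-acid change is of particular
interest for the alternative-oxidase protein.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .gene_model import GeneModel

SEVERITY = ("stop_gained", "stop_lost", "missense", "synonymous")

AA_CLASSES = {"missense", "stop_gained", "stop_lost", "synonymous"}


class ConsequenceError(ValueError):
    pass


@dataclass(frozen=True)
class ConsequenceRecord:
    key: tuple                      # (pos, type, ref, alt)
    consequence: str
    aa_change: tuple[str, int, str] | None   # (ref_aa, aa_position, alt_aa)
    in_domain: bool
    in_n_terminal: bool

    @property
    def aa_change_str(self) -> str:
        if self.aa_change is None:
            return ""
        ref_aa, pos, alt_aa = self.aa_change
        return f"{ref_aa}{pos}{alt_aa}"


def _affected_positions(key: tuple) -> list[int]:
    pos, vtype, ref, alt = key
    if vtype in ("SNV", "MNV", "Repl"):
        return list(range(pos, pos + len(ref)))
    if vtype == "Del":
        return list(range(pos + 1, pos + 1 + len(ref)))
    # Ins: the event sits in the junction right of the anchor
    return [pos]


def predict(key: tuple, model: GeneModel) -> ConsequenceRecord:
    """Classify one variant key (pos, type, ref, alt) against the model."""
    pos, vtype, ref, alt = key
    if not 1 <= pos <= len(model):
        raise ConsequenceError(f"variant position {pos} outside the model")
    if vtype in ("SNV", "MNV", "Repl"):
        span = model.sequence[pos - 1 : pos - 1 + len(ref)]
    elif vtype == "Del":
        span = model.sequence[pos : pos + len(ref)]
    else:
        span = ""
    if vtype != "Ins" and span != ref:
        raise ConsequenceError(
            f"ref allele {ref!r} does not match the model sequence {span!r} at {pos}")

    affected = _affected_positions(key)
    if affected and affected[-1] > len(model):
        raise ConsequenceError("variant extends past the model")
    exonic_flags = [model.is_exonic(p) for p in affected]
    if vtype == "Ins":
        # an insertion falls between anchor and anchor+1
        nxt = pos + 1
        exonic_flags = [model.is_exonic(pos)]
        if nxt <= len(model):
            exonic_flags.append(model.is_exonic(nxt))

    in_dom = any(model.locate(p).in_domain for p in affected)
    in_nt = any(model.locate(p).in_n_terminal for p in affected)

    if all(not f for f in exonic_flags):
        return ConsequenceRecord(key, "intronic", None, in_dom, in_nt)
    if not all(exonic_flags):
        return ConsequenceRecord(key, "boundary_spanning", None, in_dom, in_nt)

    # fully exonic from here
    if vtype in ("Ins", "Del", "Repl"):
        net = len(alt) - len(ref)
        cls = "frameshift" if net % 3 != 0 else "inframe_indel"
        return ConsequenceRecord(key, cls, None, in_dom, in_nt)

    # SNV / MNV: retranslate the affected codons
    cds_offsets = [model.cds_offset(p) for p in affected]
    if any(c is None for c in cds_offsets):
        return ConsequenceRecord(key, "noncoding", None, in_dom, in_nt)
    if cds_offsets != list(range(cds_offsets[0], cds_offsets[0] + len(affected))):
        # substituted bases are not contiguous in the spliced CDS
        return ConsequenceRecord(key, "boundary_spanning", None, in_dom, in_nt)

    cds = model.cds()
    alt_cds = (cds[: cds_offsets[0] - 1] + alt + cds[cds_offsets[-1]:])
    ref_pep = _raw_translate(cds)
    alt_pep = _raw_translate(alt_cds)
    first_codon = (cds_offsets[0] - 1) // 3 + 1
    cls, aa_change = _classify_substitution(ref_pep, alt_pep, first_codon)
    return ConsequenceRecord(key, cls, aa_change, in_dom, in_nt)


def _raw_translate(cds: str) -> str:
    """Translation including stops ('*'), no validation."""
    return str(Seq(cds).translate())


def _classify_substitution(ref_pep: str, alt_pep: str, first_codon: int):
    """Compare peptides (both include the terminal stop as '*').

    The first altered residue is reported; for multi-codon changes the class
    is the most severe one (stop_gained > stop_lost > missense > synonymous).
    A change leaving the peptide intact is synonymous at the affected codon.
    """
    assert len(ref_pep) == len(alt_pep)
    diffs = [i for i, (a, b) in enumerate(zip(ref_pep, alt_pep)) if a != b]
    if not diffs:
        i = first_codon - 1
        return "synonymous", (ref_pep[i], i + 1, alt_pep[i])
    first = diffs[0]
    classes = set()
    for i in diffs:
        if alt_pep[i] == "*":
            classes.add("stop_gained")
        elif ref_pep[i] == "*":
            classes.add("stop_lost")
        else:
            classes.add("missense")
    for cls in SEVERITY:
        if cls in classes:
            return cls, (ref_pep[first], first + 1, alt_pep[first])
    raise AssertionError("unreachable")


def predict_all(keys, model: GeneModel) -> list[ConsequenceRecord]:
    return [predict(k, model) for k in keys]


def write_consequences_tsv(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\ttype\tref\talt\tconsequence\taa_change\t"
                 "in_domain\tin_n_terminal\n")
        for r in records:
            pos, vtype, ref, alt = r.key
            fh.write(f"{pos}\t{vtype}\t{ref}\t{alt}\t{r.consequence}\t"
                     f"{r.aa_change_str}\t{int(r.in_domain)}\t"
                     f"{int(r.in_n_terminal)}\n")
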