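"""Quality-score low-frequency variant detection from mapped amplicon reads.

The caller follows a threshold-filter design suited to very deep single-gene
coverage, where variants present on only a few percent of nuclei must be
separated from sequencing error:

1. *Base screening* — a read base is trusted only if its own Phred quality is
   at least ``min_central_quality`` (20) and the mean quality of read bases
   within ``neighborhood_radius`` (5) positions of it is at least
   ``min_neighborhood_quality`` (15). Untrusted bases contribute to neither
   allele counts nor coverage.
2. *Candidate generation* — at every reference position, each non-reference
   allele (substitution, or anchored left-aligned insertion/deletion) with
   screened coverage >= ``min_coverage`` (10) and frequency
   (100 * count / coverage) >= ``min_variant_frequency`` (1%) is a candidate.
3. *Pyro-error removal* — indel candidates inside reference homopolymer runs
   of length >= ``homopolymer_min_length`` (3) are removed when their
   frequency is below ``pyro_frequency_below`` (0.8, i.e. 80%): the indel
   artifacts typical of pyrosequencing-like chemistry concentrate in
   homopolymers, so only near-fixed homopolymer indels are believed.
4. *MNV merging* — runs of adjacent SNV candidates collapse into one MNV when
   the constituent alternate bases co-occur on the same reads often enough
   (>= ``mnv_cooccurrence_min`` of the reads carrying any of them); merged
   constituents are suppressed. A deletion and insertion anchored at the same
   base merge analogously into a replacement (Repl).

Variant frequency is always read count divided by read coverage, in percent.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._util import homopolymer_runs, round_half_away
from .mapping import AlignmentRecord

TYPE_RANK = {"SNV": 0, "MNV": 1, "Ins": 2, "Del": 3, "Repl": 4}


class CallerError(ValueError):
    pass


@dataclass
class CallerParams:
    min_coverage: int = 10
    min_variant_frequency: float = 1.0     # percent
    neighborhood_radius: int = 5
    min_neighborhood_quality: float = 15.0
    min_central_quality: float = 20.0
    pyro_filter_enabled: bool = True
    homopolymer_min_length: int = 3
    pyro_frequency_below: float = 0.8      # fraction of 1; 0.8 == 80%
    mnv_cooccurrence_min: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.min_variant_frequency <= 100:
            raise CallerError("min_variant_frequency must be in (0,100]")
        for v in (self.min_coverage, self.neighborhood_radius,
                  self.min_neighborhood_quality, self.min_central_quality,
                  self.homopolymer_min_length):
            if v < 0:
                raise CallerError("thresholds must be non-negative")
        if not 0 <= self.pyro_frequency_below <= 1:
            raise CallerError("pyro_frequency_below must be in [0,1]")
        if not 0 <= self.mnv_cooccurrence_min <= 1:
            raise CallerError("mnv_cooccurrence_min must be in [0,1]")


@dataclass(frozen=True)
class VariantCall:
    pos: int
    type: str
    ref: str
    alt: str
    count: int
    coverage: int
    frequency: float            # percent, 100 * count / coverage
    supporting: frozenset = field(default_factory=frozenset)
    filter_status: str = "PASS"

    @property
    def key(self) -> tuple:
        return (self.pos, self.type, self.ref, self.alt)


@dataclass
class Pileup:
    """Screened pileup: per-position covering reads and per-allele support."""

    coverage: dict[int, set]                       # pos -> read ids
    snv_support: dict[int, dict[str, set]]         # pos -> alt base -> read ids
    ins_support: dict[tuple[int, str], set]        # (anchor, inserted) -> ids
    del_support: dict[tuple[int, str], set]        # (anchor, deleted) -> ids

    def depth(self, pos: int) -> int:
        return len(self.coverage.get(pos, ()))


def screen_bases(alignments: Sequence[AlignmentRecord],
                 params: CallerParams | None = None) -> dict[str, np.ndarray]:
    """Per-read boolean mask of trusted bases (read coordinates, oriented as
    stored). The neighbourhood mean includes the central base and truncates
    at read ends."""
    params = params or CallerParams()
    params.validate()
    out: dict[str, np.ndarray] = {}
    r = params.neighborhood_radius
    for rec in alignments:
        if not rec.qualities:
            raise CallerError(f"read {rec.read_id} has no base qualities")
        q = np.asarray(rec.qualities, dtype=float)
        n = len(q)
        csum = np.concatenate([[0.0], np.cumsum(q)])
        lo = np.maximum(np.arange(n) - r, 0)
        hi = np.minimum(np.arange(n) + r + 1, n)
        window_mean = (csum[hi] - csum[lo]) / (hi - lo)
        out[rec.read_id] = (q >= params.min_central_quality) & \
                           (window_mean >= params.min_neighborhood_quality)
    return out


def build_pileup(alignments: Sequence[AlignmentRecord], reference: str,
                 params: CallerParams | None = None) -> Pileup:
    """Screened pileup over mapped alignments.

    An indel observation is keyed by its left-aligned anchor and event
    sequence and requires the anchor base to be trusted; match/mismatch bases
    require their own base to be trusted.
    """
    params = params or CallerParams()
    masks = screen_bases([a for a in alignments if a.mapped], params)
    reference = reference.upper()
    L = len(reference)
    pile = Pileup(defaultdict(set), defaultdict(lambda: defaultdict(set)),
                  defaultdict(set), defaultdict(set))
    for rec in alignments:
        if not rec.mapped:
            continue
        mask = masks[rec.read_id]
        r = rec.ref_start
        i = 0
        last_m_trusted = False
        last_m_pos = 0
        for op, n in rec.ops:
            if op in ("=", "X"):
                for k in range(n):
                    pos = r + k
                    if pos < 1 or pos > L:
                        continue
                    if mask[i + k]:
                        pile.coverage[pos].add(rec.read_id)
                        base = rec.seq[i + k]
                        if base != reference[pos - 1]:
                            pile.snv_support[pos][base].add(rec.read_id)
                last_m_pos = r + n - 1
                last_m_trusted = bool(mask[i + n - 1])
                r += n
                i += n
            elif op == "I":
                ins = rec.seq[i : i + n]
                anchor = r - 1
                if last_m_trusted and 1 <= anchor <= L:
                    p, _, a = _left_align_event(reference, anchor, "", ins)
                    pile.ins_support[(p, a)].add(rec.read_id)
                i += n
            elif op == "D":
                dele = reference[r - 1 : r - 1 + n]
                anchor = r - 1
                if last_m_trusted and 1 <= anchor <= L:
                    p, d, _ = _left_align_event(reference, anchor, dele, "")
                    pile.del_support[(p, d)].add(rec.read_id)
                r += n
            else:  # S
                i += n
    return pile


def _left_align_event(reference: str, anchor: int, ref: str,
                      alt: str) -> tuple[int, str, str]:
    seq = ref if ref else alt
    while anchor >= 1 and seq and seq[-1] == reference[anchor - 1]:
        seq = reference[anchor - 1] + seq[:-1]
        anchor -= 1
    return (anchor, seq, alt) if ref else (anchor, ref, seq)


def _in_homopolymer(reference: str, pos: int, event_seq: str, is_del: bool,
                    min_len: int) -> bool:
    """Is an anchored, left-aligned indel event inside a reference homopolymer
    run of at least ``min_len``? The event must be a single-base repeat whose
    base matches a qualifying run adjacent to the anchor."""
    if not event_seq or len(set(event_seq)) != 1:
        return False
    base = event_seq[0]
    for (s, e, b) in homopolymer_runs(reference, min_len):
        if b != base:
            continue
        # after left-alignment the anchor sits immediately left of the run
        if s - 1 <= pos <= e:
            return True
    return False


def call_variants(alignments: Sequence[AlignmentRecord], reference: str,
                  params: CallerParams | None = None) -> list[VariantCall]:
    """Detect, filter, merge and classify variants; deterministic output order
    (position, then SNV < MNV < Ins < Del < Repl, then alt allele)."""
    params = params or CallerParams()
    params.validate()
    if not alignments:
        return []
    reference = reference.upper()
    for a in alignments:
        if a.mapped and a.ref_end > len(reference):
            raise CallerError(f"alignment {a.read_id} extends past the reference")
    pile = build_pileup(alignments, reference, params)

    snv_cands: dict[int, list[tuple[str, set]]] = defaultdict(list)
    calls: list[VariantCall] = []

    def passes(count: int, cov: int) -> bool:
        return (cov >= params.min_coverage
                and 100.0 * count / cov >= params.min_variant_frequency)

    for pos in sorted(pile.snv_support):
        cov = pile.depth(pos)
        for alt, ids in sorted(pile.snv_support[pos].items()):
            if passes(len(ids), cov):
                snv_cands[pos].append((alt, ids))

    indel_cands: dict[tuple[int, str], tuple[str, set]] = {}
    for (anchor, ins), ids in sorted(pile.ins_support.items()):
        cov = pile.depth(anchor)
        if not passes(len(ids), cov):
            continue
        freq = len(ids) / cov
        if (params.pyro_filter_enabled
                and _in_homopolymer(reference, anchor, ins, False,
                                    params.homopolymer_min_length)
                and freq < params.pyro_frequency_below):
            continue
        indel_cands[(anchor, "Ins")] = (ins, ids)
    for (anchor, dele), ids in sorted(pile.del_support.items()):
        cov = pile.depth(anchor)
        if not passes(len(ids), cov):
            continue
        freq = len(ids) / cov
        if (params.pyro_filter_enabled
                and _in_homopolymer(reference, anchor, dele, True,
                                    params.homopolymer_min_length)
                and freq < params.pyro_frequency_below):
            continue
        indel_cands[(anchor, "Del")] = (dele, ids)

    # --- MNV merging over runs of adjacent SNV candidates ------------------
    positions = sorted(snv_cands)
    used: set[int] = set()
    idx = 0
    while idx < len(positions):
        pos = positions[idx]
        if pos in used:
            idx += 1
            continue
        # best-supported alt per position is the merge candidate
        block = [(pos, *max(snv_cands[pos], key=lambda t: (len(t[1]), t[0])))]
        nxt = pos + 1
        while nxt in snv_cands and nxt not in used:
            alt, ids = max(snv_cands[nxt], key=lambda t: (len(t[1]), t[0]))
            trial = block + [(nxt, alt, ids)]
            if _cooccurrence(trial, pile) >= params.mnv_cooccurrence_min:
                block = trial
                nxt += 1
            else:
                break
        if len(block) >= 2:
            covering = set.intersection(*(pile.coverage[p] for p, _, _ in block))
            carriers = set.intersection(*(ids for _, _, ids in block)) & covering
            cov = len(covering)
            if passes(len(carriers), cov):
                ref_allele = reference[block[0][0] - 1 : block[-1][0]]
                alt_allele = "".join(alt for _, alt, _ in block)
                calls.append(VariantCall(block[0][0], "MNV", ref_allele,
                                         alt_allele, len(carriers), cov,
                                         100.0 * len(carriers) / cov,
                                         frozenset(carriers)))
                merged_positions = {p for p, _, _ in block}
                merged_alts = {(p, alt) for p, alt, _ in block}
                used.update(merged_positions)
                # suppress the constituent SNVs; keep other alts at those
                # positions as independent SNVs
                for p in merged_positions:
                    snv_cands[p] = [(a, ids) for (a, ids) in snv_cands[p]
                                    if (p, a) not in merged_alts]
                idx = positions.index(block[-1][0]) + 1
                continue
        idx += 1

    for pos in sorted(snv_cands):
        cov = pile.depth(pos)
        for alt, ids in snv_cands[pos]:
            calls.append(VariantCall(pos, "SNV", reference[pos - 1], alt,
                                     len(ids), cov, 100.0 * len(ids) / cov,
                                     frozenset(ids)))

    # --- Repl: same-anchor Del + Ins ---------------------------------------
    anchors_with_both = {a for (a, k) in indel_cands if k == "Del"} & \
                        {a for (a, k) in indel_cands if k == "Ins"}
    emitted_repl = set()
    for anchor in sorted(anchors_with_both):
        dele, del_ids = indel_cands[(anchor, "Del")]
        ins, ins_ids = indel_cands[(anchor, "Ins")]
        either = del_ids | ins_ids
        both = del_ids & ins_ids
        if either and len(both) / len(either) >= params.mnv_cooccurrence_min:
            cov = pile.depth(anchor)
            if passes(len(both), cov):
                if len(dele) != len(ins):
                    vtype = "Repl"
                else:
                    vtype = "MNV" if len(dele) >= 2 else "SNV"
                calls.append(VariantCall(anchor + 1, vtype, dele, ins,
                                         len(both), cov,
                                         100.0 * len(both) / cov,
                                         frozenset(both)))
                emitted_repl.add(anchor)
    for (anchor, kind), (seq, ids) in indel_cands.items():
        if anchor in emitted_repl:
            continue
        cov = pile.depth(anchor)
        ref_a, alt_a = (seq, "") if kind == "Del" else ("", seq)
        calls.append(VariantCall(anchor, kind, ref_a, alt_a, len(ids), cov,
                                 100.0 * len(ids) / cov, frozenset(ids)))

    calls.sort(key=lambda c: (c.pos, TYPE_RANK[c.type], c.alt))
    return calls


def _cooccurrence(block, pile: Pileup) -> float:
    """Fraction of reads carrying every constituent alt among reads covering
    all block positions and carrying at least one constituent alt."""
    covering = set.intersection(*(pile.coverage[p] for p, _, _ in block))
    any_alt = set.union(*(ids for _, _, ids in block)) & covering
    if not any_alt:
        return 0.0
    all_alt = set.intersection(*(ids for _, _, ids in block)) & covering
    return len(all_alt) / len(any_alt)


def caller_stats(calls: Sequence[VariantCall]) -> dict:
    """Mean coverage over all calls and over SNV calls only (rounded to the
    nearest integer); absent (None) when there is nothing to average."""
    cov = [c.coverage for c in calls]
    snv = [c.coverage for c in calls if c.type == "SNV"]
    return {
        "average_variant_coverage":
            round_half_away(sum(cov) / len(cov)) if cov else None,
        "average_snv_coverage":
            round_half_away(sum(snv) / len(snv)) if snv else None,
    }


# -- outputs -----------------------------------------------------------------

def write_vcf(calls: Sequence[VariantCall], reference: str, path,
              contig: str = "amplicon", sample: str | None = None) -> None:
    """VCF 4.2 with COUNT/COV/FREQ INFO fields; anchored indel alleles get
    the reference anchor base prepended per VCF convention."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={len(reference)}>\n")
        fh.write('##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant type">\n')
        fh.write('##INFO=<ID=COUNT,Number=1,Type=Integer,Description="Supporting reads">\n')
        fh.write('##INFO=<ID=COV,Number=1,Type=Integer,Description="Screened coverage">\n')
        fh.write('##INFO=<ID=FREQ,Number=1,Type=Float,Description="Frequency percent">\n')
        if sample:
            fh.write(f"##sample=<ID={sample}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.pos, TYPE_RANK[c.type], c.alt)):
            pos, ref, alt = vcf_alleles(c, reference)
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\t{c.filter_status}\t"
                     f"TYPE={c.type};COUNT={c.count};COV={c.coverage};"
                     f"FREQ={c.frequency:.4g}\n")


def vcf_alleles(call: VariantCall, reference: str) -> tuple[int, str, str]:
    """(pos, ref, alt) in VCF convention for a call keyed in anchored form."""
    if call.type in ("Ins", "Del"):
        if call.pos >= 1:
            anchor = reference[call.pos - 1]
            return call.pos, anchor + call.ref, anchor + call.alt
        # event at the very start of the reference: anchor on the right
        right = reference[len(call.ref)] if call.type == "Del" else reference[0]
        return 1, call.ref + right, call.alt + right
    return call.pos, call.ref, call.alt


def write_calls_tsv(calls: Sequence[VariantCall], path,
                    sample: str | None = None) -> None:
    """Annotated-table analog: one row per call."""
    with open(path, "w") as fh:
        cols = "pos\ttype\tref\talt\tcount\tcoverage\tfrequency_percent"
        fh.write((f"sample\t{cols}\n") if sample else (cols + "\n"))
        for c in calls:
            row = f"{c.pos}\t{c.type}\t{c.ref}\t{c.alt}\t{c.count}\t" \
                  f"{c.coverage}\t{c.frequency:.4f}"
            fh.write((f"{sample}\t{row}\n") if sample else (row + "\n"))
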