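"""Truth-annotated amplicon read simulation for multinucleate spores.

A mature spore of an arbuscular mycorrhizal fungus carries hundreds of nuclei
that need not be genetically identical (heterokaryosis), so deep amplicon
sequencing of a single spore sees variant alleles at essentially any frequency
between 0 and 1. This module generates such datasets with a known truth set:

* :func:`make_panel` allocates variants to scopes — shared by every spore,
  unique to one isolate, or unique to one spore — with declared nuclear
  frequencies, and realises them as a finite mixture of nuclear haplotypes per
  spore (default 100 nuclei), so variants placed on the same nucleus co-occur
  on reads.
* :func:`simulate_reads` draws single-end reads from the haplotype mixture
  with Phred-linked substitution errors and homopolymer-run indel errors
  (the dominant artifact of pyrosequencing-like chemistry).

Everything is deterministic under the configured seeds; reads carry their
source haplotype in the FASTQ description for truth tracing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import homopolymer_runs

VARIANT_TYPES = ("SNV", "MNV", "Ins", "Del", "Repl")


class PanelError(ValueError):
    """Infeasible panel request or inconsistent variant specification."""


@dataclass(frozen=True)
class VariantSpec:
    """A truth variant: anchored, left-aligned, allele strings exclude the anchor.

    ``pos`` is the 1-based reference position of the variant itself for
    SNV/MNV/Repl, and of the anchor base immediately left of the event for
    Ins/Del. ``ref`` is empty for Ins, ``alt`` empty for Del.
    """

    pos: int
    type: str
    ref: str
    alt: str
    scope: str            # "shared_all" | "isolate:<id>" | "spore:<id>"
    nuclear_frequency: float

    @property
    def key(self) -> tuple:
        return (self.pos, self.type, self.ref, self.alt)

    def validate(self, reference: str) -> None:
        if self.type not in VARIANT_TYPES:
            raise PanelError(f"unknown variant type {self.type!r}")
        if not 0 < self.nuclear_frequency <= 1:
            raise PanelError(f"nuclear frequency {self.nuclear_frequency} not in (0,1]")
        if self.type == "Ins":
            if self.ref != "" or not self.alt:
                raise PanelError("Ins must have empty ref and non-empty alt")
        elif self.type == "Del":
            if self.alt != "" or not self.ref:
                raise PanelError("Del must have empty alt and non-empty ref")
        elif self.type == "SNV":
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise PanelError("SNV must be a 1->1 substitution")
        elif self.type == "MNV":
            if len(self.ref) != len(self.alt) or len(self.ref) < 2:
                raise PanelError("MNV must be a k->k substitution, k>=2")
        else:  # Repl
            if not self.ref or not self.alt or len(self.ref) == len(self.alt):
                raise PanelError("Repl must change length with both alleles non-empty")
        if self.type in ("SNV", "MNV", "Repl"):
            span = reference[self.pos - 1 : self.pos - 1 + len(self.ref)]
        else:  # anchored events: ref bases sit right of the anchor
            span = reference[self.pos : self.pos + len(self.ref)]
        if self.type != "Ins" and span != self.ref:
            raise PanelError(
                f"ref allele {self.ref!r} does not match reference {span!r} at {self.pos}"
            )


@dataclass
class HaplotypePanel:
    """Reference + truth variants + per-spore haplotype mixtures.

    ``pools[spore]`` is a list of ``(haplotype_sequence, weight, variant_keys)``
    where weights sum to 1 and ``variant_keys`` lists the truth keys carried by
    that haplotype.
    """

    reference: str
    isolates: list[str]
    spores_per_isolate: dict[str, list[str]]
    truth: list[VariantSpec]
    pools: dict[str, list[tuple[str, float, tuple]]]

    @property
    def spores(self) -> list[str]:
        return [s for iso in self.isolates for s in self.spores_per_isolate[iso]]

    def isolate_of(self, spore: str) -> str:
        for iso, sps in self.spores_per_isolate.items():
            if spore in sps:
                return iso
        raise KeyError(spore)

    def expected_variants(self, spore: str) -> list[VariantSpec]:
        """Truth variants whose scope includes this spore."""
        iso = self.isolate_of(spore)
        out = []
        for v in self.truth:
            if v.scope == "shared_all" or v.scope == f"isolate:{iso}" \
                    or v.scope == f"spore:{spore}":
                out.append(v)
        return out


@dataclass
class ReadSimConfig:
    """Read-generation settings.

    Defaults mirror the study's sequencing regime at its smallest scale: a few
    thousand single-end reads per spore with mean mapped length in the
    105–156 nt band, Phred-linked substitution errors and homopolymer indel
    errors at a per-run rate scaled by (run length − 1).
    """

    n_reads: int = 4500
    read_length_mean: float = 130.0
    read_length_sd: float = 25.0
    min_read_length: int = 50
    quality_mean: float = 30.0
    quality_sd: float = 5.0
    quality_min: int = 2
    quality_max: int = 40
    substitution_errors: bool = True
    homopolymer_indel_rate: float = 0.002
    homopolymer_min_run: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_reads <= 0:
            raise PanelError("n_reads must be positive")
        if not 0 <= self.homopolymer_indel_rate <= 1:
            raise PanelError("homopolymer_indel_rate must be in [0,1]")
        if self.min_read_length < 1:
            raise PanelError("min_read_length must be >= 1")


def default_frequency_sampler(rng: np.random.Generator) -> float:
    """Nuclear-frequency draw: mostly a low band (0.5–20%), some a high band
    (80–100%) — echoing the observed spectrum where most within-spore variants
    sit below 20% frequency with a near-fixed tail."""
    if rng.random() < 0.8:
        return float(rng.uniform(0.005, 0.20))
    return float(rng.uniform(0.80, 1.00))


def random_reference(length: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def _left_align(reference: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align an anchored indel (Ins: ref=='', Del: alt=='') against the
    reference; pos is the anchor. Standard VCF-style shifting."""
    seq = ref if ref else alt
    while pos >= 1 and seq and seq[-1] == reference[pos - 1]:
        seq = reference[pos - 1] + seq[:-1]
        pos -= 1
    if ref:
        return pos, seq, alt
    return pos, ref, seq


def _random_variant(reference: str, pos: int, vtype: str,
                    rng: np.random.Generator) -> tuple[int, str, str]:
    """Draw alleles for a variant of the given type at/after ``pos``."""
    bases = "ACGT"
    if vtype == "SNV":
        ref = reference[pos - 1]
        alt = rng.choice([b for b in bases if b != ref])
        return pos, ref, str(alt)
    if vtype == "MNV":
        k = int(rng.integers(2, 4))
        ref = reference[pos - 1 : pos - 1 + k]
        while True:
            alt = "".join(str(rng.choice([b for b in bases if b != r]))
                          for r in ref)
            # avoid alts that are one-base shifts of the reference: an
            # aligner scores those as del+ins, not as a block substitution
            if alt[1:] != ref[:-1] and alt[:-1] != ref[1:]:
                return pos, ref, alt
    if vtype == "Ins":
        k = int(rng.integers(1, 3))
        ins = "".join(bases[i] for i in rng.integers(0, 4, k))
        p, r, a = _left_align(reference, pos, "", ins)
        return p, r, a
    if vtype == "Del":
        k = int(rng.integers(1, 3))
        dele = reference[pos : pos + k]
        p, r, a = _left_align(reference, pos, dele, "")
        return p, r, a
    # Repl: delete 2, insert 1 (or the reverse)
    if rng.random() < 0.5:
        ref = reference[pos - 1 : pos + 1]
        alt = str(rng.choice([b for b in bases if b != ref[0]]))
    else:
        ref = reference[pos - 1]
        alt = str(rng.choice([b for b in bases if b != ref])) + str(rng.choice(list(bases)))
    return pos, ref, alt


def make_panel(
    reference_length: int | None,
    n_isolates: int,
    n_spores_per_isolate: int,
    n_shared: int,
    n_isolate_unique: int,
    n_spore_unique: int,
    frequency_sampler: Callable[[np.random.Generator], float] | None = None,
    seed: int = 0,
    *,
    reference: str | None = None,
    type_weights: dict[str, float] | None = None,
    position_margin: int = 10,
    min_spacing: int = 6,
    n_nuclei: int = 100,
) -> HaplotypePanel:
    """Allocate a truth set of variants across scopes and build haplotype pools.

    Exactly ``n_shared + n_isolates*n_isolate_unique + n_spores*n_spore_unique``
    variants are created at distinct positions (pairwise separation at least
    ``min_spacing`` and at least ``position_margin`` from either reference
    end). Each variant is realised on ``round(f * n_nuclei)`` nuclei (at least
    one) of every spore in its scope; nuclei sharing an identical variant set
    collapse into one weighted haplotype.
    """
    rng = np.random.default_rng(seed)
    if reference is None:
        if reference_length is None or reference_length < 50:
            raise PanelError("reference_length must be >= 50")
        reference = random_reference(reference_length, rng)
    L = len(reference)
    if L < 50:
        raise PanelError("reference must be >= 50 nt")
    sampler = frequency_sampler or default_frequency_sampler
    weights = type_weights or {"SNV": 0.65, "MNV": 0.10, "Ins": 0.10, "Del": 0.15}
    types = list(weights)
    probs = np.array([weights[t] for t in types], dtype=float)
    probs /= probs.sum()

    isolates = [f"ISO{i + 1}" for i in range(n_isolates)]
    spores_per_isolate = {
        iso: [f"{iso}_S{j + 1}" for j in range(n_spores_per_isolate)]
        for iso in isolates
    }
    spores = [s for iso in isolates for s in spores_per_isolate[iso]]

    scopes = (["shared_all"] * n_shared
              + [f"isolate:{iso}" for iso in isolates for _ in range(n_isolate_unique)]
              + [f"spore:{sp}" for sp in spores for _ in range(n_spore_unique)])
    n_total = len(scopes)
    lo, hi = position_margin + 1, L - position_margin
    capacity = max(0, (hi - lo) // min_spacing + 1)
    if n_total > capacity:
        raise PanelError(
            f"cannot place {n_total} variants with spacing {min_spacing} in "
            f"[{lo},{hi}] (capacity {capacity})"
        )

    positions: list[int] = []
    attempts = 0
    while len(positions) < n_total:
        attempts += 1
        if attempts > 10000 * n_total:
            raise PanelError("could not place variants without collisions")
        p = int(rng.integers(lo, hi + 1))
        if all(abs(p - q) >= min_spacing for q in positions):
            positions.append(p)
    positions.sort()
    order = rng.permutation(n_total)

    truth: list[VariantSpec] = []
    for idx, scope in zip(order, scopes):
        pos = positions[idx]
        vtype = str(rng.choice(types, p=probs))
        p, ref, alt = _random_variant(reference, pos, vtype, rng)
        v = VariantSpec(p, vtype, ref, alt, scope, sampler(rng))
        v.validate(reference)
        truth.append(v)
    truth.sort(key=lambda v: v.pos)

    pools = {
        sp: _build_pool(reference, _assign_nuclei(truth, sp, spores_per_isolate,
                                                  n_nuclei, rng), n_nuclei)
        for sp in spores
    }
    return HaplotypePanel(reference, isolates, spores_per_isolate, truth, pools)


def _assign_nuclei(truth: Sequence[VariantSpec], spore: str,
                   spores_per_isolate: dict[str, list[str]], n_nuclei: int,
                   rng: np.random.Generator) -> list[tuple[VariantSpec, frozenset]]:
    iso = next(i for i, sps in spores_per_isolate.items() if spore in sps)
    out = []
    for v in truth:
        if v.scope not in ("shared_all", f"isolate:{iso}", f"spore:{spore}"):
            continue
        k = max(1, round(v.nuclear_frequency * n_nuclei))
        nuclei = frozenset(int(x) for x in rng.choice(n_nuclei, size=k, replace=False))
        out.append((v, nuclei))
    return out


def _apply_variants(reference: str, variants: Sequence[VariantSpec]) -> str:
    """Apply non-overlapping variants to the reference (descending position)."""
    seq = reference
    for v in sorted(variants, key=lambda v: v.pos, reverse=True):
        if v.type in ("SNV", "MNV", "Repl"):
            seq = seq[: v.pos - 1] + v.alt + seq[v.pos - 1 + len(v.ref):]
        elif v.type == "Ins":
            seq = seq[: v.pos] + v.alt + seq[v.pos:]
        else:  # Del
            seq = seq[: v.pos] + seq[v.pos + len(v.ref):]
    return seq


def _build_pool(reference: str,
                assignments: list[tuple[VariantSpec, frozenset]],
                n_nuclei: int) -> list[tuple[str, float, tuple]]:
    """Collapse per-nucleus variant sets into weighted haplotypes."""
    per_nucleus: dict[int, list[VariantSpec]] = {i: [] for i in range(n_nuclei)}
    for v, nuclei in assignments:
        for n in nuclei:
            per_nucleus[n].append(v)
    groups: dict[tuple, int] = {}
    variants_of: dict[tuple, list[VariantSpec]] = {}
    for vs in per_nucleus.values():
        key = tuple(sorted(v.key for v in vs))
        groups[key] = groups.get(key, 0) + 1
        variants_of[key] = vs
    pool = []
    for key, count in sorted(groups.items()):
        seq = _apply_variants(reference, variants_of[key])
        pool.append((seq, count / n_nuclei, key))
    return pool


def panel_from_assignments(
    reference: str,
    spores_per_isolate: dict[str, list[str]],
    truth: Sequence[VariantSpec],
    assignments: dict[str, list[tuple[VariantSpec, frozenset]]],
    n_nuclei: int = 100,
) -> HaplotypePanel:
    """Build a panel from explicit per-spore nucleus assignments (used when a
    test needs controlled linkage, e.g. two SNVs on the same nuclei)."""
    for v in truth:
        v.validate(reference)
    pools = {sp: _build_pool(reference, assignments.get(sp, []), n_nuclei)
             for iso in spores_per_isolate for sp in spores_per_isolate[iso]}
    return HaplotypePanel(reference, list(spores_per_isolate),
                          dict(spores_per_isolate), list(truth), pools)


# -- read simulation ---------------------------------------------------------

def simulate_reads(panel: HaplotypePanel, spore_id: str,
                   config: ReadSimConfig) -> list[SeqRecord]:
    """Draw truth-traced single-end reads for one spore.

    Each read comes from a haplotype picked by mixture weight, from a uniform
    window of that haplotype. Per-base Phred qualities are drawn from a
    clipped normal; a base substitutes with probability ``10**(-Q/10)`` when
    substitution errors are enabled. Within each homopolymer run of length
    ``r >= homopolymer_min_run`` overlapping the read, a 1-bp indel error is
    injected with probability ``homopolymer_indel_rate * (r - 1)``.
    """
    config.validate()
    if spore_id not in panel.pools:
        raise PanelError(f"unknown spore {spore_id!r}")
    rng = np.random.default_rng(config.seed)
    pool = panel.pools[spore_id]
    weights = np.array([w for (_, w, _) in pool], dtype=float)
    weights /= weights.sum()
    reads: list[SeqRecord] = []
    for i in range(config.n_reads):
        h = int(rng.choice(len(pool), p=weights))
        hap, _, keys = pool[h]
        rl = int(round(rng.normal(config.read_length_mean, config.read_length_sd)))
        rl = max(config.min_read_length, min(rl, len(hap)))
        start = int(rng.integers(0, len(hap) - rl + 1))  # 0-based on haplotype
        seq = hap[start : start + rl]
        seq = _inject_homopolymer_indels(seq, config, rng)
        quals = np.clip(
            np.rint(rng.normal(config.quality_mean, config.quality_sd, len(seq))),
            config.quality_min, config.quality_max,
        ).astype(int)
        bases = list(seq)
        if config.substitution_errors:
            p_err = 10.0 ** (-quals / 10.0)
            hits = np.nonzero(rng.random(len(bases)) < p_err)[0]
            for j in hits:
                bases[j] = str(rng.choice([b for b in "ACGT" if b != bases[j]]))
        rec = SeqRecord(
            Seq("".join(bases)),
            id=f"{spore_id}:read{i}",
            description=f"hap={h} start={start + 1} spore={spore_id}",
        )
        rec.letter_annotations["phred_quality"] = [int(q) for q in quals]
        reads.append(rec)
    return reads


def _inject_homopolymer_indels(seq: str, config: ReadSimConfig,
                               rng: np.random.Generator) -> str:
    if config.homopolymer_indel_rate <= 0:
        return seq
    edits = []  # (0-based position in run, +1/-1, base)
    for (s, e, base) in homopolymer_runs(seq, config.homopolymer_min_run):
        run_len = e - s + 1
        if rng.random() < config.homopolymer_indel_rate * (run_len - 1):
            edits.append((s - 1, +1 if rng.random() < 0.5 else -1, base))
    for (p, d, base) in sorted(edits, reverse=True):
        if d > 0:
            seq = seq[:p] + base + seq[p:]
        else:
            seq = seq[:p] + seq[p + 1:]
    return seq


# -- truth/reads IO ----------------------------------------------------------

def write_fastq(reads: Sequence[SeqRecord], path) -> None:
    SeqIO.write(list(reads), str(path), "fastq")


def write_truth_tsv(panel: HaplotypePanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\ttype\tref\talt\tscope\tnuclear_frequency\n")
        for v in panel.truth:
            fh.write(f"{v.pos}\t{v.type}\t{v.ref}\t{v.alt}\t{v.scope}\t"
                     f"{v.nuclear_frequency:.6g}\n")


def write_truth_vcf(panel: HaplotypePanel, path, contig: str = "amplicon") -> None:
    """Ground-truth VCF (anchored alleles get the anchor base prepended)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={len(panel.reference)}>\n")
        fh.write('##INFO=<ID=SCOPE,Number=1,Type=String,Description="Truth scope">\n')
        fh.write('##INFO=<ID=NF,Number=1,Type=Float,Description="Nuclear frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(panel.truth, key=lambda v: v.pos):
            if v.type in ("Ins", "Del"):
                anchor = panel.reference[v.pos - 1]
                ref, alt = anchor + v.ref, anchor + v.alt
            else:
                ref, alt = v.ref, v.alt
            scope = v.scope.replace(":", "_")
            fh.write(f"{contig}\t{v.pos}\t.\t{ref}\t{alt}\t.\t.\t"
                     f"SCOPE={scope};NF={v.nuclear_frequency:.6g}\n")
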