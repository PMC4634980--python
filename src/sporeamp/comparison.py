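"""Multi-spore / multi-isolate variant comparison.

Variant calls from each spore are unified on their exact key
(position, type, ref allele, alt allele) into a variants x samples frequency
matrix. Presence under a frequency threshold then partitions variants into
spore-unique, isolate-unique and shared-by-all sets — threshold 0 means "any
call counts" (how variants unique to one spore are found), threshold 100
keeps only fixed variants (how variants common to all spores are found).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import round_half_away
from .gene_model import GeneModel
from .variant_caller import TYPE_RANK, VariantCall, vcf_alleles


class ComparisonError(ValueError):
    pass


@dataclass
class VariantMatrix:
    """Frequencies (%) per variant key and sample; NaN marks "not called"."""

    table: pd.DataFrame                 # index: MultiIndex (pos,type,ref,alt)
    isolate_of: dict[str, str]

    @property
    def samples(self) -> list[str]:
        return list(self.table.columns)

    @property
    def keys(self) -> list[tuple]:
        return list(self.table.index)

    def isolates(self) -> list[str]:
        seen = []
        for s in self.samples:
            iso = self.isolate_of[s]
            if iso not in seen:
                seen.append(iso)
        return seen


@dataclass
class ComparisonSummary:
    total_variants: int
    total_snvs: int
    per_region: dict[str, int]
    per_isolate_total: dict[str, int]
    per_isolate_exclusive: dict[str, tuple[int, int]]   # (count, % of total)
    per_spore_exclusive: dict[str, tuple[int, int]]     # (count, % of isolate total)
    shared_by_all: list[tuple]


def unify(call_sets: dict[str, Sequence[VariantCall]],
          grouping: dict[str, str]) -> VariantMatrix:
    """Merge per-spore call lists into one matrix keyed by (pos,type,ref,alt)."""
    for sample in call_sets:
        if sample not in grouping:
            raise ComparisonError(f"sample {sample!r} has no isolate assignment")
        keys = [c.key for c in call_sets[sample]]
        if len(keys) != len(set(keys)):
            raise ComparisonError(f"duplicate variant key within sample {sample!r}")
    all_keys = sorted({c.key for calls in call_sets.values() for c in calls},
                      key=lambda k: (k[0], TYPE_RANK[k[1]], k[3]))
    samples = list(call_sets)
    data = np.full((len(all_keys), len(samples)), np.nan)
    key_index = {k: i for i, k in enumerate(all_keys)}
    for j, sample in enumerate(samples):
        for c in call_sets[sample]:
            data[key_index[c.key], j] = c.frequency
    index = pd.MultiIndex.from_tuples(all_keys, names=["pos", "type", "ref", "alt"])
    table = pd.DataFrame(data, index=index, columns=samples)
    return VariantMatrix(table, dict(grouping))


def presence(matrix: VariantMatrix, threshold_percent: float) -> pd.DataFrame:
    """Boolean presence: called AND frequency >= threshold (0 keeps any call)."""
    if not 0 <= threshold_percent <= 100:
        raise ComparisonError("threshold must be in [0,100]")
    t = matrix.table
    return t.notna() & (t >= threshold_percent)


def select_by_threshold(matrix: VariantMatrix,
                        threshold_percent: float) -> dict[str, list[tuple]]:
    """Rows present in exactly one sample, and rows present in every sample."""
    pres = presence(matrix, threshold_percent)
    n_present = pres.sum(axis=1)
    return {
        "unique_to_one_sample": list(pres.index[n_present == 1]),
        "common_to_all": list(pres.index[n_present == len(matrix.samples)]),
    }


def summarize(matrix: VariantMatrix,
              gene_model: GeneModel | None = None,
              threshold_percent: float = 0.0) -> ComparisonSummary:
    """Shared/unique bookkeeping with integer percentages (half away from zero).

    Isolate-exclusive percentages are relative to the grand total of variants;
    spore-exclusive percentages are relative to their isolate's total.
    """
    pres = presence(matrix, threshold_percent)
    samples = matrix.samples
    total = int((pres.sum(axis=1) > 0).sum())
    type_level = pres.index.get_level_values("type")
    total_snvs = int(((pres.sum(axis=1) > 0) & (type_level == "SNV")).sum())

    per_region: dict[str, int] = {}
    if gene_model is not None:
        for key, row_present in zip(pres.index, pres.sum(axis=1) > 0):
            if not row_present:
                continue
            pos = key[0]
            if 1 <= pos <= len(gene_model):
                ctx = gene_model.locate(pos)
                label = f"{ctx.kind}{ctx.ordinal}"
            else:
                label = "outside"
            per_region[label] = per_region.get(label, 0) + 1

    isolates = matrix.isolates()
    spores_of = {iso: [s for s in samples if matrix.isolate_of[s] == iso]
                 for iso in isolates}
    per_isolate_total: dict[str, int] = {}
    per_isolate_exclusive: dict[str, tuple[int, int]] = {}
    per_spore_exclusive: dict[str, tuple[int, int]] = {}
    for iso in isolates:
        in_iso = pres[spores_of[iso]].sum(axis=1) > 0
        out_iso = pres[[s for s in samples if s not in spores_of[iso]]].sum(axis=1) > 0 \
            if len(spores_of[iso]) < len(samples) else pd.Series(False, index=pres.index)
        iso_total = int(in_iso.sum())
        exclusive = int((in_iso & ~out_iso).sum())
        per_isolate_total[iso] = iso_total
        per_isolate_exclusive[iso] = (
            exclusive, percent_of(exclusive, total))
        for sp in spores_of[iso]:
            others = pres[[s for s in samples if s != sp]].sum(axis=1) > 0
            sp_excl = int((pres[sp] & ~others).sum())
            per_spore_exclusive[sp] = (sp_excl, percent_of(sp_excl, iso_total))

    n_present = pres.sum(axis=1)
    shared = list(pres.index[n_present == len(samples)])
    return ComparisonSummary(total, total_snvs, per_region, per_isolate_total,
                             per_isolate_exclusive, per_spore_exclusive, shared)


def percent_of(count: int, total: int) -> int:
    """Integer percentage, rounded half away from zero (47/288 -> 16,
    80/288 -> 28, 54/288 -> 19); 0 when the total is 0."""
    return round_half_away(100.0 * count / total) if total else 0


FREQ_BINS = ((0, 2), (2, 20), (20, 40), (40, 60), (60, 80), (80, 100))


def freq_histogram(matrix: VariantMatrix, sample: str) -> list[int]:
    """Counts of a sample's called variants in the frequency bins
    [0,2), [2,20), [20,40), [40,60), [60,80), [80,100]."""
    if sample not in matrix.samples:
        raise ComparisonError(f"unknown sample {sample!r}")
    freqs = matrix.table[sample].dropna().to_numpy()
    counts = []
    for i, (lo, hi) in enumerate(FREQ_BINS):
        if i == len(FREQ_BINS) - 1:
            counts.append(int(((freqs >= lo) & (freqs <= hi)).sum()))
        else:
            counts.append(int(((freqs >= lo) & (freqs < hi)).sum()))
    return counts


def snv_track(matrix: VariantMatrix, isolate: str) -> pd.Series:
    """Mean SNV frequency per position over the isolate's spores (means taken
    over the spores where the SNV was called)."""
    spores = [s for s in matrix.samples if matrix.isolate_of[s] == isolate]
    if not spores:
        raise ComparisonError(f"isolate {isolate!r} has no spores")
    sub = matrix.table[spores]
    snv_rows = sub[sub.index.get_level_values("type") == "SNV"]
    if snv_rows.empty:
        return pd.Series(dtype=float, name=isolate)
    per_row = snv_rows.mean(axis=1, skipna=True).dropna()
    track = per_row.groupby(per_row.index.get_level_values("pos")).mean()
    track.name = isolate
    return track


# -- outputs -----------------------------------------------------------------

def write_matrix_tsv(matrix: VariantMatrix, path) -> None:
    matrix.table.to_csv(path, sep="\t", na_rep="", float_format="%.4f")


def write_track_tsv(track: pd.Series, path) -> None:
    track.rename("mean_frequency").to_csv(path, sep="\t", index_label="pos",
                                          float_format="%.4f")


def write_summary_tsv(summary: ComparisonSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"total_variants\t{summary.total_variants}\n")
        fh.write(f"total_snvs\t{summary.total_snvs}\n")
        fh.write(f"shared_by_all\t{len(summary.shared_by_all)}\n")
        for region in sorted(summary.per_region):
            fh.write(f"region:{region}\t{summary.per_region[region]}\n")
        for iso, tot in summary.per_isolate_total.items():
            cnt, pct = summary.per_isolate_exclusive[iso]
            fh.write(f"isolate:{iso}\ttotal={tot}\texclusive={cnt}\t"
                     f"exclusive_percent={pct}\n")
        for sp, (cnt, pct) in summary.per_spore_exclusive.items():
            fh.write(f"spore:{sp}\texclusive={cnt}\texclusive_percent={pct}\n")


def write_multisample_vcf(matrix: VariantMatrix, reference: str, path,
                          contig: str = "amplicon") -> None:
    """Merged VCF with a per-sample FREQ (percent) FORMAT field."""
    samples = matrix.samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={len(reference)}>\n")
        fh.write('##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant type">\n')
        fh.write('##FORMAT=<ID=FREQ,Number=1,Type=Float,'
                 'Description="Variant frequency percent">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for key, row in matrix.table.iterrows():
            pos, vtype, ref, alt = key
            call = VariantCall(pos, vtype, ref, alt, 0, 0, 0.0)
            vpos, vref, valt = vcf_alleles(call, reference)
            cells = ["." if np.isnan(row[s]) else f"{row[s]:.4g}" for s in samples]
            fh.write(f"{contig}\t{vpos}\t.\t{vref}\t{valt}\t.\tPASS\t"
                     f"TYPE={vtype}\tFREQ\t" + "\t".join(cells) + "\n")
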