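"""End-to-end orchestration: simulate -> map -> call -> compare -> annotate.

One :class:`RunConfig` (loadable from a YAML file) drives a fully
deterministic run: a single global seed fans out to fixed per-stage seeds, all
stage outputs (FASTQ/SAM/VCF/TSV) land in the output directory, and a manifest
records every effective parameter plus content digests so an identical rerun
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import pandas as pd
import yaml

from ._util import derive_seed, round_half_away
from . import comparison, consequence, gene_model, synthetic_data, variant_caller
from .gene_model import GeneModel
from .mapping import MappingParams, map_all, mapping_stats, trim_reads
from .synthetic_data import HaplotypePanel, ReadSimConfig, make_panel
from .variant_caller import CallerParams

SUMMARY_COLUMNS = ["# of reads", "% of mapped reads", "Average mapped read length",
                   "Average variant coverage", "Average SNV coverage"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    out_dir: str = "run_out"
    seed: int = 0
    # panel / simulation
    n_isolates: int = 3
    n_spores_per_isolate: int = 3
    n_shared: int = 5
    n_isolate_unique: int = 4
    n_spore_unique: int = 2
    n_reads_per_spore: int = 1500
    read_length_mean: float = 130.0
    read_length_sd: float = 25.0
    substitution_errors: bool = True
    homopolymer_indel_rate: float = 0.002
    position_margin: int = 80
    use_riaox_reference: bool = True
    reference_length: int = 1250   # used when use_riaox_reference is False
    # trimming
    trim_quality: int = 20
    trim_min_length: int = 50
    # stage parameter blocks
    mapping: MappingParams = field(default_factory=MappingParams)
    caller: CallerParams = field(default_factory=CallerParams)
    comparison_threshold: float = 0.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mapping = MappingParams(**raw.pop("mapping", {}))
        caller = CallerParams(**raw.pop("caller", {}))
        return cls(mapping=mapping, caller=caller, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig,
                 log: Callable[[str], None] | None = None) -> dict:
    """Run the full pipeline; returns the manifest dict (also written to
    ``manifest.json`` in the output directory)."""
    say = log or (lambda msg: None)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    model: GeneModel | None = None
    if config.use_riaox_reference:
        model = gene_model.riaox_model()
        reference = model.sequence
    else:
        import numpy as np
        reference = synthetic_data.random_reference(
            config.reference_length,
            np.random.default_rng(derive_seed(config.seed, "reference")))

    stage = "panel"
    try:
        say(f"[{stage}] allocating truth panel")
        panel = make_panel(
            None, config.n_isolates, config.n_spores_per_isolate,
            config.n_shared, config.n_isolate_unique, config.n_spore_unique,
            seed=derive_seed(config.seed, "panel"),
            reference=reference,
            position_margin=config.position_margin,
        )
        synthetic_data.write_truth_tsv(panel, out / "truth.tsv")
        synthetic_data.write_truth_vcf(panel, out / "truth.vcf")
        if model is not None:
            gene_model.write_gene_model(model, out / "reference.fasta",
                                        out / "reference.features.tsv")

        call_sets: dict[str, list] = {}
        grouping: dict[str, str] = {}
        per_spore_rows = []
        for spore in panel.spores:
            stage = f"simulate:{spore}"
            say(f"[{stage}] generating reads")
            sim = ReadSimConfig(
                n_reads=config.n_reads_per_spore,
                read_length_mean=config.read_length_mean,
                read_length_sd=config.read_length_sd,
                substitution_errors=config.substitution_errors,
                homopolymer_indel_rate=config.homopolymer_indel_rate,
                seed=derive_seed(config.seed, f"reads:{spore}"),
            )
            reads = synthetic_data.simulate_reads(panel, spore, sim)
            synthetic_data.write_fastq(reads, out / f"{spore}.fastq")

            stage = f"map:{spore}"
            say(f"[{stage}] trimming and mapping")
            trimmed = trim_reads(reads, config.trim_quality, config.trim_min_length)
            params = dataclasses.replace(
                config.mapping, seed=derive_seed(config.seed, f"map:{spore}"))
            records, mstats = map_all(trimmed, reference, params,
                                      sam_path=out / f"{spore}.sam")
            (out / f"{spore}.mapping_stats.tsv").write_text(
                "n_reads\tn_mapped\tpercent_mapped\tmean_mapped_read_length\n"
                f"{mstats.n_reads}\t{mstats.n_mapped}\t{mstats.percent_mapped}\t"
                f"{mstats.mean_mapped_read_length}\n")

            stage = f"call:{spore}"
            say(f"[{stage}] calling variants")
            calls = variant_caller.call_variants(
                [r for r in records if r.mapped], reference, config.caller)
            variant_caller.write_vcf(calls, reference, out / f"{spore}.vcf",
                                     sample=spore)
            variant_caller.write_calls_tsv(calls, out / f"{spore}.calls.tsv",
                                           sample=spore)
            call_sets[spore] = calls
            grouping[spore] = panel.isolate_of(spore)
            cstats = variant_caller.caller_stats(calls)
            per_spore_rows.append({
                "Sample": spore,
                "# of reads": len(reads),
                "% of mapped reads": mstats.percent_mapped,
                "Average mapped read length": mstats.mean_mapped_read_length,
                "Average variant coverage": cstats["average_variant_coverage"],
                "Average SNV coverage": cstats["average_snv_coverage"],
            })

        stage = "compare"
        say(f"[{stage}] unifying and comparing call sets")
        matrix = comparison.unify(call_sets, grouping)
        comparison.write_matrix_tsv(matrix, out / "variant_matrix.tsv")
        comparison.write_multisample_vcf(matrix, reference, out / "variants.vcf")
        summary = comparison.summarize(matrix, model, config.comparison_threshold)
        comparison.write_summary_tsv(summary, out / "comparison_summary.tsv")
        for spore in panel.spores:
            hist = comparison.freq_histogram(matrix, spore)
            (out / f"{spore}.freq_histogram.tsv").write_text(
                "bin_low\tbin_high\tcount\n" + "".join(
                    f"{lo}\t{hi}\t{c}\n" for (lo, hi), c
                    in zip(comparison.FREQ_BINS, hist)))
        for iso in matrix.isolates():
            track = comparison.snv_track(matrix, iso)
            comparison.write_track_tsv(track, out / f"{iso}.snv_track.tsv")

        stage = "annotate"
        if model is not None:
            say(f"[{stage}] predicting coding consequences")
            records_cons = consequence.predict_all(matrix.keys, model)
            consequence.write_consequences_tsv(records_cons,
                                               out / "consequences.tsv")

        stage = "summary"
        table = summary_table(per_spore_rows)
        table.to_csv(out / "summary_table.tsv", sep="\t", index=False)
    except Exception as exc:
        digest = hashlib.sha256(repr(config.to_dict()).encode()).hexdigest()[:12]
        raise PipelineError(
            f"stage {stage!r} failed (config digest {digest}): {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_truth_variants": len(panel.truth),
        "outputs": {},
    }
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256_file(p)
    manifest["digest"] = hashlib.sha256(
        json.dumps(manifest["outputs"], sort_keys=True).encode()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    say(f"[done] manifest digest {manifest['digest'][:12]}")
    return manifest


def summary_table(per_spore_rows: list[dict]) -> pd.DataFrame:
    """Per-spore statistics plus TOTAL (read count only) and Mean rows, every
    mean rounded to the nearest integer (half away from zero)."""
    if not per_spore_rows:
        raise PipelineError("summary table needs at least one spore")
    df = pd.DataFrame(per_spore_rows, columns=["Sample"] + SUMMARY_COLUMNS)
    total_row = {c: None for c in df.columns}
    total_row["Sample"] = "TOTAL"
    total_row["# of reads"] = int(df["# of reads"].sum())
    mean_row = {"Sample": "Mean"}
    for c in SUMMARY_COLUMNS:
        vals = df[c].dropna()
        mean_row[c] = round_half_away(float(vals.mean())) if len(vals) else None
    return pd.concat([df, pd.DataFrame([total_row, mean_row])],
                     ignore_index=True)
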