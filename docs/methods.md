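# Methods

## The analysis

`sporeamp` treats one PCR amplicon of a single gene sequenced very deeply in
individual multinucleate spores. Because a spore pools hundreds of nuclei,
an allele present on a fraction of them appears in the reads at that
fraction — the analysis is low-frequency variant *detection*, not diploid
genotyping. Five stages: read trimming and mapping, quality-screened
threshold calling, multi-spore comparison, coding-consequence prediction,
and a synthetic-data generator that provides truth-annotated inputs.

## Gene model

A `GeneModel` is a sense-strand sequence tiled by strictly alternating
exon/intron features (1-based inclusive coordinates throughout), a CDS given
as genomic intervals over exon bases, a conserved-domain interval whose
endpoints must be exonic, and an N-terminal targeting-peptide length in
residues. Invariants (contiguous tiling, alternation, CDS length divisible
by 3, no internal stop) are checked on construction; `locate` maps any
position to feature, codon index/phase, and domain membership.

The bundled `riaox_model()` fixture encodes the published architecture of
the *R. irregularis* AOX gene: exons of 444/116/188/281 nt and introns of
69/81/68 nt, a 1032-nt CDS and a 343-aa peptide. The published exon sum
(1029 nt) and CDS length (1032 nt) disagree by one codon; the fixture pads
exon 4 to 284 nt so that the exon total equals the CDS length and the gene
total equals the published 1250 bp. The pad is recorded in
`model.metadata["cds_padding_nt"]`. The nucleotide sequence itself, the
domain interval (codons 120–320) and the positions chosen for the invariant
domain glutamates/histidines are deterministic synthetic stand-ins — the
real sequence is not bundled — so consequence *inventories* on the fixture
are illustrative, while consequence *logic* is exact. The published
"52 bp" N-terminal length is stored as 52 residues, since targeting-peptide
predictors report residue counts.

## Mapping

Reads are Phred end-trimmed (default cutoff Q20, minimum surviving length
50 nt — the trimming step is documented in the original workflow without
cutoffs, so these are package defaults) and placed by local alignment
scoring +1 per match, −2 per mismatch, −3 per inserted or deleted base,
i.e. the mismatch-cost-2 / indel-cost-3 scheme of desktop mappers. Read
ends may be soft-clipped freely and reference ends are free; a pure
minimum-cost formulation with free clipping is degenerate (clipping
everything costs nothing), which is why the aligner maximises score while
still reporting the edit cost (2·mismatches + 3·gap bases) of the aligned
region. Both orientations are tried. Equal-scoring placements or
orientations are resolved uniformly by a generator seeded per read
(seed × read-id hash), so non-specific matches map randomly but
reproducibly. Acceptance requires

* aligned_read_fraction = (read length − clipped bases) / read length ≥ 0.5
* identity = matches / (matches + mismatches + internal gap bases) ≥ 0.8.

Full-length exact substring matches attain the maximum possible score, so
they bypass the dynamic program; otherwise the score matrix is computed
row-wise with a prefix-max scan (linear gaps make the in-row deletion
recurrence a running maximum). Tracebacks prefer extending an open gap, so
indel runs stay contiguous; anchored events are then left-aligned, making
representation canonical within homopolymers. SAM output (M/I/D/S CIGARs,
MAPQ 60, NM tag) round-trips through `read_sam` exactly.

## Variant calling

Base screening: a read base contributes to the pileup only if its own
quality is ≥ 20 (central) and the mean quality over read positions within
±5 (window truncated at read ends, centre included) is ≥ 15. Screened-out
bases are removed from both allele counts and coverage, so frequency is a
property of trusted observations only; whether the original tool's
"minimum coverage" counted raw or screened depth is unstated, and screened
depth is the choice here. Indel observations are keyed by their left-aligned
anchor and require a trusted anchor base.

Candidates need screened coverage ≥ 10 and frequency ≥ 1%. The pyro-error
filter removes indel candidates lying inside reference homopolymer runs of
length ≥ 3 whose frequency is below 0.8 — on the percent scale, below 80% —
so only near-fixed homopolymer indels survive; that asymmetry is the
original parameterisation, kept as-is. Runs of adjacent SNV candidates are
merged greedily left-to-right into an MNV when, among reads covering the
whole block and carrying at least one constituent alternate, the fraction
carrying *all* of them is ≥ 0.5; merged constituents are suppressed. A
deletion and insertion anchored at the same base merge into a replacement
(Repl) under the same co-occurrence rule; the upstream tool's exact merge
rules are unpublished, so both thresholds are exposed parameters. Output
order is deterministic: position, then SNV < MNV < Ins < Del < Repl, then
alt allele.

## Comparison

Calls are unified on the exact key (pos, type, ref, alt) into a pandas
frequency matrix — near-misses (same position, different allele) are
distinct rows by design. Presence under threshold t means called with
frequency ≥ t, so t = 0 counts any call (finding spore-unique variants) and
t = 100 keeps fixed variants (finding variants common to all spores);
whether "common to all" in the original analysis meant presence or fixation
is honoured by parameterising the threshold. Percentages are rounded to the
nearest integer, half away from zero — the rule reproducing all three
published worked examples (47/288 → 16, 80/288 → 28, 54/288 → 19).
Isolate-exclusive percentages are relative to the grand total;
spore-exclusive percentages are relative to their isolate's total.
Frequency histograms use bins [0,2), [2,20), [20,40), [40,60), [60,80),
[80,100]; only the outermost bins are dictated by the source analysis, the
20-point interior width is a package choice. The per-isolate SNV track is
the per-position mean frequency over the spores where the SNV was called.

## Consequence prediction

Intron-contained variants are `intronic`; exonic substitutions are
re-translated through the standard genetic code (`synonymous`, `missense`,
`stop_gained`, `stop_lost`); exonic length changes are `frameshift` when the
net length change is not divisible by 3, else `inframe_indel`; events
touching exon and intron bases are `boundary_spanning`, a terminal class —
no splice-site modelling is attempted. MNVs within one codon yield a single
amino-acid change; MNVs spanning codons report the first altered residue and
classify by the most severe change (stop_gained > stop_lost > missense >
synonymous). Exon bases outside the CDS (absent from the bundled fixture)
classify as `noncoding`, a small extension to the class set.

## Synthetic data

`make_panel` allocates variants to three scopes — shared by every spore,
unique to one isolate, unique to one spore — at distinct positions (pairwise
spacing ≥ 6 nt, margin ≥ `position_margin` from the amplicon ends, where
coverage tapers). Nuclear frequencies default to a mixture of a low band
(0.5–20%, 80% of draws) and a high band (80–100%), echoing the observed
spectrum in which most within-spore variants sit below 20% with a near-fixed
tail. Each variant is realised on `round(f·100)` of 100 nuclei per spore;
nuclei with identical variant sets collapse into weighted haplotypes, so
variants assigned to the same nuclei are linked and co-occur on reads — the
property MNV merging is tested against. MNV alt alleles that are one-base
shifts of the reference are rejected at generation time, because an aligner
scores those as deletion+insertion rather than a block substitution.

`simulate_reads` draws single-end reads (default 4 500 per spore — the
smallest published per-spore regime — mean length 130 nt, sd 25, matching
the 105–156 nt mapped-length band) from uniformly placed windows of
mixture-weighted haplotypes. Qualities come from a clipped normal
(mean Q30, sd 5); a base substitutes with probability 10^(−Q/10); within
each homopolymer run of length r ≥ 3 a one-base indel error occurs with
probability rate·(r−1) (default rate 0.002). No error profile was published
for the original instrument run, so the homopolymer-indel-dominant model is
an assumption recorded here, not a sourced fact. The generator does not
model whole-genome-amplification chimeras, paired ends or PCR duplicates,
so passing tests demonstrate correctness of the analysis machinery, not
robustness to those artefacts.

## Problem sizes and numerical choices

Pipeline defaults and the acceptance experiments run 9 spores × 1 500 reads
(panel recovery uses 1 200) on the 1 250-nt fixture — the package's
desk-scale choice, giving ~120–160× mid-amplicon coverage. One global seed
fans out to per-stage seeds through a CRC-based name hash, so stages are
independently reproducible and a rerun is byte-identical.

The exact-recovery experiment (3 × 3 spores, allocation 5/4/2, error-free
reads, truth frequencies uniform in 0.15–0.95 so every variant sits above
the detection floor) uses SNV-only truth panels. With multi-base variants,
reads whose window boundary falls inside the variant align ambiguously — a
few boundary reads represent an MNV as deletion+insertion — and at the 1%
frequency floor two or three such reads already constitute a spurious indel
key, so key-level exact recovery is not attainable for MNV/indel panels
under the original caller settings. MNV linkage and indel calling are
verified by dedicated unit tests instead.

## Known limitations

* The published end-to-end variant counts (288 variants, 93 SNVs, 13 shared)
  depend on the original unreleased reads and a closed-source caller and are
  deliberately not reproduction targets; the package instead proves its
  machinery on truth-annotated simulations plus the published worked
  examples.
* At coverage below ~100×, a single error read exceeds the 1% frequency
  floor; the caller inherits this permissiveness from its parameterisation
  (the original study relied on 10³–10⁴× coverage).
* Replacement (Repl) calls arise only from same-anchor deletion+insertion
  observations; cost-optimal alignments usually prefer mismatch
  representations, so Repl is rare by construction.
* The aligner is an exact dynamic program (no seeding heuristics) and is
  sized for amplicon work, not genome-scale mapping.
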