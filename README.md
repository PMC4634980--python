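# sporeamp

Single-spore amplicon variant analysis for multinucleate fungi.

Spores of arbuscular mycorrhizal fungi such as *Rhizophagus irregularis*
carry hundreds of nuclei that need not be genetically identical
(heterokaryosis). Deep amplicon sequencing of one spore therefore observes
variant alleles at *within-organism* frequencies anywhere between <2% and
~100%, and comparing spores and isolates asks which variants are shared by
all, private to an isolate, or private to a single spore. `sporeamp`
implements that analysis end to end for a single-gene amplicon — here the
alternative-oxidase gene (*AOX*), whose conserved ferritin-like domain
carries the di-iron-center glutamate/histidine residues — together with a
truth-annotated read simulator so every stage is testable without external
data.

## What it computes

For reads \(r\) mapped to a reference amplicon, a variant's frequency is

    f = 100 * count / coverage   (%)

with both numerator and denominator restricted to quality-screened bases: a
read base is trusted only if its Phred quality is ≥ 20 and the mean quality
in a ±5-base window is ≥ 15. A non-reference allele becomes a call when
coverage ≥ 10 and f ≥ 1%; insertion/deletion candidates inside reference
homopolymer runs of length ≥ 3 are discarded while f < 80% (pyro-error
removal); adjacent SNVs co-occurring on ≥ 50% of their carrier reads merge
into an MNV, and a co-occurring deletion+insertion at one anchor becomes a
replacement (Repl). Mapping uses local alignment with match +1,
mismatch cost 2, insertion/deletion cost 3 per base, and accepts a placement
when ≥ 50% of the read is aligned with ≥ 80% identity (non-specific matches
are placed randomly under a seed).

Across spores, calls are unified into a variants × spores frequency matrix;
presence under a threshold t (called and f ≥ t) partitions variants into
spore-unique (t = 0), isolate-exclusive and shared-by-all (t = 100 keeps
fixed variants only). Exonic variants are re-translated through the standard
genetic code into synonymous / missense / stop / frameshift classes with
flags for the conserved domain and the 52-residue N-terminal targeting
region.

## A worked example

```sh
python examples/01_gene_model.py
```

prints

```
gene RiAOX: 1250 nt, 4 exons
CDS 1032 nt -> peptide 343 aa (starts MECVWWANQT..., N-terminal targeting region 52 aa)
  position     1: exon1, codon 1.1, domain=False
  position   445: intron1, non-coding, domain=False
  position   600: exon2, codon 177.3, domain=True
  position   358: exon1, codon 120.1, domain=True
```

i.e. the bundled gene model has four exons (444/116/188/284 nt) interrupted
by three introns (69/81/68 nt); its 1032-nt coding sequence translates to a
343-residue peptide, and `locate` maps any genomic coordinate to its
exon/intron, codon and domain context. The other examples walk through read
simulation (`02`), mapping + variant calling (`03`), multi-spore comparison
(`04`) and consequence prediction (`05`), each printing the quantities it
computes and a line on how to read them.

The same stages run from the shell:

```sh
sporeamp run-all --out-dir run_out --seed 7
```

which writes per-spore FASTQ/SAM/VCF, the unified variant matrix, comparison
summaries, frequency histograms, per-isolate SNV tracks, the consequence
table, a per-spore summary table with TOTAL/Mean rows, and a manifest whose
digest is identical on any rerun with the same seed.

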