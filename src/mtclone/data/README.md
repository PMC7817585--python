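# Bundled data files

## rcrs_synthetic.fasta — SYNTHETIC reference

A 16,569-bp synthetic stand-in for the human mitochondrial reference
(rCRS, NC_012920). It is **not** the real rCRS sequence: only the
properties the analysis depends on are preserved —

* standard public locus coordinates (see `loci.tsv`), 1-based, circular;
* the placeholder `N` at position 3107;
* the reference base at every variant site of the bundled cohort equals
  the published REF allele;
* whole codons at protein-coding variant sites are pinned so translation
  reproduces the published amino-acid substitutions (including the
  light-strand MT-ND6 sites);
* every other base is filled from a seeded RNG
  (`scripts/build_synthetic_reference.py`).

Coordinate arithmetic, locus assignment and codon numbering are therefore
exactly as for the real rCRS; only the unconstrained background bases are
synthetic.

## loci.tsv

Standard rCRS gene/locus intervals (symbol, type, start, end, strand),
1-based inclusive. The control region (MT-DLoop) spans the origin and is
stored as two intervals (16024–16569 and 1–576). MT-ATP8/MT-ATP6 and
MT-ND4L/MT-ND4 overlap.

## table2_variants.tsv / table2_annotations.tsv

Transcription of the study's 36 tumor-specific variants: per-patient
compartment calls (BC / CBC / BC+CBC) and the per-variant nucleotide
variability (NV), population allele frequency (AF) and disease score (DS).
`NA` marks values not available in the source (never 0). European-style
grouped decimals in the source (e.g. `0,000,096,165`) were normalized to
dot-decimal (`0.000096165`) at transcription time. `printed_gene`,
`printed_aa` and `printed_pathogenic` preserve the published labels
verbatim (including the two known discrepancies: m.1982G>A printed under
MT-RNR1 though standard coordinates place 1982 in MT-RNR2, and the
MT-ND6 m.14207G>A "S20N" / m.9525G>A "A107" amino-acid labels that do not
follow from standard codon arithmetic).

## table1_clinical.csv

Transcription of the 30 case pairs' clinico-pathological features
(histotype, grade, pTNM, stage, in-situ component, IHC bioprofile,
inter-tumor interval in months) together with the published discordance
factors and the published clinical and mtDNA clonality calls
(`printed_*` columns, used only as expected values in tests).
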