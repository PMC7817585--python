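# Methods

## Model and assumptions

The clonality inference rests on a single biological assumption: somatic
mitochondrial substitutions are non-recurrent. The mitochondrial genome
lacks mutational hotspots, and population/nucleotide variability of the
relevant sites is near zero, so the probability that two independent tumors
of one patient acquire the identical tumor-specific substitution is
negligible. Consequently the decision rule is asymmetric:

* **shared tumor-specific variant present** → the pair is clonal (metCBC);
  one shared variant suffices, and no minimum count is imposed;
* **no shared variant** → non-informative (NI). Absence of sharing is not
  evidence of independence: a mutation may postdate the metastatic spread,
  be lost, or the metastasis may derive from a non-mutated subclone. The
  classifier therefore never emits an "independent" verdict.

A variant is *tumor-specific* iff absent from the matched normal tissue,
compared by the identity triple (position, ref, alt). Heteroplasmy never
affects identity: a mixed peak in one tumor and a pure peak in the other is
the same somatic event observed at different tumor-cell fractions (stromal
contamination), and a heteroplasmic normal call suppresses a homoplasmic
tumor call at the same site.

## Coordinates, reference, translation

All coordinates are 1-based rCRS positions (m.-notation); no 0-based
representation is exposed anywhere. The control region spans the origin and
is modelled as one locus with two intervals (16024–16569, 1–576) so all
interval logic stays linear. For the two overlapping gene pairs
(MT-ATP8/MT-ATP6, MT-ND4L/MT-ND4) lookups return all containing loci in
ascending-start order and the primary annotation uses the smaller start,
giving deterministic single-row output.

Protein consequences use the vertebrate mitochondrial genetic code
(translation table 2, via Biopython: ATA=M, TGA=W, AGA/AGG=stop). Codon
number for heavy-strand genes is `floor((pos − start)/3) + 1`; light-strand
genes (MT-ND6) read the reverse complement from the interval end, so their
first codon sits at `end`. Position 3107 carries the historical rCRS
placeholder 'N': it is untranslatable, never called, and excluded from
somatic sets.

The bundled reference FASTA is a synthetic stand-in (see
`src/mtclone/data/README.md`): real locus coordinates, pinned reference
bases and whole codons at every site used by the bundled cohort, seeded
random elsewhere. Locus assignment, codon arithmetic and every bundled
consequence are therefore identical to the real rCRS; analyses of new
samples should substitute a real rCRS FASTA (`--reference`).

Two published labels are deliberately *not* reproduced and are tracked as
known discrepancies rather than matched: m.1982G>A is printed under MT-RNR1
but position 1982 falls in MT-RNR2 under standard boundaries, and the
printed "S20N" for m.14207G>A does not follow from standard MT-ND6 codon
arithmetic (which yields codon 156). The printed "A107" for m.9525G>A lacks
a target residue; the package reports its computed change (A107T).

## Alignment and variant calling

Samples are full-length mitochondrial consensus sequences (Sanger exports),
assumed linearized at the rCRS origin; no rotation search is performed
(documented limitation). The default aligner is edlib's global
edit-distance alignment: with unit costs a substitution (1) is cheaper than
a gap pair (2), so near-identical genomes align substitution-first, and a
16.5-kb pair aligns in milliseconds, which keeps cohort-scale simulation
cheap. Because equal-cost gap placements are not unique under unit costs,
an affine-gap engine (Biopython PairwiseAligner; match +1, mismatch −2, gap
open −4, gap extend −1, exposed via `--scoring`) is available when gap
structure matters; both engines feed the identical column-interpretation
rules.

Per mismatch column: a plain base is a homoplasmic call; a two-fold IUPAC
code containing the reference base is a heteroplasmic call for the other
base; 'N', codes not containing the reference base, and three/four-fold
codes produce no call (logged) — a three-allele mixture is uninterpretable
as a single substitution. Gap columns become indel *events*, never
variants; indel nomenclature is out of scope. The positional diff oracle
applies the same column rules without alignment and is the independent
check for the aligner path on indel-free input.

## Pathogenicity

Thresholds are applied exactly as stated by the HmtVar-style criteria,
inclusive at the boundary: missense DS ≥ 0.43 ∧ AF ≤ 0.003264; tRNA
DS ≥ 0.35 ∧ AF ≤ 0.005020. Dashes in the source table parse to an explicit
missing marker, never 0 — a missing DS or AF always means "not pathogenic",
and the rule applies only to missense and tRNA classes (synonymous, rRNA
and control variants are never scored). A stop-gain would be held to the
missense thresholds; none occurs in the bundled cohort.

## Clinico-pathological rule engine

Factors indicating an independent second primary: **Histology**
(special-type — ILC or other special type — vs IC NST), **IHC** (different
bioprofile among Lum / Lum-H / Her2 / TN; ER/PR/HER2 collapse as: hormone
receptor positive → Lum, plus HER2 → Lum-H, HER2 only → Her2, none → TN;
no luminal A/B split), **InSitu** (in-situ component in the second tumor of
a metachronous pair, or in both tumors of a synchronous pair — one-sided
in-situ in a synchronous pair is uninformative). The metastasis indicator
is **Stage**: stage 3 in either tumor of a synchronous pair, or in the
first tumor of a metachronous pair (a stage-3 *second* tumor of a
metachronous pair indicates nothing about the first seeding the second).

Verdict precedence: independence factors only → bilCBC; Stage only →
metCBC; both → DisNI (discordant, non-informative) when the stage-3 tumor
is the primary, otherwise the independence factors win; no factors → NI.
This precedence is this package's codification — the unique simple rule
consistent with all 30 bundled case pairs, including the contrast between
the discordant cases (stage-3 primaries) and the bilCBC cases whose stage-3
tumor is the second one. Grade differences, distant metastasis and the
inter-tumor interval are carried as inputs but never act as factors; stage
is consumed as a provided column rather than derived from pTNM, because the
bundled stage labels do not always follow anatomic AJCC grouping and silent
re-derivation would disagree with the source data. A pair is metachronous
iff the interval exceeds 6 months.

## Cohort report

The report is a pure function of its inputs: per-case rows plus aggregates
whose percentages are always derived from stored counts. Rounding is
decimal half-up at the printed precision of each statistic (one decimal for
means/SDs, whole percent for the metachronous informativeness). Medians of
even-length lists are the mean of the central pair. Both the sample (n−1)
and population (n) standard deviations are emitted; the bundled cohort's
printed values correspond to the sample convention. The metachronous
informativeness is 100 × (metachronous metCBC) / (metachronous pairs),
undefined for cohorts without metachronous pairs.

## Synthetic cohorts

The simulator emulates exactly the structure the analysis assumes: a
germline haplotype shared by all three tissues (Poisson mean 15 variants —
a typical haplotype distance from the reference); private somatic variants
per tumor (Poisson mean 0.6); for clonal pairs a shared somatic set,
non-empty with probability `p_shared_given_clonal` and of size 1 + Poisson(0.3)
(matching ~1.3 shared variants per informative pair in the bundled cohort);
heteroplasmic emission with probability 0.9 ("nearly all" real shared
variants were mixed peaks). Defaults mirror the bundled cohort's
conditions: 30 cases, clonal fraction 0.23, synchronous fraction 0.37,
metachronous intervals uniform on 10–133 months, ages ≈ N(63.9, 14.1).

Somatic positions are drawn uniformly *without replacement within a
patient* over non-N reference positions — the non-recurrence assumption
made literal, which is why truth-independent pairs can never be called
metCBC (specificity 1 by construction). Cross-patient recurrence is allowed
and harmless since all comparisons are within-patient. Clinical features
come from a small categorical model (independent pairs enriched for
discordance factors, clonal pairs for stage-3 primaries) rather than a fit
of the bundled table's joint distribution. One seeded generator drives the
cohort; per-patient substreams are derived from the seed plus a CRC32 hash
of the patient id, so extending a cohort never perturbs existing patients.

What the simulator does **not** model — and hence what passing tests do not
establish about real data: sequencing error, chimeric or incomplete
amplicons, indels, rotated (non-linearized) assemblies, nuclear
mitochondrial insertions (NUMT contamination), or quantitative peak-height
heteroplasmy. Real-world specificity depends on those error modes being
controlled upstream (e.g. by replicate PCR confirmation).

## Problem sizes and numerical choices

The bundled-cohort analysis (30 pairs, 36 variants) is instantaneous and
fully deterministic. Simulation-based checks use cohorts of 8–200 patients
through the full alignment path and 500 patients through the positional
diff path for the clonal-fraction recovery check; the binomial tolerance is
3 standard errors. All randomness in the package lives in the simulator —
the analysis path contains none.
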