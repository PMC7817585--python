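# mtclone

Mitochondrial-DNA based clonality analysis of paired tumors — built for the
contralateral breast cancer (CBC) setting, where the clinical question is
whether the second tumor is an independent new primary (**bilCBC**) or a
metastatic spread of the first (**metCBC**).

## The idea

Somatic mtDNA mutations are effectively non-recurrent: the mitochondrial
genome has no mutational hotspots, so two independent tumors in the same
patient acquiring the *same* tumor-specific substitution by chance is
essentially impossible. Therefore:

* call substitutions in each tissue (tumor 1 = BC, tumor 2 = CBC, matched
  normal = N) against the rCRS reference (16,569 bp, 1-based m. coordinates);
* remove the germline haplotype: a variant is **tumor-specific** iff it is
  absent from the matched normal;
* if the two tumors share ≥ 1 tumor-specific variant, the pair is clonal
  (**metCBC**); if not, the evidence is **non-informative** (NI) — never
  "independent", since mutations can arise after metastatic seeding.

Around this core the package provides: heteroplasmy-aware calling (mixed
Sanger peaks as IUPAC ambiguity codes), locus and amino-acid-change
annotation under the vertebrate mitochondrial genetic code (translation
table 2), HmtVar-style pathogenicity classification (missense: DS ≥ 0.43
and AF ≤ 0.003264; tRNA: DS ≥ 0.35 and AF ≤ 0.005020), a codified
clinico-pathological rule engine (histotype / IHC bioprofile / in-situ
component vs. stage-3 indicators), a cohort-level concordance report, and a
synthetic-cohort simulator with ground-truth labels.

The bundled reference FASTA is a clearly-labelled **synthetic stand-in**
for the rCRS with the real public locus coordinates (see
`src/mtclone/data/README.md`); any real rCRS FASTA can be substituted.

## Worked example

The package ships a 30-pair cohort (per-compartment variant calls, NV/AF/DS
annotations, clinical features). Running the variant-table entry point:

```python
from importlib import resources
from mtclone import cohort_fixture
from mtclone.pipeline import PipelineContext, _finish, profiles_from_calls

fx = cohort_fixture()
ctx = PipelineContext(annotation_db=fx.annotation_db)
report = _finish(profiles_from_calls(fx.variant_calls), fx.clinical_pairs, ctx)
a = report.aggregates
print(a["n_somatic_variants"], "tumor-specific variants in",
      a["n_cases_with_somatic"], "of", a["n_cases"], "cases")
print(a["n_shared_variants"], "shared variants in", a["n_informative"],
      "informative (metCBC) patients:", a["informative_patients"])
print("clinical:", a["clinical_counts"])
print("mtDNA reclassifies clinical bilCBC:",
      a["disagreements"]["clinical_bilCBC_mtdna_metCBC"])
print("mtDNA resolves clinically non-informative:",
      a["disagreements"]["mtdna_resolves_clinical_NI"])
```

prints

```
36 tumor-specific variants in 20 of 30 cases
9 shared variants in 7 informative (metCBC) patients: ['C13', 'C19', 'C27', 'C30', 'C5', 'C8', 'C9']
clinical: {'bilCBC': 17, 'metCBC': 6, 'NI': 4, 'DisNI': 3}
mtDNA reclassifies clinical bilCBC: ['C5', 'C9']
mtDNA resolves clinically non-informative: ['C27', 'C8']
```

i.e. 7/30 pairs (23%) carry shared tumor-specific variants proving a clonal
origin; for C5 and C9 this contradicts the histopathological verdict, and
for C8 and C27 it settles pairs the clinical rules could not classify.

The same analysis from the shell:

```
mtclone simulate --seed 5 -o sim/                       # synthetic cohort
mtclone run --fasta sim/cohort.fasta --clinical sim/clinical.csv -o out/
mtclone clinical src/mtclone/data/table1_clinical.csv -o calls.tsv
```

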