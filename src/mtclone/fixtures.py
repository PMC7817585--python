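"""Bundled cohort fixture: the 30-pair study cohort as in-memory objects.

``cohort_fixture()`` exposes the transcription of the published study
tables shipped under ``mtclone/data``: per-patient, per-compartment
tumor-specific variant calls (36 variants over 20 of 30 patients), the
NV/AF/DS annotation table, and the clinical features of all 30 pairs —
together with the published expected outputs (discordance factors, clinical
and mtDNA clonality calls, gene labels, amino-acid labels, pathogenicity
flags) used as oracle values in tests.

Known transcription notes (kept verbatim in the ``printed_*`` fields, and
flagged — not silently matched — by the annotation layer):

* m.1982G>A is printed under MT-RNR1 although standard rCRS boundaries
  place position 1982 in MT-RNR2;
* m.14207G>A is printed as "S20N" although light-strand codon arithmetic
  from standard MT-ND6 coordinates yields codon 156;
* m.9525G>A is printed as "A107" without a target residue; this package
  reports its own computed change (A107T).
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .io import VariantAnnotationDB, read_clinical_table, read_variant_table
from .variants import Variant, parse_variant

ALL_PATIENTS = tuple(f"C{i}" for i in range(1, 31))

#: published labels that standard coordinate/codon arithmetic does not reproduce
KNOWN_DISCREPANCIES = {
    "m.1982G>A": "printed gene MT-RNR1; standard boundaries give MT-RNR2",
    "m.14207G>A": "printed amino-acid change S20N; standard MT-ND6 codon arithmetic gives codon 156",
    "m.9525G>A": "printed amino-acid change A107 lacks a target residue; computed change is A107T",
}


@dataclass(frozen=True)
class CohortFixture:
    """The bundled cohort: inputs plus published expected outputs."""

    variant_calls: dict  # patient_id -> {"BC": set, "CBC": set, "N": set}
    annotation_db: VariantAnnotationDB
    clinical_pairs: list  # list[PairFeatures], all 30 patients
    expected: pd.DataFrame  # printed_* columns of the clinical table
    printed_annotations: pd.DataFrame  # printed gene/aa/pathogenic per variant

    @property
    def patients(self) -> tuple[str, ...]:
        return ALL_PATIENTS


def _data(name: str):
    return resources.as_file(resources.files("mtclone.data") / name)


def cohort_fixture() -> CohortFixture:
    """Load the bundled cohort tables (see module docstring)."""
    with _data("table2_variants.tsv") as p:
        calls = read_variant_table(p)
    # patients without any tumor-specific variant still have (empty) profiles
    for pid in ALL_PATIENTS:
        calls.setdefault(pid, {"BC": set(), "CBC": set(), "N": set()})
    with _data("table2_annotations.tsv") as p:
        db = VariantAnnotationDB.from_tsv(p)
        printed = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    with _data("table1_clinical.csv") as p:
        pairs = read_clinical_table(p)
        expected = pd.read_csv(p, dtype=str, keep_default_na=False)[
            ["patient_id", "printed_discordance", "printed_clinical_call",
             "printed_mtdna_call"]
        ]
    return CohortFixture(
        variant_calls=calls,
        annotation_db=db,
        clinical_pairs=pairs,
        expected=expected,
        printed_annotations=printed,
    )


def printed_pathogenic_variants(fixture: CohortFixture) -> set[Variant]:
    """The variants flagged pathogenic in the published table (10 of 36)."""
    rows = fixture.printed_annotations
    return {
        parse_variant(v)
        for v, flag in zip(rows["variant"], rows["printed_pathogenic"])
        if str(flag) == "1"
    }
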