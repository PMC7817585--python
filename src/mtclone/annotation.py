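"""Functional annotation and pathogenicity classification of somatic variants.

Each variant gets its locus (standard rCRS intervals), a functional class,
an amino-acid change where applicable, and NV / AF / DS values looked up
from a static annotation table (HmtVar-style disease score and population
allele frequency).

The pathogenicity rule is class-specific and inclusive at the boundaries:

* missense (non-synonymous) variants: DS >= 0.43 and AF <= 0.003264
* tRNA variants:                      DS >= 0.35 and AF <= 0.005020

Everything else (synonymous, rRNA, control, intergenic) is never called
pathogenic, and a missing DS or AF also means not pathogenic — missingness
is explicit and distinct from zero. A stop-gain change would be held to the
missense thresholds (none occur in the bundled cohort).
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import ReferenceMismatchError
from .io import VariantAnnotationDB
from .reference import LocusMap, ReferenceGenome, amino_acid_change
from .variants import Variant

VARIANT_CLASSES = ("missense", "synonymous", "rRNA", "tRNA", "control", "other")

MISSENSE_DS_MIN = 0.43
MISSENSE_AF_MAX = 0.003264
TRNA_DS_MIN = 0.35
TRNA_AF_MAX = 0.005020


@dataclass(frozen=True)
class AnnotationRecord:
    """Full annotation of one somatic variant."""

    variant: Variant
    locus_symbol: str | None  # None = intergenic
    variant_class: str
    aa_change: str | None  # e.g. "M257T"; None for non-coding/synonymous label kept below
    NV: float | None
    AF: float | None
    DS: float | None
    pathogenic: bool


def _classify(locus, consequence: str) -> tuple[str, str | None]:
    if locus is None:
        return "other", None
    if locus.locus_type == "rRNA":
        return "rRNA", None
    if locus.locus_type == "tRNA":
        return "tRNA", None
    if locus.locus_type == "control":
        return "control", None
    # protein-coding
    if consequence.startswith("synonymous:"):
        return "synonymous", consequence.split(":", 1)[1]
    if consequence == "non-coding":
        return "other", None
    return "missense", consequence


def _pathogenic(variant_class: str, AF: float | None, DS: float | None) -> bool:
    if DS is None or AF is None:
        return False
    if variant_class == "missense":
        return DS >= MISSENSE_DS_MIN and AF <= MISSENSE_AF_MAX
    if variant_class == "tRNA":
        return DS >= TRNA_DS_MIN and AF <= TRNA_AF_MAX
    return False


def annotate(
    variant: Variant,
    db: VariantAnnotationDB,
    reference: ReferenceGenome,
    locus_map: LocusMap,
) -> AnnotationRecord:
    """Annotate one variant; raises ReferenceMismatchError on a bad REF base."""
    ref_base = reference.base(variant.position)
    if ref_base != variant.ref:
        raise ReferenceMismatchError(
            f"{variant.label}: reference has {ref_base} at {variant.position}"
        )
    locus = locus_map.locus_of(variant.position)
    consequence = amino_acid_change(variant, reference, locus=locus)
    variant_class, aa = _classify(locus, consequence)
    values = db.get(variant)
    return AnnotationRecord(
        variant=variant,
        locus_symbol=locus.symbol if locus else None,
        variant_class=variant_class,
        aa_change=aa,
        NV=values.NV,
        AF=values.AF,
        DS=values.DS,
        pathogenic=_pathogenic(variant_class, values.AF, values.DS),
    )


def is_pathogenic(record: AnnotationRecord) -> bool:
    """Class-specific DS/AF threshold rule (see module docstring)."""
    return _pathogenic(record.variant_class, record.AF, record.DS)


def annotate_all(
    variants,
    db: VariantAnnotationDB,
    reference: ReferenceGenome,
    locus_map: LocusMap,
) -> dict[Variant, AnnotationRecord]:
    return {v: annotate(v, db, reference, locus_map) for v in variants}
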