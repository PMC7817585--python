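"""Substitution calling against the mitochondrial reference.

A sample's full-length mitochondrial sequence (Sanger consensus exported as
FASTA, with mixed peaks encoded as IUPAC ambiguity codes) is globally
aligned to the reference; every mismatch column is interpreted as a
substitution call:

* plain base B != R            -> homoplasmic variant R>B
* two-fold ambiguity {R, B'}   -> heteroplasmic variant R>B' (mixed peak
  containing the reference allele)
* 'N', ambiguity without R, or three/four-fold ambiguity -> no call (logged)
* gap columns -> indel events, reported separately, never as variants
* reference 'N' columns (the rCRS placeholder at 3107) -> no call

The default alignment engine is edlib's global (Needleman-Wunsch)
edit-distance alignment: unit costs make one substitution (cost 1) cheaper
than a gap pair (cost 2), so substitutions are preferred on near-identical
full-length genomes, and it is fast enough for cohort-scale use. An
affine-gap engine (Biopython PairwiseAligner) with configurable scoring is
available for small inputs and cross-checks.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib

from .errors import InsufficientSequenceError, OracleInapplicableError
from .io import SampleRecord
from .reference import ReferenceGenome
from .variants import BASES, Variant

log = logging.getLogger(__name__)

#: IUPAC ambiguity code -> set of bases
IUPAC_EXPANSION = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: base pair (frozenset) -> two-fold IUPAC code
AMBIGUITY_OF = {v: k for k, v in IUPAC_EXPANSION.items() if len(v) == 2}


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap scores for the Biopython engine (exposed in config/CLI)."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1


@dataclass(frozen=True)
class Alignment:
    """A global pairwise alignment of one sample against the reference."""

    sample_aligned: str
    reference_aligned: str
    patient_id: str | None = None
    tissue: str | None = None

    def __post_init__(self) -> None:
        if len(self.sample_aligned) != len(self.reference_aligned):
            raise ValueError("aligned strings must have equal length")


@dataclass(frozen=True)
class IndelEvent:
    """A gap run in the alignment (never part of variant identity)."""

    reference_position: int  # 1-based position of the last reference base before/at the event
    kind: str  # "deletion" (gap in sample) | "insertion" (gap in reference)
    length: int
    bases: str


def align_to_reference(
    sample: SampleRecord,
    reference: ReferenceGenome,
    scoring: AlignmentScoring | None = None,
) -> Alignment:
    """Global end-to-end alignment of a sample to the reference.

    With ``scoring=None`` the edlib engine is used (default); passing an
    :class:`AlignmentScoring` selects the affine-gap Biopython engine.
    """
    n, m = len(sample.sequence), len(reference.sequence)
    if n < 0.5 * m:
        raise InsufficientSequenceError(
            f"sample {sample.patient_id}|{sample.tissue} covers only "
            f"{n}/{m} bases"
        )
    if not 0.95 * m <= n <= 1.05 * m:
        log.warning(
            "sample %s|%s length %d deviates >5%% from reference",
            sample.patient_id, sample.tissue, n,
        )
    if scoring is None:
        res = edlib.align(sample.sequence, reference.sequence, mode="NW", task="path")
        nice = edlib.getNiceAlignment(res, sample.sequence, reference.sequence)
        return Alignment(
            nice["query_aligned"], nice["target_aligned"],
            sample.patient_id, sample.tissue,
        )
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=scoring.match,
        mismatch_score=scoring.mismatch,
        open_gap_score=scoring.gap_open,
        extend_gap_score=scoring.gap_extend,
    )
    aln = aligner.align(sample.sequence, reference.sequence)[0]
    sample_aligned, reference_aligned = str(aln[0]), str(aln[1])
    return Alignment(sample_aligned, reference_aligned, sample.patient_id, sample.tissue)


def _interpret_column(ref_base: str, sample_base: str) -> tuple[str, bool] | None:
    """Substitution rule for one gap-free column: (alt, heteroplasmic) or no call."""
    if ref_base not in BASES:  # reference 'N' placeholder
        return None
    expansion = IUPAC_EXPANSION.get(sample_base)
    if expansion is None:
        return None
    if len(expansion) == 1:
        (base,) = expansion
        if base == ref_base:
            return None
        return base, False
    if len(expansion) == 2 and ref_base in expansion:
        (other,) = expansion - {ref_base}
        return other, True
    return None


def call_variants(alignment: Alignment) -> set[Variant]:
    """Substitution calls from every mismatch column of an alignment."""
    variants: set[Variant] = set()
    ref_pos = 0
    for sample_base, ref_base in zip(
        alignment.sample_aligned, alignment.reference_aligned
    ):
        if ref_base != "-":
            ref_pos += 1
        if sample_base == "-" or ref_base == "-":
            continue
        if sample_base == ref_base:
            continue
        interpreted = _interpret_column(ref_base, sample_base)
        if interpreted is None:
            log.debug(
                "no call at m.%d (ref %s, sample %s)", ref_pos, ref_base, sample_base
            )
            continue
        alt, heteroplasmic = interpreted
        variants.add(
            Variant(ref_pos, ref_base, alt,
                    heteroplasmic=heteroplasmic, source_tissue=alignment.tissue)
        )
    return variants


def indel_events(alignment: Alignment) -> list[IndelEvent]:
    """Gap runs in the alignment, reported as events (not variants)."""
    events: list[IndelEvent] = []
    ref_pos = 0
    run_kind: str | None = None
    run_bases: list[str] = []
    run_anchor = 0

    def flush() -> None:
        nonlocal run_kind, run_bases
        if run_kind is not None:
            events.append(
                IndelEvent(run_anchor, run_kind, len(run_bases), "".join(run_bases))
            )
        run_kind, run_bases = None, []

    for sample_base, ref_base in zip(
        alignment.sample_aligned, alignment.reference_aligned
    ):
        if ref_base != "-":
            ref_pos += 1
        if sample_base == "-" and ref_base != "-":
            if run_kind != "deletion":
                flush()
                run_kind, run_anchor = "deletion", ref_pos
            run_bases.append(ref_base)
        elif ref_base == "-" and sample_base != "-":
            if run_kind != "insertion":
                flush()
                run_kind, run_anchor = "insertion", ref_pos
            run_bases.append(sample_base)
        else:
            flush()
    flush()
    return events


def diff_oracle(
    sample_sequence: str, reference_sequence: str, tissue: str | None = None
) -> set[Variant]:
    """Position-by-position substitution calling for indel-free input.

    Independent oracle for :func:`call_variants`: applies the identical
    per-column rules but without any alignment step, hence only valid when
    sample and reference have equal length.
    """
    if len(sample_sequence) != len(reference_sequence):
        raise OracleInapplicableError(
            "diff oracle requires equal-length, indel-free sequences"
        )
    variants: set[Variant] = set()
    for i, (sample_base, ref_base) in enumerate(
        zip(sample_sequence.upper(), reference_sequence.upper()), start=1
    ):
        if sample_base == ref_base:
            continue
        interpreted = _interpret_column(ref_base, sample_base)
        if interpreted is not None:
            alt, heteroplasmic = interpreted
            variants.add(
                Variant(i, ref_base, alt,
                        heteroplasmic=heteroplasmic, source_tissue=tissue)
            )
    return variants
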