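"""End-to-end orchestration: call -> somatic -> annotate -> clonality ->
clinical -> report.

Two entry points cover the two ways a cohort arrives:

* :func:`run_from_fasta` — per-patient N/BC/CBC mitochondrial sequences;
  each sample is aligned to the reference and substitutions are called;
* :func:`run_from_variant_table` — pre-computed per-compartment variant
  calls (the form in which published mtDNA cohorts are reported).

Both paths then share the identical somatic-filter / annotation /
clonality / clinical / report code, and both are deterministic: all
randomness in the package lives in the simulator.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .annotation import annotate_all
from .calling import AlignmentScoring, align_to_reference, call_variants
from .clinical import classify_clinical
from .clonality import cohort_calls
from .errors import MissingNormalError
from .io import (
    SampleRecord,
    VariantAnnotationDB,
    read_clinical_table,
    read_cohort_fasta,
    read_variant_table,
    write_report,
    write_variant_table,
)
from .reference import LocusMap, ReferenceGenome, load_locus_map, load_reference
from .report import ClonalityReport, summarize_cohort
from .somatic import build_profile

log = logging.getLogger(__name__)


@dataclass
class PipelineContext:
    """Shared resources; defaults to the bundled reference and locus map."""

    reference: ReferenceGenome = field(default_factory=load_reference)
    locus_map: LocusMap = field(default_factory=load_locus_map)
    annotation_db: VariantAnnotationDB = field(default_factory=VariantAnnotationDB)
    scoring: AlignmentScoring | None = None  # None -> edlib engine


def _finish(profiles, pairs, context, notes=()) -> ClonalityReport:
    mtdna = cohort_calls(profiles)
    clinical = [classify_clinical(p) for p in pairs]
    annotations = {
        p.patient_id: annotate_all(
            p.all_somatic, context.annotation_db, context.reference, context.locus_map
        )
        for p in profiles
    }
    return summarize_cohort(profiles, clinical, mtdna, annotations, pairs, notes)


def profiles_from_calls(calls: dict, require_normal: bool = False) -> list:
    """Somatic profiles from per-patient {BC, CBC, N} call sets.

    Variant tables of published cohorts list only tumor-specific variants,
    so a missing normal entry is treated as an empty (wild-type) normal
    unless ``require_normal`` is set.
    """
    profiles = []
    skipped = []
    for pid in sorted(calls):
        tissues = calls[pid]
        normal = tissues.get("N")
        if normal is None and require_normal:
            skipped.append(pid)
            continue
        profiles.append(
            build_profile(pid, tissues.get("BC", set()), tissues.get("CBC", set()),
                          normal if normal is not None else set())
        )
    if skipped:
        log.warning("skipped %d patient(s) without a matched normal: %s",
                    len(skipped), ", ".join(skipped))
    return profiles


def run_from_variant_table(
    variant_table_path, clinical_path, context: PipelineContext | None = None
) -> ClonalityReport:
    """Pipeline entry point for pre-computed variant calls."""
    context = context or PipelineContext()
    calls = read_variant_table(variant_table_path)
    pairs = read_clinical_table(clinical_path)
    for p in pairs:  # patients with no listed variants still have profiles
        calls.setdefault(p.patient_id, {"BC": set(), "CBC": set(), "N": set()})
    return _finish(profiles_from_calls(calls), pairs, context)


def profiles_from_samples(
    samples: list[SampleRecord], context: PipelineContext
) -> list:
    """Align and call every sample, then somatic-filter per patient.

    Patients without a matched normal are skipped with a warning (their
    tumor-specific status cannot be ascertained).
    """
    by_patient: dict[str, dict[str, SampleRecord]] = {}
    for s in samples:
        by_patient.setdefault(s.patient_id, {})[s.tissue] = s
    profiles = []
    for pid in sorted(by_patient):
        tissues = by_patient[pid]
        if "N" not in tissues:
            log.warning("skipping patient %s: no matched normal sample", pid)
            continue
        calls = {}
        for tissue, sample in tissues.items():
            aln = align_to_reference(sample, context.reference, context.scoring)
            calls[tissue] = call_variants(aln)
        try:
            profiles.append(
                build_profile(pid, calls.get("BC", set()), calls.get("CBC", set()),
                              calls["N"])
            )
        except MissingNormalError:  # pragma: no cover - guarded above
            continue
    return profiles


def run_from_fasta(
    fasta_paths, clinical_path, context: PipelineContext | None = None
) -> ClonalityReport:
    """Pipeline entry point for raw per-sample sequences."""
    context = context or PipelineContext()
    samples = read_cohort_fasta(fasta_paths)
    profiles = profiles_from_samples(samples, context)
    pairs = read_clinical_table(clinical_path)
    kept = {p.patient_id for p in profiles}
    pairs = [p for p in pairs if p.patient_id in kept]
    return _finish(profiles, pairs, context)


def write_outputs(report: ClonalityReport, profiles, outdir) -> None:
    """Write the JSON report and the somatic-profile TSV intermediate."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_report(report.to_dict(), outdir / "report.json")
    write_variant_table(
        {p.patient_id: {"BC": p.bc_somatic, "CBC": p.cbc_somatic} for p in profiles},
        outdir / "somatic_profiles.tsv",
    )
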