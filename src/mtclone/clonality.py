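"""Shared-somatic-variant clonality call for a paired-tumor patient.

The inference rests on the non-recurrence of somatic mtDNA mutations: two
independent tumors acquiring the identical substitution by chance is
essentially impossible, so one shared tumor-specific variant suffices to
call the pair clonal (metCBC — the contralateral tumor is a metastatic
spread). The absence of sharing is *not* evidence of independence, because
mutations may arise after the metastatic seeding or be lost; such pairs are
non-informative (NI), never "independent".
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import EmptyCohortError
from .somatic import PatientVariantProfile
from .variants import Variant

MTDNA_CALLS = ("metCBC", "NI")


@dataclass(frozen=True)
class MtdnaCall:
    """Per-patient mtDNA clonality verdict with the supporting evidence."""

    patient_id: str
    call: str
    shared_variants: frozenset[Variant]
    bc_only: frozenset[Variant]
    cbc_only: frozenset[Variant]

    def __post_init__(self) -> None:
        assert (self.call == "metCBC") == bool(self.shared_variants)


def classify_pair(profile: PatientVariantProfile) -> MtdnaCall:
    """metCBC iff the two tumors share >= 1 tumor-specific variant."""
    shared = profile.bc_somatic & profile.cbc_somatic
    return MtdnaCall(
        patient_id=profile.patient_id,
        call="metCBC" if shared else "NI",
        shared_variants=frozenset(shared),
        bc_only=frozenset(profile.bc_somatic - shared),
        cbc_only=frozenset(profile.cbc_somatic - shared),
    )


@dataclass(frozen=True)
class CohortCalls:
    """All per-patient calls plus cohort-level counters."""

    calls: tuple[MtdnaCall, ...]

    @property
    def informative_patients(self) -> tuple[str, ...]:
        return tuple(c.patient_id for c in self.calls if c.call == "metCBC")

    @property
    def n_informative(self) -> int:
        return len(self.informative_patients)

    @property
    def shared_variant_total(self) -> int:
        return sum(len(c.shared_variants) for c in self.calls)


def cohort_calls(profiles) -> CohortCalls:
    """Classify every profile; patient order follows sorted patient ids."""
    profiles = list(profiles)
    if not profiles:
        raise EmptyCohortError("no profiles to classify")
    ordered = sorted(profiles, key=lambda p: p.patient_id)
    return CohortCalls(tuple(classify_pair(p) for p in ordered))
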