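"""Cohort-level aggregation and clinical-vs-mtDNA concordance report.

The report is a pure function of its inputs: per-case rows (both
classifications plus the variant evidence) and cohort aggregates (counts
per verdict, descriptive statistics of ages and metachronous intervals,
pathogenicity and rRNA tallies, and the three disagreement/concordance
lists). Percentages are always derived from the stored counts, rounded
half-up to the stated precision; both the sample (n-1) and population (n)
standard deviations are emitted.
"""
from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from .annotation import AnnotationRecord
from .clinical import ClinicalCall, PairFeatures
from .clonality import CohortCalls
from .errors import InconsistencyError, UndefinedStatisticError
from .somatic import PatientVariantProfile
from .variants import Variant


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (0.5 -> 1), as printed statistics use."""
    q = Decimal(1).scaleb(-ndigits)
    v = float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
    return v if ndigits > 0 else (int(v) if ndigits == 0 else v)


@dataclass(frozen=True)
class ClonalityReport:
    """Per-case rows plus cohort aggregates; JSON-serializable."""

    cases: tuple[dict, ...]
    aggregates: dict
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "cases": list(self.cases),
            "aggregates": self.aggregates,
            "notes": list(self.notes),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClonalityReport":
        return cls(tuple(d["cases"]), dict(d["aggregates"]), tuple(d["notes"]))


def _descriptives(values: list[float]) -> dict:
    out = {
        "mean": round_half_up(statistics.fmean(values), 1),
        "median": float(statistics.median(values)),
        "min": min(values),
        "max": max(values),
    }
    if len(values) > 1:
        out["sd_sample"] = round_half_up(statistics.stdev(values), 1)
        out["sd_population"] = round_half_up(statistics.pstdev(values), 1)
    return out


def _compartment(profile: PatientVariantProfile, variant: Variant) -> str:
    in_bc = variant in profile.bc_somatic
    in_cbc = variant in profile.cbc_somatic
    if in_bc and in_cbc:
        return "BC+CBC"
    return "BC" if in_bc else "CBC"


def summarize_cohort(
    profiles: Iterable[PatientVariantProfile],
    clinical_calls: Iterable[ClinicalCall],
    mtdna_calls: CohortCalls,
    annotations: Mapping[str, Mapping[Variant, AnnotationRecord]],
    pairs: Iterable[PairFeatures],
    notes: Iterable[str] = (),
) -> ClonalityReport:
    """Build the full cohort report; all inputs must cover the same patients."""
    profiles = {p.patient_id: p for p in profiles}
    clinical = {c.patient_id: c for c in clinical_calls}
    mtdna = {c.patient_id: c for c in mtdna_calls.calls}
    pair_by_id = {p.patient_id: p for p in pairs}
    sets = {
        "profiles": set(profiles), "clinical": set(clinical),
        "mtdna": set(mtdna), "pairs": set(pair_by_id),
    }
    universe = set.union(*sets.values())
    for name, s in sets.items():
        if s != universe:
            raise InconsistencyError(
                f"patient set mismatch in {name}: {sorted(universe ^ s)}"
            )

    cases = []
    n_pathogenic = 0
    pathogenic_cbc_only = 0
    pathogenic_shared = 0
    n_rrna = 0
    for pid in sorted(universe):
        prof, clin, mt, pair = profiles[pid], clinical[pid], mtdna[pid], pair_by_id[pid]
        anns = annotations.get(pid, {})
        pathogenic = sorted(v for v, a in anns.items() if a.pathogenic)
        rrna = sorted(v for v, a in anns.items() if a.variant_class == "rRNA")
        n_pathogenic += len(pathogenic)
        n_rrna += len(rrna)
        for v in pathogenic:
            comp = _compartment(prof, v)
            if comp == "CBC":
                pathogenic_cbc_only += 1
            elif comp == "BC+CBC":
                pathogenic_shared += 1
        cases.append(
            {
                "patient_id": pid,
                "age": pair.age,
                "synchronicity": pair.synchronicity,
                "interval_months": pair.interval_months,
                "clinical_call": clin.call,
                "clinical_factors": sorted(clin.factors),
                "mtdna_call": mt.call,
                "shared_variants": [v.label for v in sorted(mt.shared_variants)],
                "bc_only_variants": [v.label for v in sorted(mt.bc_only)],
                "cbc_only_variants": [v.label for v in sorted(mt.cbc_only)],
                "n_somatic": len(prof.all_somatic),
                "pathogenic_variants": [v.label for v in pathogenic],
                "rrna_variants": [v.label for v in rrna],
            }
        )

    n = len(cases)
    metachronous = [c for c in cases if c["synchronicity"] == "M"]
    met_informative = [c for c in metachronous if c["mtdna_call"] == "metCBC"]

    def ids(rows) -> list[str]:
        return [c["patient_id"] for c in rows]

    clinical_counts = {call: 0 for call in ("bilCBC", "metCBC", "NI", "DisNI")}
    for c in cases:
        clinical_counts[c["clinical_call"]] += 1
    mtdna_counts = {"metCBC": 0, "NI": 0}
    for c in cases:
        mtdna_counts[c["mtdna_call"]] += 1

    aggregates = {
        "n_cases": n,
        "clinical_counts": clinical_counts,
        "mtdna_counts": mtdna_counts,
        "n_somatic_variants": sum(c["n_somatic"] for c in cases),
        "n_cases_with_somatic": sum(1 for c in cases if c["n_somatic"]),
        "n_shared_variants": mtdna_calls.shared_variant_total,
        "n_informative": mtdna_calls.n_informative,
        "informative_patients": sorted(mtdna_calls.informative_patients),
        "n_synchronous": n - len(metachronous),
        "n_metachronous": len(metachronous),
        "ages": _descriptives([c["age"] for c in cases if c["age"] is not None]),
        "n_pathogenic_variants": n_pathogenic,
        "n_cases_with_pathogenic": sum(1 for c in cases if c["pathogenic_variants"]),
        "n_pathogenic_shared": pathogenic_shared,
        "n_rrna_variants": n_rrna,
        "disagreements": {
            "clinical_bilCBC_mtdna_metCBC": ids(
                c for c in cases
                if c["clinical_call"] == "bilCBC" and c["mtdna_call"] == "metCBC"
            ),
            "mtdna_resolves_clinical_NI": ids(
                c for c in cases
                if c["clinical_call"] in ("NI", "DisNI") and c["mtdna_call"] == "metCBC"
            ),
            "concordant_metCBC": ids(
                c for c in cases
                if c["clinical_call"] == "metCBC" and c["mtdna_call"] == "metCBC"
            ),
        },
    }
    if n_pathogenic:
        aggregates["pathogenic_cbc_exclusive_percent"] = round_half_up(
            100.0 * pathogenic_cbc_only / n_pathogenic
        )
    if metachronous:
        aggregates["metachronous_intervals"] = _descriptives(
            [c["interval_months"] for c in metachronous]
        )
        aggregates["metachronous_informative_percent"] = round_half_up(
            100.0 * len(met_informative) / len(metachronous)
        )
    return ClonalityReport(tuple(cases), aggregates, tuple(notes))


def metachronous_informativeness(report: ClonalityReport) -> int:
    """Whole-percent share of metachronous pairs called metCBC by mtDNA."""
    if report.aggregates.get("n_metachronous", 0) == 0:
        raise UndefinedStatisticError("no metachronous cases in the cohort")
    return int(report.aggregates["metachronous_informative_percent"])
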