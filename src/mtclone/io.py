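"""Readers and writers for all external artifacts.

Formats (all plain text, UTF-8, LF):

* sample FASTA — one record per sample, header ``<patient>|<tissue>`` with
  tissue in {BC, CBC, N};
* variant table TSV — columns ``patient_id, variant, compartment`` with
  compartment in {BC, CBC, BC+CBC} and variants in canonical m.-notation;
* annotation DB TSV — columns ``variant, NV, AF, DS`` (missing values as
  ``NA``, never 0);
* clinical CSV — one row per case pair (see ``clinical``);
* JSON reports (deterministic key order, lossless round trip).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import DuplicateRecordError, FormatError
from .variants import TISSUES, Variant, format_variant, parse_variant

log = logging.getLogger(__name__)

IUPAC = frozenset("ACGTNRYSWKMBDHV")

COMPARTMENTS = ("BC", "CBC", "BC+CBC")


@dataclass(frozen=True)
class SampleRecord:
    """One sample sequence: a patient's tumor (BC/CBC) or normal (N) tissue."""

    patient_id: str
    tissue: str
    sequence: str

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise FormatError(
                f"unknown tissue code {self.tissue!r} (expected one of {TISSUES})"
            )
        bad = set(self.sequence) - IUPAC
        if bad:
            raise FormatError(f"non-IUPAC characters in sequence: {sorted(bad)}")


def read_cohort_fasta(paths) -> list[SampleRecord]:
    """Parse sample FASTA file(s) with ``<patient>|<tissue>`` headers."""
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    records: list[SampleRecord] = []
    seen: set[tuple[str, str]] = set()
    for path in paths:
        n_before = len(records)
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.id.split("|")
            if len(parts) != 2 or not parts[0]:
                raise FormatError(f"malformed FASTA header {rec.id!r} in {path}")
            patient_id, tissue = parts
            key = (patient_id, tissue)
            if key in seen:
                raise DuplicateRecordError(f"duplicate sample {patient_id}|{tissue}")
            seen.add(key)
            records.append(SampleRecord(patient_id, tissue, str(rec.seq).upper()))
        if len(records) == n_before:
            log.warning("no FASTA records found in %s", path)
    return records


def write_cohort_fasta(records: Iterable[SampleRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.patient_id}|{rec.tissue}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_variant_table(path) -> dict[str, dict[str, set[Variant]]]:
    """Per-patient, per-tissue variant sets from a compartment TSV.

    ``BC+CBC`` rows are expanded into both tumor sets. An optional
    ``heteroplasmic`` column (0/1) is honored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"patient_id", "variant", "compartment"}
    if not required.issubset(df.columns):
        raise FormatError(f"variant table needs columns {sorted(required)}")
    out: dict[str, dict[str, set[Variant]]] = {}
    for i, row in df.iterrows():
        compartment = row["compartment"].strip()
        if compartment not in COMPARTMENTS:
            raise FormatError(f"row {i}: unknown compartment {compartment!r}")
        het = str(row.get("heteroplasmic", "0")).strip() in {"1", "True", "true"}
        try:
            variant = parse_variant(row["variant"], heteroplasmic=het)
        except FormatError as exc:
            raise FormatError(f"row {i} ({row['patient_id']}): {exc}") from exc
        tissues = ["BC", "CBC"] if compartment == "BC+CBC" else [compartment]
        patient = out.setdefault(row["patient_id"], {"BC": set(), "CBC": set(), "N": set()})
        for tissue in tissues:
            patient[tissue].add(variant)
    return out


def write_variant_table(
    calls: Mapping[str, Mapping[str, Iterable[Variant]]], path
) -> None:
    """Write per-patient tumor variant sets back to the compartment TSV."""
    rows = []
    for patient_id in sorted(calls):
        tissues = calls[patient_id]
        bc = set(tissues.get("BC", ()))
        cbc = set(tissues.get("CBC", ()))
        for v in sorted(bc & cbc):
            rows.append((patient_id, format_variant(v), "BC+CBC"))
        for v in sorted(bc - cbc):
            rows.append((patient_id, format_variant(v), "BC"))
        for v in sorted(cbc - bc):
            rows.append((patient_id, format_variant(v), "CBC"))
    pd.DataFrame(rows, columns=["patient_id", "variant", "compartment"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass(frozen=True)
class AnnotationValues:
    """NV/AF/DS triplet for one variant; ``None`` means not available."""

    NV: float | None
    AF: float | None
    DS: float | None


class VariantAnnotationDB:
    """Lookup of NV / AF / DS by variant identity (position, ref, alt)."""

    def __init__(self, values: Mapping[Variant, AnnotationValues] | None = None):
        self._values = dict(values or {})
        for v in self._values.values():
            for x in (v.NV, v.AF, v.DS):
                if x is not None and not 0.0 <= x <= 1.0:
                    raise FormatError(f"annotation value {x} outside [0,1]")

    def get(self, variant: Variant) -> AnnotationValues:
        return self._values.get(variant, AnnotationValues(None, None, None))

    def __len__(self) -> int:
        return len(self._values)

    def __contains__(self, variant: Variant) -> bool:
        return variant in self._values

    @classmethod
    def from_tsv(cls, path) -> "VariantAnnotationDB":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"variant", "NV", "AF", "DS"}
        if not required.issubset(df.columns):
            raise FormatError(f"annotation DB needs columns {sorted(required)}")

        def val(x) -> float | None:
            if pd.isna(x) or str(x).strip() in {"NA", "-", "–", ""}:
                return None
            return float(x)

        values = {}
        for _, row in df.iterrows():
            values[parse_variant(row["variant"])] = AnnotationValues(
                val(row["NV"]), val(row["AF"]), val(row["DS"])
            )
        return cls(values)


def write_report(report: dict, path) -> None:
    """Serialize a report mapping to JSON (stable key order, LF endings)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def read_clinical_table(path) -> list:
    """Clinical CSV -> list of :class:`mtclone.clinical.PairFeatures`.

    Accepts either pre-computed ``ihc_1``/``ihc_2`` categories or raw
    ``er_1, pr_1, her2_1`` (and ``_2``) boolean columns, which are collapsed
    to the four IHC classes. Extra columns (e.g. the bundled ``printed_*``
    expected values) are ignored here.
    """
    from .clinical import PairFeatures, TumorFeatures, ihc_class

    df = pd.read_csv(path, dtype=str)

    def boolean(x) -> bool:
        return str(x).strip().lower() in {"yes", "true", "1"}

    def tumor(row, k: int) -> TumorFeatures:
        if f"ihc_{k}" in row and not pd.isna(row[f"ihc_{k}"]):
            ihc = row[f"ihc_{k}"].strip()
        else:
            ihc = ihc_class(
                boolean(row[f"er_{k}"]), boolean(row[f"pr_{k}"]), boolean(row[f"her2_{k}"])
            )
        return TumorFeatures(
            histotype=row[f"histology_{k}"].strip(),
            grade=row[f"grade_{k}"].strip(),
            stage=int(row[f"stage_{k}"]),
            in_situ=boolean(row[f"in_situ_{k}"]),
            ihc=ihc,
            ptnm=str(row.get(f"ptnm_{k}", "") or ""),
        )

    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            PairFeatures(
                patient_id=row["patient_id"],
                first=tumor(row, 1),
                second=tumor(row, 2),
                interval_months=float(row["interval_months"]),
                age=float(row["age"]) if "age" in row and not pd.isna(row["age"]) else None,
            )
        )
    return pairs


def write_clinical_table(pairs, path) -> None:
    rows = []
    for p in pairs:
        row = {"patient_id": p.patient_id, "age": p.age,
               "interval_months": p.interval_months}
        for k, t in (("1", p.first), ("2", p.second)):
            row[f"histology_{k}"] = t.histotype
            row[f"grade_{k}"] = t.grade
            row[f"ptnm_{k}"] = t.ptnm
            row[f"stage_{k}"] = t.stage
            row[f"in_situ_{k}"] = "Yes" if t.in_situ else "No"
            row[f"ihc_{k}"] = t.ihc
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
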