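"""Codified clinico-pathological clonality classification of a tumor pair.

The rule engine reproduces the routine histopathological reasoning used to
label a contralateral pair as independent (bilCBC), metastatic (metCBC),
non-informative (NI) or discordant/non-informative (DisNI):

Discordance factors (evidence for an independent second primary):

* **Histology** — special-type histology (ILC or other special type) in one
  tumor versus no-special-type carcinoma (IC NST) in the other;
* **IHC** — different immunohistochemical bioprofiles (Lum / Lum-H / Her2 /
  TN, derived from ER/PR/HER2; no luminal A/B split);
* **InSitu** — an in-situ component in the second tumor of a metachronous
  pair, or in *both* tumors of a synchronous pair (one-sided in-situ in a
  synchronous pair is not informative).

Metastasis indicator:

* **Stage** — stage 3 at onset in either tumor of a synchronous pair, or in
  the first tumor of a metachronous pair.

Verdict precedence: independence factors alone -> bilCBC; the stage factor
alone -> metCBC; both present -> DisNI when the stage-3 tumor is the
primary (truly contradictory evidence), otherwise the independence factors
win (bilCBC); no factors -> NI. Grade differences, distant metastasis and
the time interval are recorded but never act as factors. A pair is
metachronous when the inter-tumor interval exceeds 6 months.
"""
from __future__ import annotations

from dataclasses import dataclass

HISTOTYPES = ("IC NST", "ILC", "other special")
GRADES = ("G1", "G2", "G3")
IHC_CLASSES = ("Lum", "Lum-H", "Her2", "TN")
CLINICAL_CALLS = ("bilCBC", "metCBC", "NI", "DisNI")
FACTORS = ("Histology", "IHC", "InSitu", "Stage")

METACHRONOUS_THRESHOLD_MONTHS = 6

BIL_FACTORS = frozenset({"Histology", "IHC", "InSitu"})


@dataclass(frozen=True)
class TumorFeatures:
    """Histopathological profile of one tumor."""

    histotype: str
    grade: str
    stage: int
    in_situ: bool
    ihc: str
    ptnm: str = ""

    def __post_init__(self) -> None:
        if self.histotype not in HISTOTYPES:
            raise ValueError(f"unknown histotype {self.histotype!r}")
        if self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r}")
        if self.stage not in (1, 2, 3):
            raise ValueError(f"stage must be 1/2/3, got {self.stage!r}")
        if self.ihc not in IHC_CLASSES:
            raise ValueError(f"unknown IHC class {self.ihc!r}")

    @property
    def special_type(self) -> bool:
        return self.histotype != "IC NST"


@dataclass(frozen=True)
class PairFeatures:
    """One case pair: the first (primary) tumor, the contralateral tumor,
    and the inter-tumor interval in months (0 = simultaneous diagnosis)."""

    patient_id: str
    first: TumorFeatures
    second: TumorFeatures
    interval_months: float
    age: float | None = None

    def __post_init__(self) -> None:
        if self.interval_months < 0:
            raise ValueError("interval_months must be >= 0")

    @property
    def synchronicity(self) -> str:
        """"M" (metachronous) iff the interval exceeds 6 months, else "S"."""
        return "M" if self.interval_months > METACHRONOUS_THRESHOLD_MONTHS else "S"


@dataclass(frozen=True)
class ClinicalCall:
    """Factor set and verdict for one pair."""

    patient_id: str
    factors: frozenset[str]
    stage3_in_primary: bool
    call: str

    def __post_init__(self) -> None:
        assert (self.call == "NI") == (not self.factors)
        if self.call == "DisNI":
            assert "Stage" in self.factors and self.factors & BIL_FACTORS


def ihc_class(er: bool, pr: bool, her2: bool) -> str:
    """IHC bioprofile from receptor status.

    Hormone-receptor positive (ER and/or PR) without HER2 is luminal-like
    (Lum), with HER2 luminal/HER2+ (Lum-H); HER2 alone is Her2; none is
    triple negative (TN).
    """
    if er or pr:
        return "Lum-H" if her2 else "Lum"
    return "Her2" if her2 else "TN"


def discordance_factors(pair: PairFeatures) -> tuple[frozenset[str], bool]:
    """The factor set and whether the stage-3 indicator sits in the primary."""
    factors: set[str] = set()
    if pair.first.special_type != pair.second.special_type:
        factors.add("Histology")
    if pair.first.ihc != pair.second.ihc:
        factors.add("IHC")
    metachronous = pair.synchronicity == "M"
    if metachronous:
        if pair.second.in_situ:
            factors.add("InSitu")
        if pair.first.stage == 3:
            factors.add("Stage")
    else:
        if pair.first.in_situ and pair.second.in_situ:
            factors.add("InSitu")
        if pair.first.stage == 3 or pair.second.stage == 3:
            factors.add("Stage")
    stage3_in_primary = "Stage" in factors and pair.first.stage == 3
    return frozenset(factors), stage3_in_primary


def classify_clinical(pair: PairFeatures) -> ClinicalCall:
    """Apply the verdict precedence to the pair's discordance factors."""
    factors, stage3_in_primary = discordance_factors(pair)
    bil = bool(factors & BIL_FACTORS)
    met = "Stage" in factors
    if bil and not met:
        call = "bilCBC"
    elif met and not bil:
        call = "metCBC"
    elif met and bil:
        call = "DisNI" if stage3_in_primary else "bilCBC"
    else:
        call = "NI"
    return ClinicalCall(pair.patient_id, factors, stage3_in_primary, call)
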