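"""Tumor-specific (somatic) variant filtering against the matched normal.

A variant is tumor-specific when it is absent from the same patient's
non-tumor tissue. Membership is by (position, ref, alt) identity only: a
heteroplasmic normal call suppresses a homoplasmic tumor call of the same
substitution, because the criterion is presence in normal, not dosage.
Calls at the rCRS placeholder position 3107 are excluded up front.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import MissingNormalError
from .variants import Variant

log = logging.getLogger(__name__)

PLACEHOLDER_POSITION = 3107


@dataclass(frozen=True)
class PatientVariantProfile:
    """Somatic variant sets of one patient's tumor pair plus the germline."""

    patient_id: str
    bc_somatic: frozenset[Variant]
    cbc_somatic: frozenset[Variant]
    germline: frozenset[Variant]

    def __post_init__(self) -> None:
        if self.bc_somatic & self.germline or self.cbc_somatic & self.germline:
            raise ValueError("somatic sets must be disjoint from germline")

    @property
    def all_somatic(self) -> frozenset[Variant]:
        return self.bc_somatic | self.cbc_somatic


def _clean(calls) -> frozenset[Variant]:
    kept = frozenset(v for v in calls if v.position != PLACEHOLDER_POSITION)
    dropped = len(set(calls)) - len(kept)
    if dropped:
        log.info("excluded %d call(s) at the rCRS placeholder position", dropped)
    return kept


def somatic_variants(tumor_calls, normal_calls) -> frozenset[Variant]:
    """Tumor calls absent from the matched normal, by identity triple."""
    return _clean(tumor_calls) - _clean(normal_calls)


def build_profile(
    patient_id: str, bc_calls, cbc_calls, normal_calls
) -> PatientVariantProfile:
    """Assemble a patient's somatic profile; the matched normal is mandatory.

    ``normal_calls`` may be an empty set (a normal that matched the reference
    everywhere) but never ``None``: without a sequenced normal the
    tumor-specific origin of a variant cannot be ascertained.
    """
    if normal_calls is None:
        raise MissingNormalError(f"patient {patient_id} lacks a matched normal")
    germline = _clean(normal_calls)
    return PatientVariantProfile(
        patient_id=patient_id,
        bc_somatic=somatic_variants(bc_calls, germline),
        cbc_somatic=somatic_variants(cbc_calls, germline),
        germline=germline,
    )
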