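"""The substitution-variant model and the m.-notation dialect.

A variant is a single-base substitution on the mitochondrial reference,
written in HGVS-like m.-notation: ``m.<pos><REF>><ALT>`` (canonical form has
no spaces; the parser tolerates the spaced form found in print, e.g.
``m.11529 T > C``).

Identity for all set operations is the triple ``(position, ref, alt)``:
heteroplasmy status and tissue of origin are carried as annotations but are
deliberately excluded from equality/hashing, because a variant seen as a
mixed peak in one tumor and a pure peak in the other is still the same
somatic event (the mixture reflects stromal-cell contamination, not a
different allele).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import FormatError

BASES = frozenset("ACGT")

#: tissue compartments: primary tumor, contralateral tumor, matched normal
TISSUES = ("BC", "CBC", "N")

_M_NOTATION = re.compile(
    r"^m\.\s*(\d+)\s*([ACGT])\s*>\s*([ACGT])$"
)


@dataclass(frozen=True, order=True)
class Variant:
    """One substitution in rCRS coordinates (1-based).

    ``heteroplasmic`` and ``source_tissue`` are excluded from comparison and
    hashing; see module docstring.
    """

    position: int
    ref: str
    alt: str
    heteroplasmic: bool = field(default=False, compare=False)
    source_tissue: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise FormatError(f"bases must be A/C/G/T, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise FormatError(f"ref and alt identical at m.{self.position}")
        if self.position < 1:
            raise FormatError(f"position must be >= 1, got {self.position}")

    @property
    def label(self) -> str:
        """Canonical m.-notation, e.g. ``m.11529T>C``."""
        return f"m.{self.position}{self.ref}>{self.alt}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_variant(text: str, **kwargs) -> Variant:
    """Parse m.-notation (spaces tolerated) into a :class:`Variant`.

    Extra keyword arguments (``heteroplasmic``, ``source_tissue``) are passed
    through to the constructor.
    """
    m = _M_NOTATION.match(text.strip())
    if not m:
        raise FormatError(f"unparsable variant string: {text!r}")
    pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
    return Variant(pos, ref, alt, **kwargs)


def format_variant(variant: Variant) -> str:
    """Canonical writer: never emits spaces."""
    return variant.label
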