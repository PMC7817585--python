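"""Coordinate model of the human mitochondrial reference.

The reference is the 16,569-bp circular genome in rCRS coordinates
(1-based, m.-notation). The packaged copy is a clearly-labelled synthetic
stand-in (see ``data/README.md``): locus intervals and codon arithmetic
match the standard public annotation exactly, while unconstrained
background bases are seeded-random. Any real rCRS FASTA can be supplied in
its place.

Translation uses the vertebrate mitochondrial genetic code (NCBI
translation table 2), which differs from the standard code at four codons:
ATA=Met, TGA=Trp, AGA/AGG=stop. Light-strand genes (MT-ND6 and most tRNAs)
are translated from the reverse complement of the heavy-strand reference.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio import SeqIO

from .errors import CoordinateError, InvalidLocusError, ReferenceMismatchError
from .variants import Variant

RCRS_LENGTH = 16569

LOCUS_TYPES = ("protein", "rRNA", "tRNA", "control")


def _mito_code() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


#: codon -> one-letter amino acid ('*' for stop), vertebrate mitochondrial code
MITO_GENETIC_CODE: dict[str, str] = _mito_code()


@dataclass(frozen=True)
class ReferenceGenome:
    """The mitochondrial reference sequence in 1-based circular coordinates."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) != RCRS_LENGTH:
            raise ValueError(
                f"reference must be {RCRS_LENGTH} bp, got {len(self.sequence)}"
            )
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("reference alphabet must be A/C/G/T/N")

    def base(self, position: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= position <= RCRS_LENGTH:
            raise CoordinateError(f"position {position} outside 1..{RCRS_LENGTH}")
        return self.sequence[position - 1]

    @classmethod
    def from_fasta(cls, path, name: str | None = None) -> "ReferenceGenome":
        record = next(SeqIO.parse(str(path), "fasta"))
        return cls(name or record.id, str(record.seq).upper())


@dataclass(frozen=True)
class Locus:
    """One annotated locus; the control region carries two intervals."""

    symbol: str
    locus_type: str
    intervals: tuple[tuple[int, int], ...]
    strand: str  # "heavy" | "light"

    def __post_init__(self) -> None:
        if self.locus_type not in LOCUS_TYPES:
            raise ValueError(f"unknown locus type {self.locus_type!r}")
        for start, end in self.intervals:
            if not (1 <= start <= end <= RCRS_LENGTH):
                raise ValueError(f"bad interval {start}-{end} in {self.symbol}")

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[0][1]

    def contains(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.intervals)


class LocusMap:
    """Interval lookup over the locus table (39 loci, two overlapping pairs)."""

    def __init__(self, loci: Iterable[Locus]):
        self.loci = tuple(loci)
        self._by_symbol = {l.symbol: l for l in self.loci}

    def __getitem__(self, symbol: str) -> Locus:
        return self._by_symbol[symbol]

    def __iter__(self):
        return iter(self.loci)

    def loci_at(self, position: int) -> tuple[Locus, ...]:
        """All loci containing a position, in ascending order of start."""
        if not 1 <= position <= RCRS_LENGTH:
            raise CoordinateError(f"position {position} outside 1..{RCRS_LENGTH}")
        hits = [l for l in self.loci if l.contains(position)]
        hits.sort(key=lambda l: (l.start, l.symbol))
        return tuple(hits)

    def locus_of(self, position: int) -> Locus | None:
        """Primary locus at a position (smallest start wins for overlaps);
        ``None`` for intergenic positions."""
        hits = self.loci_at(position)
        return hits[0] if hits else None

    @classmethod
    def from_tsv(cls, path) -> "LocusMap":
        rows: dict[str, dict] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                entry = rows.setdefault(
                    row["symbol"],
                    {"type": row["type"], "strand": row["strand"], "intervals": []},
                )
                entry["intervals"].append((int(row["start"]), int(row["end"])))
        return cls(
            Locus(sym, e["type"], tuple(e["intervals"]), e["strand"])
            for sym, e in rows.items()
        )


def load_locus_map() -> LocusMap:
    """The bundled standard rCRS locus table."""
    with resources.as_file(resources.files("mtclone.data") / "loci.tsv") as p:
        return LocusMap.from_tsv(p)


def load_reference() -> ReferenceGenome:
    """The bundled (synthetic stand-in) reference genome."""
    with resources.as_file(
        resources.files("mtclone.data") / "rcrs_synthetic.fasta"
    ) as p:
        return ReferenceGenome.from_fasta(p, name="rCRS")


def codon_index(position: int, locus: Locus) -> tuple[int, int]:
    """Codon number (1-based) and offset within codon (0/1/2) of a position.

    Heavy-strand genes read start->end; light-strand genes read end->start on
    the reverse complement, so their first codon sits at the interval's end.
    """
    if locus.locus_type != "protein":
        raise InvalidLocusError(f"{locus.symbol} is not protein-coding")
    if not locus.contains(position):
        raise CoordinateError(f"position {position} not in {locus.symbol}")
    if locus.strand == "heavy":
        off = position - locus.start
    else:
        off = locus.end - position
    return off // 3 + 1, off % 3


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _codon_positions(locus: Locus, codon_number: int) -> tuple[int, int, int]:
    """Heavy-strand positions of a codon, in translation (5'->3') order."""
    if locus.strand == "heavy":
        p = locus.start + 3 * (codon_number - 1)
        return (p, p + 1, p + 2)
    p = locus.end - 3 * (codon_number - 1)
    return (p, p - 1, p - 2)


def reference_codon(locus: Locus, codon_number: int, reference: ReferenceGenome) -> str:
    """The reference codon read in coding orientation (strand-aware)."""
    bases = [reference.base(p) for p in _codon_positions(locus, codon_number)]
    if locus.strand == "light":
        bases = [b.translate(_COMPLEMENT) for b in bases]
    return "".join(bases)


def amino_acid_change(
    variant: Variant,
    reference: ReferenceGenome,
    locus_map: LocusMap | None = None,
    locus: Locus | None = None,
) -> str:
    """Consequence label of a substitution.

    Returns ``"M257T"`` style labels for missense/stop changes,
    ``"synonymous:<label>"`` for silent changes, and ``"non-coding"`` when
    the primary locus is not protein-coding. Stop is written ``*``.
    """
    ref_base = reference.base(variant.position)
    if ref_base != variant.ref:
        raise ReferenceMismatchError(
            f"{variant.label}: reference has {ref_base} at {variant.position}"
        )
    if locus is None:
        if locus_map is None:
            raise ValueError("either locus_map or locus is required")
        locus = locus_map.locus_of(variant.position)
    if locus is None or locus.locus_type != "protein":
        return "non-coding"
    number, offset = codon_index(variant.position, locus)
    ref_codon = reference_codon(locus, number, reference)
    alt_base = variant.alt
    if locus.strand == "light":
        alt_base = alt_base.translate(_COMPLEMENT)
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    if "N" in ref_codon or "N" in alt_codon:
        return "non-coding"  # untranslatable across the rCRS placeholder
    aa_ref = MITO_GENETIC_CODE[ref_codon]
    aa_alt = MITO_GENETIC_CODE[alt_codon]
    label = f"{aa_ref}{number}{aa_alt}"
    if aa_ref == aa_alt:
        return f"synonymous:{label}"
    return label
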