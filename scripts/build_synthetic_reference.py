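"""Build the synthetic mitochondrial reference bundled with mtclone.

The true revised Cambridge Reference Sequence (rCRS, NC_012920) is public
but is not redistributed here; instead the package ships a SYNTHETIC
stand-in of the same length (16,569 bp) that preserves every property the
analysis depends on:

* the standard locus coordinates (``data/loci.tsv``) are the real public
  annotation;
* the placeholder 'N' at position 3107 is kept;
* at every variant site used by the bundled cohort fixture the reference
  base equals the published REF allele;
* at protein-coding variant sites the WHOLE codon is pinned so that
  translating reference vs. mutated codon reproduces the published
  amino-acid substitution (e.g. m.9591G>A -> V129I, m.14484T>C -> M64V on
  the light strand);
* all remaining bases are filled from a seeded RNG.

Run from the repository root:

    python scripts/build_synthetic_reference.py
"""
from __future__ import annotations

import pathlib

import numpy as np

LENGTH = 16569
OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "mtclone" / "data" / "rcrs_synthetic.fasta"

# Whole-codon pins for protein-coding variant sites.  Spans are heavy-strand
# 1-based inclusive; the written bases are heavy-strand.  For light-strand
# genes (MT-ND6) the codon is the reverse complement of the written span.
CODON_PINS = {
    # (start_pos, heavy-strand bases)          variant        consequence
    (11528, "ATG"): "m.11529T>C M257T MT-ND4",
    (7937, "TTC"): "m.7937T>C F118L MT-COII",
    (3526, "GCC"): "m.3526G>A A74T MT-ND1",
    (3832, "CTC"): "m.3833T>C L176P MT-ND1",
    (6642, "ATC"): "m.6642A>G I247V MT-COI",
    (9591, "GTC"): "m.9591G>A V129I MT-COIII",
    (13150, "CTA"): "m.13151T>C L272P MT-ND5",
    (11723, "ACC"): "m.11723A>T T322S MT-ND4",
    (12382, "ATC"): "m.12383T>C I16T MT-ND5",
    (11642, "GCC"): "m.11642G>A A295T MT-ND4",
    (5070, "ACC"): "m.5070A>G T201A MT-ND2",
    (13633, "GGC"): "m.13633G>A G433S MT-ND5",
    (5211, "CTG"): "m.5212T>C L248P MT-ND2",
    (9525, "GCC"): "m.9525G>A A107T MT-COIII",
    # synonymous third-position changes (printed '-' amino acid)
    (4105, "GCC"): "m.4107C>T syn MT-ND1",
    (6897, "CTG"): "m.6899G>A syn MT-COI",
    (3847, "GGG"): "m.3849G>A syn MT-ND1",
    (15851, "ATC"): "m.15853C>T syn MT-CYB",
    (10626, "CTC"): "m.10628C>T syn MT-ND4L",
    # light-strand MT-ND6 codons (heavy-strand bases written)
    (14206, "TGC"): "m.14207G>A A156V MT-ND6 (light)",
    (14482, "CAT"): "m.14484T>C M64V MT-ND6 (light)",
}

# Single-base REF pins for non-coding variant sites.
BASE_PINS = {
    1415: "G", 1641: "G", 1646: "T", 1743: "T", 1776: "G", 1982: "G",
    2233: "T", 2470: "G", 2492: "G", 2614: "T", 3019: "G", 3117: "C",
    3146: "G", 3153: "T", 3213: "A", 16078: "A",
}


def build(seed: int = 20201124) -> str:
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=LENGTH)
    seq[3107 - 1] = "N"
    for pos, base in BASE_PINS.items():
        seq[pos - 1] = base
    for (start, bases), _note in CODON_PINS.items():
        for i, b in enumerate(bases):
            seq[start - 1 + i] = b
    return "".join(seq)


def main() -> None:
    seq = build()
    assert len(seq) == LENGTH and seq[3106] == "N"
    with open(OUT, "w") as fh:
        fh.write(">rCRS-synthetic 16569 bp synthetic stand-in for NC_012920 (see data/README.md)\n")
        for i in range(0, LENGTH, 70):
            fh.write(seq[i:i + 70] + "\n")
    print(f"wrote {OUT} ({LENGTH} bp)")


if __name__ == "__main__":
    main()
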