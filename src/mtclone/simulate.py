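"""Synthetic paired-tumor cohort generator.

Emulates the statistical structure the clonality analysis assumes:

* every patient carries a shared germline mtDNA haplotype (the same
  substitutions in normal and both tumors);
* each tumor additionally acquires private somatic substitutions at
  positions drawn *without replacement within the patient* — the
  non-recurrence assumption that makes a shared somatic variant proof of
  clonality (cross-patient recurrence is allowed and harmless, since all
  comparisons are within-patient);
* a clonal (metastatic) pair retains a non-empty shared somatic set with
  probability ``p_shared_given_clonal``; an independent pair never shares;
* somatic variants are emitted heteroplasmically (as the IUPAC code of
  {ref, alt}) with probability ``p_heteroplasmic``, mimicking mixed Sanger
  peaks from stromal contamination;
* clinical features come from a small categorical model in which
  independent pairs are enriched for discordance factors and clonal pairs
  for stage-3 primaries.

Default parameters mirror the bundled 30-pair cohort: clonal fraction 0.23
(7/30 informative), ~1.3 shared variants per clonal pair (9/7), private
somatic rate 0.6 per tumor, heteroplasmy probability 0.9 ("nearly all"
shared variants were mixed peaks), synchronous fraction 0.37 (11/30),
metachronous intervals uniform on 10-133 months, ages ~ N(63.9, 14.1).

One seeded generator drives the cohort; each patient uses a substream
derived from the cohort seed and a stable hash of the patient id, so adding
patients never perturbs earlier ones.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .calling import AMBIGUITY_OF
from .clinical import PairFeatures, TumorFeatures
from .errors import ConfigError
from .io import SampleRecord, write_cohort_fasta, write_clinical_table
from .reference import ReferenceGenome
from .variants import Variant


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters (see module docstring)."""

    n_cases: int = 30
    p_clonal: float = 0.23
    germline_count: float = 15.0  # Poisson mean of haplotype variants
    somatic_rate: float = 0.6  # Poisson mean of private somatic variants per tumor
    shared_extra_rate: float = 0.3  # shared count = 1 + Poisson(this) when retained
    p_shared_given_clonal: float = 1.0
    p_heteroplasmic: float = 0.9
    p_synchronous: float = 0.37
    p_stage3_clonal: float = 0.5  # clonal pairs: force a stage-3 primary
    p_discordant_independent: float = 0.7  # independent pairs: force a bil factor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ConfigError("n_cases must be >= 1")
        for name in ("p_clonal", "p_shared_given_clonal", "p_heteroplasmic",
                     "p_synchronous", "p_stage3_clonal", "p_discordant_independent"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0,1]")
        for name in ("germline_count", "somatic_rate", "shared_extra_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CaseTruth:
    """Ground truth for one simulated patient."""

    patient_id: str
    clonal: bool
    germline: frozenset[Variant]
    bc_private: frozenset[Variant]
    cbc_private: frozenset[Variant]
    shared: frozenset[Variant]

    def __post_init__(self) -> None:
        assert not self.shared or self.clonal


@dataclass(frozen=True)
class SyntheticCohort:
    samples: tuple[SampleRecord, ...]
    clinical_pairs: tuple[PairFeatures, ...]
    truths: tuple[CaseTruth, ...]


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(patient_id.encode())])
    )


def _mutate(sequence: list[str], variants, rng, p_het: float) -> list[str]:
    out = list(sequence)
    for v in variants:
        if p_het > 0 and rng.random() < p_het:
            out[v.position - 1] = AMBIGUITY_OF[frozenset((v.ref, v.alt))]
        else:
            out[v.position - 1] = v.alt
    return out


_IHC_MARGINS = (("Lum", 0.85), ("Lum-H", 0.08), ("Her2", 0.02), ("TN", 0.05))


def _draw_tumor(rng: np.random.Generator) -> TumorFeatures:
    histotype = "ILC" if rng.random() < 0.15 else "IC NST"
    grade = ("G1", "G2", "G3")[rng.choice(3, p=[0.2, 0.4, 0.4])]
    stage = int(rng.choice([1, 2, 3], p=[0.45, 0.35, 0.2]))
    in_situ = bool(rng.random() < 0.3)
    labels, probs = zip(*_IHC_MARGINS)
    ihc = labels[rng.choice(len(labels), p=probs)]
    return TumorFeatures(histotype, grade, stage, in_situ, ihc)


def _draw_clinical(
    rng: np.random.Generator, patient_id: str, clonal: bool, config: SimulationConfig
) -> PairFeatures:
    first = _draw_tumor(rng)
    second = _draw_tumor(rng)
    if clonal:
        # clonal pairs look alike and are enriched for stage-3 primaries
        second = TumorFeatures(first.histotype, second.grade, second.stage,
                               second.in_situ, first.ihc)
        if rng.random() < config.p_stage3_clonal:
            first = TumorFeatures(first.histotype, first.grade, 3,
                                  first.in_situ, first.ihc)
    elif rng.random() < config.p_discordant_independent:
        kind = rng.choice(3)
        if kind == 0:
            flipped = "ILC" if first.histotype == "IC NST" else "IC NST"
            second = TumorFeatures(flipped, second.grade, second.stage,
                                   second.in_situ, second.ihc)
        elif kind == 1:
            other = [c for c, _ in _IHC_MARGINS if c != first.ihc]
            second = TumorFeatures(second.histotype, second.grade, second.stage,
                                   second.in_situ, other[rng.choice(len(other))])
        else:
            second = TumorFeatures(second.histotype, second.grade, second.stage,
                                   True, second.ihc)
    if rng.random() < config.p_synchronous:
        interval = 0.0
    else:
        interval = float(rng.integers(10, 134))
    age = float(np.clip(round(rng.normal(63.9, 14.1)), 25, 95))
    return PairFeatures(patient_id, first, second, interval, age=age)


def generate_cohort(
    config: SimulationConfig, reference: ReferenceGenome
) -> SyntheticCohort:
    """Simulate N/BC/CBC sequences, clinical features and truth labels."""
    valid_positions = np.array(
        [i + 1 for i, b in enumerate(reference.sequence) if b in "ACGT"]
    )
    base_list = list(reference.sequence)
    samples: list[SampleRecord] = []
    pairs: list[PairFeatures] = []
    truths: list[CaseTruth] = []
    for i in range(1, config.n_cases + 1):
        pid = f"S{i}"
        rng = _patient_rng(config.seed, pid)
        clonal = bool(rng.random() < config.p_clonal)
        n_germline = int(rng.poisson(config.germline_count))
        n_bc = int(rng.poisson(config.somatic_rate))
        n_cbc = int(rng.poisson(config.somatic_rate))
        n_shared = 0
        if clonal and rng.random() < config.p_shared_given_clonal:
            n_shared = 1 + int(rng.poisson(config.shared_extra_rate))
        total = n_germline + n_bc + n_cbc + n_shared
        if total > len(valid_positions):
            raise ConfigError("variant rates exhaust the distinct reference positions")
        positions = rng.choice(valid_positions, size=total, replace=False)

        def make(positions_slice) -> frozenset[Variant]:
            out = set()
            for pos in positions_slice:
                ref_base = base_list[pos - 1]
                alts = [b for b in "ACGT" if b != ref_base]
                out.add(Variant(int(pos), ref_base, alts[rng.choice(3)]))
            return frozenset(out)

        germline = make(positions[:n_germline])
        k = n_germline
        bc_private = make(positions[k : k + n_bc]); k += n_bc
        cbc_private = make(positions[k : k + n_cbc]); k += n_cbc
        shared = make(positions[k : k + n_shared])

        germ_seq = _mutate(base_list, germline, rng, p_het=0.0)
        samples.append(SampleRecord(pid, "N", "".join(germ_seq)))
        samples.append(
            SampleRecord(
                pid, "BC",
                "".join(_mutate(germ_seq, bc_private | shared, rng,
                                config.p_heteroplasmic)),
            )
        )
        samples.append(
            SampleRecord(
                pid, "CBC",
                "".join(_mutate(germ_seq, cbc_private | shared, rng,
                                config.p_heteroplasmic)),
            )
        )
        pairs.append(_draw_clinical(rng, pid, clonal, config))
        truths.append(
            CaseTruth(pid, clonal, germline, bc_private, cbc_private, shared)
        )
    return SyntheticCohort(tuple(samples), tuple(pairs), tuple(truths))


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write cohort.fasta, clinical.csv and truth.tsv into a directory."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cohort_fasta(cohort.samples, outdir / "cohort.fasta")
    write_clinical_table(cohort.clinical_pairs, outdir / "clinical.csv")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("patient_id\tclonal\tgermline\tbc_private\tcbc_private\tshared\n")
        for t in cohort.truths:
            def labels(vs):
                return ",".join(v.label for v in sorted(vs)) or "-"
            fh.write(
                f"{t.patient_id}\t{int(t.clonal)}\t{labels(t.germline)}\t"
                f"{labels(t.bc_private)}\t{labels(t.cbc_private)}\t{labels(t.shared)}\n"
            )
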