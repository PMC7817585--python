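"""Alignment-based substitution calling and its positional-diff oracle."""
import numpy as np
import pytest

from mtclone.calling import (
    AMBIGUITY_OF,
    AlignmentScoring,
    align_to_reference,
    call_variants,
    diff_oracle,
    indel_events,
)
from mtclone.errors import InsufficientSequenceError, OracleInapplicableError
from mtclone.io import SampleRecord
from mtclone.variants import Variant


def _sample(reference, mutations: dict[int, str], patient="P1", tissue="BC"):
    seq = list(reference.sequence)
    for pos, base in mutations.items():
        seq[pos - 1] = base
    return SampleRecord(patient, tissue, "".join(seq))


def _implant(rng, reference, k, heteroplasmic_fraction=0.3):
    """Implant k substitutions at distinct non-N positions; return (sample, truth)."""
    valid = [i + 1 for i, b in enumerate(reference.sequence) if b in "ACGT"]
    positions = rng.choice(valid, size=k, replace=False)
    truth = set()
    mutations = {}
    for pos in positions:
        ref_base = reference.sequence[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref_base])
        het = bool(rng.random() < heteroplasmic_fraction)
        mutations[int(pos)] = AMBIGUITY_OF[frozenset((ref_base, alt))] if het else alt
        truth.add(Variant(int(pos), ref_base, alt, heteroplasmic=het))
    return _sample(reference, mutations), truth


class TestAlignment:
    def test_identical_sequences_align_without_mismatch(self, reference):
        aln = align_to_reference(_sample(reference, {}), reference)
        assert aln.sample_aligned == aln.reference_aligned

    def test_single_substitution_single_mismatch_column(self, reference):
        ref_base = reference.base(5000)
        alt = "A" if ref_base != "A" else "G"
        aln = align_to_reference(_sample(reference, {5000: alt}), reference)
        mismatches = sum(
            1 for s, r in zip(aln.sample_aligned, aln.reference_aligned) if s != r
        )
        assert mismatches == 1

    def test_three_base_deletion_yields_gap_not_substitutions(self, reference):
        seq = reference.sequence[:7999] + reference.sequence[8002:]
        sample = SampleRecord("P1", "BC", seq)
        # edit-distance engine: three deleted columns, zero substitution calls
        aln = align_to_reference(sample, reference)
        assert sum(e.length for e in indel_events(aln) if e.kind == "deletion") == 3
        assert call_variants(aln) == set()
        # affine-gap engine prefers one contiguous 3-column gap
        aln = align_to_reference(sample, reference, AlignmentScoring())
        events = indel_events(aln)
        assert len(events) == 1
        assert events[0].kind == "deletion" and events[0].length == 3
        assert call_variants(aln) == set()

    def test_too_short_sample_rejected(self, reference):
        with pytest.raises(InsufficientSequenceError):
            align_to_reference(
                SampleRecord("P1", "BC", reference.sequence[:5000]), reference
            )

    def test_affine_engine_agrees_on_substitutions(self, reference):
        # the configurable-scoring engine is exercised on a short window
        rng = np.random.default_rng(11)
        sample, truth = _implant(rng, reference, 5, heteroplasmic_fraction=0.0)
        short_ref = type(reference)("rCRS", reference.sequence)
        aln = align_to_reference(sample, short_ref, AlignmentScoring())
        assert call_variants(aln) == truth


class TestCallRules:
    def test_homoplasmic_and_heteroplasmic_calls(self, reference):
        ref_base = reference.base(11529)
        assert ref_base == "T"
        het_code = AMBIGUITY_OF[frozenset("GA")]  # R
        sample = _sample(reference, {11529: "C", 1982: het_code})
        calls = call_variants(align_to_reference(sample, reference))
        by_pos = {v.position: v for v in calls}
        assert by_pos[11529] == Variant(11529, "T", "C")
        assert not by_pos[11529].heteroplasmic
        assert by_pos[1982] == Variant(1982, "G", "A")
        assert by_pos[1982].heteroplasmic

    def test_n_and_uninterpretable_ambiguities_give_no_call(self, reference):
        # N, three-fold codes, and two-fold codes missing the reference base
        non_ref_pair = AMBIGUITY_OF[
            frozenset("ACGT".replace(reference.base(4200), "")[:2])
        ]
        sample = _sample(reference, {4000: "N", 4100: "B", 4200: non_ref_pair})
        calls = call_variants(align_to_reference(sample, reference))
        assert {v.position for v in calls}.isdisjoint({4000, 4100, 4200})

    def test_reference_placeholder_never_called(self, reference):
        # position 3107 is 'N' in the reference: sample bases there are ignored
        sample = _sample(reference, {3107: "A"})
        calls = call_variants(align_to_reference(sample, reference))
        assert not any(v.position == 3107 for v in calls)


class TestOracleEquivalence:
    def test_identity_pair_is_empty(self, reference):
        assert diff_oracle(reference.sequence, reference.sequence) == set()

    def test_two_fold_ambiguity_is_heteroplasmic_call(self):
        calls = diff_oracle("AYA", "ATA")
        assert calls == {Variant(2, "T", "C")}
        assert next(iter(calls)).heteroplasmic

    def test_unequal_lengths_rejected(self):
        with pytest.raises(OracleInapplicableError):
            diff_oracle("ACGT", "ACG")

    @pytest.mark.parametrize("seed", range(25))
    def test_aligner_calls_equal_positional_diff(self, reference, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(0, 25))
        sample, truth = _implant(rng, reference, k)
        aligned = call_variants(align_to_reference(sample, reference))
        assert aligned == diff_oracle(sample.sequence, reference.sequence)
        assert aligned == truth


class TestImplantRecover:
    @pytest.mark.parametrize("k", range(0, 21))
    def test_implanted_substitutions_recovered_exactly(self, reference, k):
        rng = np.random.default_rng(1000 + k)
        sample, truth = _implant(rng, reference, k)
        calls = call_variants(align_to_reference(sample, reference))
        assert calls == truth
        assert {v: v.heteroplasmic for v in calls} == {v: v.heteroplasmic for v in truth}

    def test_calls_invariant_to_fasta_line_wrapping(self, reference, tmp_path):
        from mtclone.io import read_cohort_fasta, write_cohort_fasta

        rng = np.random.default_rng(99)
        sample, truth = _implant(rng, reference, 8)
        results = []
        for width in (60, 70, 16569):
            path = tmp_path / f"w{width}.fasta"
            write_cohort_fasta([sample], path, width=width)
            (rec,) = read_cohort_fasta(path)
            results.append(call_variants(align_to_reference(rec, reference)))
        assert results[0] == results[1] == results[2] == truth
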