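"""Clinico-pathological rule engine: factors, precedence, full-cohort agreement."""
import pytest

from mtclone.clinical import (
    PairFeatures,
    TumorFeatures,
    classify_clinical,
    discordance_factors,
    ihc_class,
)


def _tumor(histotype="IC NST", grade="G2", stage=1, in_situ=False, ihc="Lum"):
    return TumorFeatures(histotype, grade, stage, in_situ, ihc)


def _pair(first, second, interval=0.0, pid="P"):
    return PairFeatures(pid, first, second, interval)


class TestIhcClass:
    @pytest.mark.parametrize(
        "er, pr, her2, expected",
        [
            (True, True, False, "Lum"),
            (True, False, False, "Lum"),
            (False, True, True, "Lum-H"),
            (True, True, True, "Lum-H"),
            (False, False, True, "Her2"),
            (False, False, False, "TN"),
        ],
    )
    def test_bioprofile(self, er, pr, her2, expected):
        assert ihc_class(er, pr, her2) == expected


class TestDiscordanceFactors:
    def test_histology_factor_for_lobular_vs_nst(self):
        pair = _pair(_tumor(), _tumor(histotype="ILC"), interval=133)
        factors, _ = discordance_factors(pair)
        assert factors == {"Histology"}

    def test_metachronous_stage3_primary_with_ihc_and_insitu(self):
        # first tumor stage 3 Lum-H; second stage 1 Lum with in-situ
        pair = _pair(
            _tumor(stage=3, ihc="Lum-H"),
            _tumor(in_situ=True),
            interval=73,
        )
        factors, stage3_primary = discordance_factors(pair)
        assert factors == {"Stage", "IHC", "InSitu"}
        assert stage3_primary

    def test_concordant_metachronous_pair_has_no_factors(self):
        pair = _pair(_tumor(stage=2, in_situ=True), _tumor(stage=2), interval=48)
        factors, _ = discordance_factors(pair)
        assert factors == set()

    def test_identical_synchronous_pair_has_no_factors(self):
        assert discordance_factors(_pair(_tumor(), _tumor()))[0] == set()

    def test_one_sided_in_situ_synchronous_is_not_a_factor(self):
        pair = _pair(_tumor(), _tumor(in_situ=True), interval=0)
        assert discordance_factors(pair)[0] == set()

    def test_both_sided_in_situ_synchronous_is_a_factor(self):
        pair = _pair(_tumor(in_situ=True), _tumor(in_situ=True), interval=0)
        assert discordance_factors(pair)[0] == {"InSitu"}

    def test_metachronous_second_tumor_stage3_is_not_a_factor(self):
        pair = _pair(_tumor(), _tumor(stage=3), interval=69)
        assert "Stage" not in discordance_factors(pair)[0]

    def test_grade_difference_is_never_a_factor(self):
        pair = _pair(_tumor(grade="G1"), _tumor(grade="G3"), interval=12)
        assert discordance_factors(pair)[0] == set()


class TestClassifyClinical:
    def test_stage3_primary_with_independence_factor_is_discordant(self):
        pair = _pair(_tumor(stage=3, ihc="Lum-H"), _tumor(in_situ=True), interval=0)
        assert classify_clinical(pair).call == "DisNI"

    def test_stage3_in_second_tumor_lets_independence_factors_win(self):
        pair = _pair(_tumor(in_situ=True), _tumor(histotype="ILC", stage=3), interval=0)
        assert classify_clinical(pair).call == "bilCBC"

    def test_stage_factor_alone_is_metastatic(self):
        pair = _pair(_tumor(), _tumor(stage=3, in_situ=True), interval=0)
        assert classify_clinical(pair).call == "metCBC"

    def test_no_factors_is_non_informative(self):
        assert classify_clinical(_pair(_tumor(), _tumor())).call == "NI"

    def test_adding_independence_factor_to_metastatic_never_stays_metastatic(self):
        base = _pair(_tumor(stage=3), _tumor(), interval=12)
        assert classify_clinical(base).call == "metCBC"
        with_bil = _pair(_tumor(stage=3), _tumor(histotype="ILC"), interval=12)
        assert classify_clinical(with_bil).call != "metCBC"


class TestFullCohortAgreement:
    def test_factors_and_calls_match_all_30_published_rows(self, cohort):
        expected = cohort.expected.set_index("patient_id")
        for pair in cohort.clinical_pairs:
            call = classify_clinical(pair)
            row = expected.loc[pair.patient_id]
            printed = row["printed_discordance"]
            printed_factors = set() if printed == "None" else set(printed.split("/"))
            assert call.factors == printed_factors, pair.patient_id
            assert call.call == row["printed_clinical_call"], pair.patient_id

    def test_published_verdict_totals(self, cohort):
        calls = [classify_clinical(p).call for p in cohort.clinical_pairs]
        assert calls.count("bilCBC") == 17
        assert calls.count("metCBC") == 6
        assert calls.count("NI") == 4
        assert calls.count("DisNI") == 3

    def test_synchronicity_split(self, cohort):
        sync = [p.synchronicity for p in cohort.clinical_pairs]
        assert sync.count("S") == 11 and sync.count("M") == 19
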