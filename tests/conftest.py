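import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def reference():
    from mtclone import load_reference

    return load_reference()


@pytest.fixture(scope="session")
def locus_map():
    from mtclone import load_locus_map

    return load_locus_map()


@pytest.fixture(scope="session")
def cohort():
    """The bundled 30-pair cohort fixture (variants, annotations, clinical)."""
    from mtclone import cohort_fixture

    return cohort_fixture()


@pytest.fixture(scope="session")
def cohort_report(cohort):
    """Full pipeline report on the bundled cohort (variant-table entry)."""
    from mtclone.pipeline import PipelineContext, _finish, profiles_from_calls

    ctx = PipelineContext(annotation_db=cohort.annotation_db)
    profiles = profiles_from_calls(cohort.variant_calls)
    return _finish(profiles, cohort.clinical_pairs, ctx)
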