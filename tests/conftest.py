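import pytest

from mirshift import datasets


@pytest.fixture(scope="session")
def cortical_profile():
    return datasets.cortical_profile()


@pytest.fixture(scope="session")
def cortical_families():
    return datasets.cortical_family_annotation()


@pytest.fixture(scope="session")
def dcx_lis1_sites():
    return datasets.cortical_dcx_lis1_sites()


@pytest.fixture(scope="session")
def cortical_records(cortical_profile, cortical_families):
    from mirshift.diffexp import classify_differential, restrict_to_conserved

    return restrict_to_conserved(
        classify_differential(cortical_profile), cortical_families
    )
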