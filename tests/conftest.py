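import pytest

from cyp21kit import load_locus_model, load_reference_cohort


@pytest.fixture(scope="session")
def model():
    return load_locus_model()


@pytest.fixture(scope="session")
def cohort():
    return load_reference_cohort()
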