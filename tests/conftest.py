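import pytest

from coastrisk import sample_io


@pytest.fixture(scope="session")
def registry():
    return sample_io.load_reference_registry()


@pytest.fixture(scope="session")
def metal_survey():
    """The packaged 18-sample coastal metal survey (mg/L)."""
    return sample_io.load_table1_metals()


@pytest.fixture(scope="session")
def pah_survey():
    """The packaged 8-site PAH survey with non-detects set to zero."""
    return sample_io.substitute_nondetects(sample_io.load_table2_pahs(), "zero")


@pytest.fixture(scope="session")
def toc_survey():
    return sample_io.load_table3_toc()
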