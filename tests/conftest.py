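import pytest

from mosaicdpcr import (
    ASSAYS,
    ChipSpec,
    packaged_cohort,
    reference_curves,
)


@pytest.fixture(scope="session")
def curves():
    """Packaged reference calibrator curves, keyed by target variant."""
    return reference_curves()


@pytest.fixture(scope="session")
def cohort_records():
    """The packaged 79-sample cohort transcription."""
    return packaged_cohort()


@pytest.fixture(scope="session")
def assay_604():
    return ASSAYS["c.604C>T"]


@pytest.fixture(scope="session")
def assay_605():
    return ASSAYS["c.605G>A"]


@pytest.fixture(scope="session")
def default_spec():
    return ChipSpec()
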