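import pytest

from gmunit import (
    bundled_gmfm_ratings,
    bundled_reference_table,
    default_anchors,
    published_equation,
)


@pytest.fixture(scope="session")
def gmfm_table():
    return bundled_gmfm_ratings()


@pytest.fixture(scope="session")
def reference_rows():
    return bundled_reference_table()


@pytest.fixture(scope="session")
def equation():
    return published_equation()


@pytest.fixture(scope="session")
def anchors():
    return default_anchors()
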