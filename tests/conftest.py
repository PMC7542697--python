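import pytest

from igkit.fixtures import make_germline_fixture


@pytest.fixture(scope="session")
def fixture_set():
    """One shared synthetic reference set (germline + constants + primers)."""
    return make_germline_fixture(seed=1)
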