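import pytest

from spgcea import default_params


@pytest.fixture(scope="session")
def base_params():
    return default_params()
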