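import pytest

from carotidwk import load_atlas


@pytest.fixture(scope="session")
def atlas():
    return load_atlas("as-published")


@pytest.fixture(scope="session")
def evaluated(atlas):
    return atlas.evaluate()
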