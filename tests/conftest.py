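import pytest
from hypothesis import settings

from ylinkage import RPROC1_LIBRARIES

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture
def catalog():
    """The sex-separated library catalog of the RproC1 assembly."""
    return RPROC1_LIBRARIES


@pytest.fixture
def write_tsv(tmp_path):
    def _write(name, lines):
        p = tmp_path / name
        p.write_text("".join(line + "\n" for line in lines))
        return p

    return _write
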