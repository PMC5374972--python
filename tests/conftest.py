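import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def pdb_writer(tmp_path):
    """Write raw PDB text to a temp file and return its path."""

    def _write(text, name="test.pdb"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
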