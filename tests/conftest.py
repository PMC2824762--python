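import numpy as np
import pytest

from clampdna.synthetic_data import SyntheticClampSpec, make_synthetic_clamp


@pytest.fixture(scope="session")
def ring3():
    """An exactly C3-symmetric synthetic clamp, axis +z."""
    return make_synthetic_clamp(SyntheticClampSpec(n_fold=3, seed=4))


@pytest.fixture(scope="session")
def ring6():
    """An exactly C6-symmetric synthetic clamp."""
    return make_synthetic_clamp(SyntheticClampSpec(n_fold=6, seed=9))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


MINIMAL_PDB = (
    "ATOM      1  CA  GLY A   1      11.104   6.134  -6.504  1.00  0.00"
    "           C\n"
    "END\n"
)


@pytest.fixture()
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p
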