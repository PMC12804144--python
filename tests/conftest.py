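import numpy as np
import pytest

from epidyn.synthetic_data import ToyComplexSpec, make_toy_complex

PDB_ONE_ATOM = (
    "ATOM      1  N   GLY A   1      11.000  22.000  33.000  1.00 20.00           N\n"
    "END\n"
)

PDB_SMALL = """\
ATOM      1  N   GLY A   1      11.000  22.000  33.000  1.00 20.00           N
ATOM      2  CA  GLY A   1      12.400  22.000  33.000  1.00 20.00           C
ATOM      3  N   ALA A   2      14.000  23.000  33.500  1.00 20.00           N
ATOM      4  CA  ALA A   2      15.400  23.000  33.500  1.00 20.00           C
HETATM    5  C1  MYR C   0       1.000   2.000   3.000  1.00 20.00           C
END
"""


@pytest.fixture(scope="session")
def toy_pair():
    """Exposed/buried toy groove-ligand complexes (seed 7) with their ASAs."""
    spec = ToyComplexSpec(seed=7)
    exposed, asa_e = make_toy_complex(spec, "exposed")
    buried, asa_b = make_toy_complex(spec, "buried")
    return exposed, asa_e, buried, asa_b


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
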