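import numpy as np
import pytest

from surfppi.structures_io import Atom, AtomCloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_carbon():
    return AtomCloud([Atom("C", "CA", "ALA", 1, "A", (0.0, 0.0, 0.0))])


TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  O   ALA A   1       2.400   1.100   0.000  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ASER A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA BSER A   1       1.500   0.000   0.000  0.40  0.00           C
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


def random_cloud(rng, n=20, scale=5.0):
    elements = rng.choice(["C", "N", "O", "S"], size=n)
    pos = rng.normal(scale=scale, size=(n, 3))
    atoms = [
        Atom(str(elements[i]), str(elements[i]), "ALA", i + 1, "A", tuple(pos[i]))
        for i in range(n)
    ]
    return AtomCloud(atoms)
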