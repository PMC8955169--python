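import numpy as np
import pytest

from bonefiber.structure import Structure
from bonefiber.cell_geometry import TriclinicCell
from bonefiber.synthetic import ToyFibrilSpec, make_toy_fibril

WATER_PDB = """\
CRYST1   10.000   10.000   10.000  90.00  90.00  90.00 P 1           1
ATOM      1  OH2 TIP3A   1       0.000   0.000   0.000  1.00  0.00           O
ATOM      2  H1  TIP3A   1       0.957   0.000   0.000  1.00  0.00           H
ATOM      3  H2  TIP3A   1      -0.240   0.927   0.000  1.00  0.00           H
CONECT    1    2    3
END
"""

#: triclinic cell of the collagen fibril crystal (rat tail tendon, 1 D-period)
FIBRIL_CELL = TriclinicCell(39.970, 26.950, 677.900, 89.24, 94.59, 105.58)


@pytest.fixture
def water_pdb(tmp_path):
    p = tmp_path / "water.pdb"
    p.write_text(WATER_PDB)
    return p


@pytest.fixture
def water_structure():
    return Structure(
        np.array([[0.0, 0.0, 0.0], [0.957, 0.0, 0.0], [-0.240, 0.927, 0.0]]),
        ["O", "H", "H"],
        names=["OH2", "H1", "H2"],
        residue_names=["TIP3"] * 3,
        bonds=np.array([[0, 1], [0, 2]]),
        cell=TriclinicCell.cubic(10.0),
    )


@pytest.fixture(scope="session")
def toy_fibril():
    """Default toy fibril crystal with its construction ground truth."""
    return make_toy_fibril(ToyFibrilSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
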