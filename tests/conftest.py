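import numpy as np
import pytest

from qnsmech.structures import Atom, Residue, Structure
from qnsmech.synthetic import make_toy_receptor

THREE_RESIDUE_PDB = """\
CRYST1   10.000   10.000   10.000  90.00  90.00  90.00 P 1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.460   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.020   1.370   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1       3.240   1.490   0.000  1.00 10.00           O
ATOM      5  CB  ALA A   1       1.950  -0.770   1.210  1.00 10.00           C
ATOM      6  N   SER A   2       1.230   2.420   0.000  1.00 11.00           N
ATOM      7  CA  SER A   2       1.690   3.800   0.000  1.00 11.00           C
ATOM      8  C   SER A   2       0.520   4.770   0.100  1.00 11.00           C
ATOM      9  O   SER A   2      -0.650   4.380   0.100  1.00 11.00           O
ATOM     10  CB  SER A   2       2.560   4.090   1.230  1.00 11.00           C
ATOM     11  OG  SER A   2       3.250   5.320   1.100  1.00 11.00           O
ATOM     12  N   GLY A   3       0.830   6.060   0.200  1.00 12.00           N
ATOM     13  CA  GLY A   3      -0.170   7.110   0.300  1.00 12.00           C
ATOM     14  C   GLY A   3       0.420   8.490   0.300  1.00 12.00           C
ATOM     15  O   GLY A   3       1.640   8.650   0.300  1.00 12.00           O
TER
HETATM   16  O   HOH A 101       6.000   6.000   6.000  1.00 20.00           O
HETATM   17  O   HOH A 102       7.000   7.000   7.000  1.00 20.00           O
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


@pytest.fixture(scope="session")
def toy_receptor():
    return make_toy_receptor(n_residues=40, seed=7)


def single_atom_structure(element="C", name="C1", pos=(0.0, 0.0, 0.0)):
    res = Residue("A", 1, "UNK", [Atom(1, name, element, np.array(pos))])
    return Structure(chains={"A": [res]})
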