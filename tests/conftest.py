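import numpy as np
import pytest

from torsiongrid.binning import make_scheme
from torsiongrid.geometry import compute_angles
from torsiongrid.synthetic import build_fragment


@pytest.fixture(scope="session")
def scheme5():
    return make_scheme(5.0)


@pytest.fixture(scope="session")
def helix_chain():
    return build_fragment("H" * 12, seed=1)


@pytest.fixture(scope="session")
def mixed_chain():
    """A 60-residue mixed-topology fragment."""
    return build_fragment("H" * 20 + "E" * 10 + "C" * 10 + "H" * 20, seed=5)


@pytest.fixture(scope="session")
def mixed_angles(mixed_chain):
    return compute_angles(mixed_chain)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


TOY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.674   6.719  -4.163  1.00  0.00           C
ATOM      4  N   GLY A   2       9.580   6.021  -3.872  1.00  0.00           N
ATOM      5  CA  GLY A   2       8.580   6.496  -2.926  1.00  0.00           C
ATOM      6  C   GLY A   2       7.223   6.680  -3.593  1.00  0.00           C
ATOM      7  N   SER A   3       6.394   5.639  -3.555  1.00  0.00           N
ATOM      8  CA  SER A   3       5.053   5.690  -4.131  1.00  0.00           C
ATOM      9  C   SER A   3       4.238   6.808  -3.496  1.00  0.00           C
TER
END
"""


@pytest.fixture(scope="session")
def toy_pdb_text():
    return TOY_PDB


PSSM_FIXTURE = """
Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts
             A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V   A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V
    1 M     -2  -3  -4  -5  -3  -2  -4  -5  -3   1   2  -3   8  -1  -4  -3  -2  -3  -2   0    0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.50 0.10
    2 K     -1   2   0  -1  -4   1   1  -2  -1  -3  -3   5  -2  -4  -2   0  -1  -4  -2  -3    0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.40 0.12
    3 V      0  -3  -4  -4  -1  -3  -3  -4  -4   3   1  -3   1  -1  -3  -2   0  -4  -2   4    0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.55 0.15
    4 L     -2  -3  -4  -5  -2  -3  -4  -5  -4   2   5  -3   2   0  -4  -3  -2  -3  -2   1    0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.60 0.14
    5 A      5  -2  -2  -2  -1  -1  -1   0  -2  -2  -2  -1  -2  -3  -1   1   0  -3  -2  -1    0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.45 0.11

                      K         Lambda
Standard Ungapped    0.1330     0.3180
"""


@pytest.fixture(scope="session")
def pssm_text():
    return PSSM_FIXTURE
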