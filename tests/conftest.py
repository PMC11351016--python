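import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from toplap.synthdata import SynthConfig, make_toy_complex


@pytest.fixture(scope="session")
def toy_complex():
    """Deterministic two-chain poly-alanine complex (20 residues/chain)."""
    return make_toy_complex(SynthConfig(seed=1), complex_id="TOY1")


@pytest.fixture(scope="session")
def big_complex():
    """Larger complex with a 13-residue flexible segment per chain."""
    return make_toy_complex(
        SynthConfig(n_residues=50, flex_span=(20, 33), seed=3), complex_id="TOY3"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240808)


ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 20.00           N
ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.60 20.00           C
ATOM      3  CA BALA A   1       1.400   0.200   0.000  0.40 20.00           C
ATOM      4  C   ALA A   1       2.009   1.420   0.000  1.00 20.00           C
ATOM      5  O   ALA A   1       1.251   2.390   0.000  1.00 20.00           O
ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00 20.00           N
ATOM      7  CA  GLY A   2       3.988   2.839   0.000  1.00 20.00           C
ATOM      8  C   GLY A   2       5.504   2.693   0.000  1.00 20.00           C
ATOM      9  O   GLY A   2       6.030   1.580   0.000  1.00 20.00           O
TER      10      GLY A   2
ATOM     11  N   SER B   5      10.000   0.000   0.000  1.00 30.00           N
ATOM     12  CA  SER B   5      11.458   0.000   0.000  1.00 30.00           C
ATOM     13  C   SER B   5      12.009   1.420   0.000  1.00 30.00           C
ATOM     14  O   SER B   5      11.251   2.390   0.000  1.00 30.00           O
ATOM     15  OG  SER B   5      12.100  -1.200   0.000  1.00 30.00           O
HETATM   16  O   HOH B 101      20.000  20.000  20.000  1.00 40.00           O
TER      17      SER B   5
END
"""


@pytest.fixture()
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p
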