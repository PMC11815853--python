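import numpy as np
import pytest

from nmdn.synthetic_fixtures import gen_complex, make_class_mixtures


def random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix via QR decomposition."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_complex():
    return gen_complex(n_residues=8, n_lig_atoms=5, n_metals=1, seed=42)


@pytest.fixture(scope="session")
def class_mixtures():
    return make_class_mixtures(aa_codes=("A", "G"), elements=("C", "O"), seed=7)


TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      5  CB AALA A   1       1.958  -0.760   1.220  0.70 10.00           C
ATOM      6  CB BALA A   1       1.958  -0.760  -1.220  0.30 10.00           C
ATOM      7  N   GLY A   2       3.332   1.536   0.000  1.00 10.00           N
ATOM      8  CA  GLY A   2       3.985   2.831   0.000  1.00 10.00           C
ATOM      9  C   GLY A   2       5.498   2.705   0.000  1.00 10.00           C
ATOM     10  O   GLY A   2       6.062   1.610   0.000  1.00 10.00           O
HETATM   11 ZN    ZN A 101       4.000   5.000   1.000  1.00 10.00          ZN
HETATM   12  O   HOH A 201       8.000   8.000   8.000  1.00 10.00           O
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path
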