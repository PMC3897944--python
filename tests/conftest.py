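import numpy as np
import pytest

import ligpatmine as lp
from ligpatmine import fixtures as fx

#: handwritten minimal PDB: one ALA (5 heavy atoms), one HETATM ligand atom,
#: three waters, and an altloc pair on CB (A occ 0.6, B occ 0.4)
TOY_PDB = """\
HEADER    TEST COMPLEX                                        TOY1
EXPDTA    X-RAY DIFFRACTION
REMARK   2 RESOLUTION.    2.10 ANGSTROMS.
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      12.684   7.181  -4.993  1.00 10.00           C
ATOM      4  O   ALA A   1      13.603   7.285  -5.793  1.00 10.00           O
ATOM      5  CB AALA A   1      12.256   4.700  -4.897  0.60 10.00           C
ATOM      6  CB BALA A   1      12.256   4.800  -4.897  0.40 10.00           C
HETATM    7  C1  LIG A 101       9.000   5.000  -6.000  1.00 10.00           C
HETATM    8  O   HOH A 201       5.000   5.000   5.000  1.00 10.00           O
HETATM    9  O   HOH A 202       6.000   5.000   5.000  1.00 10.00           O
HETATM   10  O   HOH A 203       7.000   5.000   5.000  1.00 10.00           O
END
"""


@pytest.fixture
def toy_pdb_path(tmp_path):
    path = tmp_path / "toy1.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture
def radii():
    return lp.VdwRadiusTable()


@pytest.fixture(scope="session")
def planted():
    """Small planted-mixture dataset shared by mining-dependent tests."""
    return fx.end_to_end_fixture(seed=11, n_complexes=15, atoms_per_complex=8)


@pytest.fixture(scope="session")
def mined(planted):
    cfg = lp.EngineConfig(k_max=3, restarts=2, seed=11)
    return lp.mine_patterns(
        [(st, st.ligands[0]) for st in planted.complexes], cfg)


def random_fragment(rng) -> lp.Fragment:
    """A geometrically valid random fragment (non-collinear atoms)."""
    while True:
        pts = rng.uniform(-10, 10, size=(3, 3))
        if 0.5 * np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0])) > 0.1:
            break
    atoms = tuple(
        lp.AtomRecord(serial=i + 1, name=n, element=n[0], residue_name="ALA",
                      residue_id=("A", 1, ""), coordinates=p)
        for i, (n, p) in enumerate(zip(("N", "CA", "CB"), pts))
    )
    return lp.Fragment(atoms=atoms, type_label="ALA:N-CA-CB")
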