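import numpy as np
import pytest

from wetbind import synthetic


@pytest.fixture(scope="session")
def toy_complex():
    """Small receptor-ligand complex with recorded force field (seed 7)."""
    return synthetic.gen_toy_complex(3, seed=7, n_frames=40)


@pytest.fixture(scope="session")
def small_water_box():
    """64-water MC box, enough snapshots for energy sanity checks."""
    return synthetic.gen_water_box(n_waters=64, density=0.997,
                                   temperature=300.0, n_snapshots=30, seed=2)


@pytest.fixture(scope="session")
def tethered_pair():
    """Two tethered sites: one ordered (kappa=20), one orientation-free."""
    sites = [
        synthetic.TetheredSiteSpec(center=(0.0, 0.0, 0.0),
                                   translational_sigma=0.3,
                                   orientational_concentration=20.0,
                                   occupancy_prob=1.0),
        synthetic.TetheredSiteSpec(center=(8.0, 0.0, 0.0),
                                   translational_sigma=0.45,
                                   orientational_concentration=0.0,
                                   occupancy_prob=0.5),
    ]
    return synthetic.gen_tethered_waters(sites, n_frames=2000, seed=3)


PDB_FIXTURE = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CB  ALA A   1      12.919   6.898  -5.041  1.00  0.00           C
HETATM    4  O   HOH W   2       2.000   3.000   4.000  1.00  0.00           O
HETATM    5  H1  HOH W   2       2.500   3.500   4.200  1.00  0.00           H
HETATM    6  H2  HOH W   2       1.500   3.400   4.300  1.00  0.00           H
HETATM    7  O   HOH W   3       8.000   1.000   2.000  1.00  0.00           O
HETATM    8  H1  HOH W   3       8.500   1.500   2.200  1.00  0.00           H
HETATM    9  H2  HOH W   3       7.500   1.400   2.300  1.00  0.00           H
END
"""


@pytest.fixture()
def pdb_text():
    return PDB_FIXTURE
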