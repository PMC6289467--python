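import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seqgnm.elastic import structure_gnm
from seqgnm.synthetic import make_chain

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# A small, well-formed Cα-only PDB: 3 residues of chain A with B-factors
# 10/20/30, one HETATM that must be ignored, and one chain B residue pair.
PDB_TEXT = """\
HEADER    TEST PROTEIN
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00 20.00           C
ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00 30.00           C
HETATM    4  O   HOH A 101       9.000   9.000   9.000  1.00  5.00           O
ATOM      5  CA  LEU B  10      20.000   0.000   0.000  1.00 40.00           C
ATOM      6  CA  LYS B  11      23.800   0.000   0.000  1.00 50.00           C
TER
END
"""

# Residue 2 has alternate-location Cα records A and B; the first must win.
PDB_ALTLOC = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C
ATOM      2  CA AGLY A   2       3.800   0.000   0.000  0.50 20.00           C
ATOM      3  CA BGLY A   2       3.900   0.100   0.000  0.50 21.00           C
ATOM      4  CA  SER A   3       7.600   0.000   0.000  1.00 30.00           C
END
"""


@pytest.fixture(scope="session")
def pdb_text():
    return PDB_TEXT


@pytest.fixture(scope="session")
def pdb_altloc():
    return PDB_ALTLOC


@pytest.fixture(scope="session")
def walk_chain():
    """One compact self-avoiding-walk chain shared across tests."""
    return make_chain(100, fold="compact_walk", seed=3)


@pytest.fixture(scope="session")
def walk_profile(walk_chain):
    return structure_gnm(walk_chain)


@pytest.fixture(scope="session")
def helix_chain():
    return make_chain(60, fold="helix", seed=1)


def random_connected_laplacian(n, rng):
    """Seeded random connected weighted graph Laplacian (test fixture)."""
    while True:
        adj = rng.random((n, n)) < 0.2
        adj = np.triu(adj, 1)
        w = np.where(adj, rng.uniform(0.1, 2.0, size=(n, n)), 0.0)
        w = w + w.T
        lap = np.diag(w.sum(axis=1)) - w
        # connectivity check via spanning reachability
        from scipy.sparse.csgraph import connected_components

        if connected_components(w > 0, directed=False)[0] == 1:
            return lap
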