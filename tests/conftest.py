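import numpy as np
import pytest

from icpca import MolecularGraph, cholesterol_fixture


@pytest.fixture(scope="session")
def cholesterol():
    return cholesterol_fixture()


@pytest.fixture
def butane():
    """All-atom n-butane: C0-C1-C2-C3 with 3+2+2+3 hydrogens."""
    elements = ["C"] * 4 + ["H"] * 10
    bonds = [(0, 1), (1, 2), (2, 3)]
    h = 4
    for carbon, nh in ((0, 3), (1, 2), (2, 2), (3, 3)):
        for _ in range(nh):
            bonds.append((carbon, h))
            h += 1
    return MolecularGraph(elements, bonds)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_connected_graph(rng, n_atoms, extra_edges=0):
    """Random tree plus optional extra edges; elements all carbon."""
    bonds = [(int(rng.integers(0, i)), i) for i in range(1, n_atoms)]
    existing = {tuple(sorted(b)) for b in bonds}
    tries = 0
    while extra_edges > 0 and tries < 200:
        a, b = rng.integers(0, n_atoms, size=2)
        key = (min(int(a), int(b)), max(int(a), int(b)))
        tries += 1
        if a != b and key not in existing:
            existing.add(key)
            bonds.append(key)
            extra_edges -= 1
    return MolecularGraph(["C"] * n_atoms, bonds)
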