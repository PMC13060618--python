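import warnings

import numpy as np
import pytest

from taamkit.atom_typing import assign_atom_types, build_bond_graph
from taamkit.bank import make_fixture_bank
from taamkit.fixtures import FixtureRecipe, make_structure


@pytest.fixture(scope="session")
def bank():
    return make_fixture_bank(0)


@pytest.fixture(scope="session")
def structures():
    """All fixture recipes at seed 0, built once."""
    names = ("methane", "water", "water-no-h", "benzene", "pentane",
             "decalin", "peptide", "random-P1", "triclinic-mixed",
             "chiral-P21", "altloc-overlap", "clash")
    return {name: make_structure(FixtureRecipe(name, 0)) for name in names}


def typed(structure, bank):
    """Bond graph + assignment with fixture clash warnings silenced."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        graph = build_bond_graph(structure)
        assignment = assign_atom_types(structure, graph, bank)
    return graph, assignment


@pytest.fixture(scope="session")
def typed_methane(structures, bank):
    return typed(structures["methane"], bank)


@pytest.fixture(scope="session")
def typed_triclinic(structures, bank):
    return typed(structures["triclinic-mixed"], bank)


def random_rotation(rng):
    a = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(a)
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
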