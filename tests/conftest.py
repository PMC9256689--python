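import numpy as np
import pytest

from cgdamage.cgbuild import BeadArray, build_cg_model
from cgdamage.fixtures import build_bdna, nucleotide_template, element_of
from cgdamage.potential import load_bond_params


class TemplateAtom:
    """Minimal atom wrapper around the nucleotide template coordinates."""

    def __init__(self, name, position):
        self.name = name
        self.element = element_of(name)
        self.position = np.asarray(position, dtype=float)


@pytest.fixture(scope="session")
def bond_params():
    return load_bond_params()


@pytest.fixture(scope="session")
def template():
    return nucleotide_template()


@pytest.fixture(scope="session")
def template_atoms(template):
    return {name: TemplateAtom(name, pos) for name, pos in template.items()}


@pytest.fixture(scope="session")
def small_linear_model():
    return build_bdna(10, "linear", "straight", rng_seed=1)


@pytest.fixture(scope="session")
def small_cg_beads(small_linear_model):
    return build_cg_model(small_linear_model)


@pytest.fixture(scope="session")
def small_bead_array(small_cg_beads):
    return BeadArray.from_beads(small_cg_beads)
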