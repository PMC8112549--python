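import numpy as np
import pytest

from mgforge.structio import DomainSpec, Selection
from mgforge.synthfix import (
    make_duplex,
    make_octahedral_site,
    make_toy_ternary_templates,
    make_two_metal_site,
    octahedral_site_definition,
    two_metal_site_definition,
)


@pytest.fixture(scope="session")
def oct_site():
    """Ideal one-metal octahedral site (no noise) with its manifest."""
    return make_octahedral_site(seed=0)


@pytest.fixture(scope="session")
def oct_site_def():
    return octahedral_site_definition()


@pytest.fixture(scope="session")
def two_metal():
    """Ideal two-metal site (seed 7) with its manifest."""
    return make_two_metal_site(seed=7)


@pytest.fixture(scope="session")
def two_metal_def():
    return two_metal_site_definition()


@pytest.fixture(scope="session")
def toy_templates():
    """(templates dict, designed reference chimera, manifest)."""
    return make_toy_ternary_templates(seed=0)


@pytest.fixture(scope="session")
def duplex10():
    return make_duplex(10)


@pytest.fixture
def duplex_domain():
    return DomainSpec("duplex", (("D", 1, 10), ("E", 1, 10)))


@pytest.fixture
def keep_nucleic_and_ions():
    return Selection.mol_class("nucleic") | Selection.element("MG")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
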