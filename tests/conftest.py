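import numpy as np
import pytest

from kinemorph import ForceFieldParams, build_peptide, helix_extended_pair


@pytest.fixture(scope="session")
def forcefield():
    return ForceFieldParams()


@pytest.fixture()
def tripeptide():
    """Small mixed chain with one chi1-bearing residue."""
    return build_peptide("LAG", -70.0, -35.0)


@pytest.fixture()
def pentapeptide():
    return build_peptide("LKVAG", -70.0, -35.0)


@pytest.fixture()
def helix10():
    return helix_extended_pair()[0]


@pytest.fixture()
def morph_pair():
    """Strained helix and relaxed extended chain of the same 10-mer."""
    return helix_extended_pair()


@pytest.fixture()
def rng():
    return np.random.default_rng(20140612)
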