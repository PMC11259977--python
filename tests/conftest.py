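import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from wgdchronos import synthetic as syn
from wgdchronos import treeio as tio


@pytest.fixture(scope="session")
def design():
    """Default 12-taxon / 30-locus study design."""
    return syn.default_design()


@pytest.fixture(scope="session")
def duplicated_tree(design):
    """18-leaf duplicated topology with default calibrations attached."""
    return design.duplicated_tree()


@pytest.fixture(scope="session")
def chronogram(design):
    """One seeded chronogram drawn from the study's age prior."""
    return syn.simulate_chronogram(design, seed_or_rng=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_aged_tree():
    """4-leaf ultrametric tree with assigned ages (100-Myr units)."""
    t = tio.parse_newick("((A:1,B:1)AB:1,(C:1.5,D:1.5)CD:0.5)R;")
    t.set_ages_from_edge_lengths()
    return t
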