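import warnings

import numpy as np
import pytest

from upna_ppi import Interactome, make_fixture, sample_tppni

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture()
def c4():
    """4-cycle 1-2-3-4-1."""
    return Interactome.from_edges([("1", "2"), ("2", "3"), ("3", "4"), ("4", "1")])


@pytest.fixture()
def path4():
    """Path graph 1-2-3-4."""
    return Interactome.from_edges([("1", "2"), ("2", "3"), ("3", "4")])


@pytest.fixture()
def k4():
    nodes = "abcd"
    return Interactome.from_edges(
        [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]])


@pytest.fixture(scope="session")
def fixture0():
    """Default planted-complementarity fixture, seed 0 (shared, read-only)."""
    return make_fixture(0)


@pytest.fixture(scope="session")
def tppni0(fixture0):
    return sample_tppni(fixture0.graph)


@pytest.fixture(scope="session")
def trained0(fixture0, tppni0):
    """One trained inductive experiment on the shared fixture (seed 0)."""
    from upna_ppi.experiments import inductive_experiment

    return inductive_experiment(0, fixture=fixture0, tppni=tppni0)
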