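import numpy as np
import pytest

from oncodag import FitnessLandscape, GenParams
from oncodag.restrictions import ROOT, from_edges
from oncodag.synthetic import fig1_fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fixtures():
    return fig1_fixtures()


@pytest.fixture(scope="session")
def chain_pair(fixtures):
    """5-gene DAG with a direct dependency (A->B) and a chain (F->G->H)."""
    return fixtures["chain"]


@pytest.fixture(scope="session")
def conjunction_pair(fixtures):
    """4-gene DAG where D requires both A and B."""
    return fixtures["conjunction"]


@pytest.fixture
def additive_landscape():
    """3-locus landscape with exactly additive, strictly positive effects."""
    s = np.array([0.2, 0.3, 0.5])
    fit = np.array(
        [1.0 + sum(s[k] for k in range(3) if g >> k & 1) for g in range(8)]
    )
    return FitnessLandscape(("A", "B", "C"), fit)


def two_locus_square(f00, f10, f01, f11):
    return FitnessLandscape(("A", "B"), np.array([f00, f10, f01, f11]))
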