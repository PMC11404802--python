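import numpy as np
import pytest

from cliquebars import WeightedNetwork


def make_network(edges, n=None, subject_id="net"):
    """Complete or partial network from {(i, j): weight}."""
    nodes = max(max(i, j) for i, j in edges) + 1
    n = n or nodes
    return WeightedNetwork.from_edges(n, edges, subject_id=subject_id)


@pytest.fixture
def k3_distinct():
    """Triangle with weights .9, .8, .7 (complete, all distinct)."""
    w = np.array([[0, 0.9, 0.8], [0.9, 0, 0.7], [0.8, 0.7, 0]])
    return WeightedNetwork(w, subject_id="k3")


@pytest.fixture
def k3_tied():
    """Triangle with all weights equal (full tie)."""
    w = np.full((3, 3), 0.5)
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(w, subject_id="k3tied")


@pytest.fixture
def chorded_cycle():
    """4-cycle (0,1)=.9 (1,2)=.8 (2,3)=.7 (3,0)=.6 with chords
    (0,2)=.5 (1,3)=.4 — the worked example whose single 1-dimensional
    hole lives over [4/6, 5/6)."""
    w = np.zeros((4, 4))
    for i, j, v in [(0, 1, 0.9), (1, 2, 0.8), (2, 3, 0.7),
                    (3, 0, 0.6), (0, 2, 0.5), (1, 3, 0.4)]:
        w[i, j] = w[j, i] = v
    return WeightedNetwork(w, subject_id="chord4")


@pytest.fixture
def rng():
    return np.random.default_rng(20240916)
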