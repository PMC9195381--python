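import numpy as np
import pytest

from grsr.network import IncidenceMatrix


def random_incidence(rng: np.random.Generator,
                     max_hosts: int = 10, max_clusters: int = 8) -> IncidenceMatrix:
    """Random binary incidence matrix with no empty rows/columns."""
    while True:
        I = rng.integers(2, max_hosts + 1)
        J = rng.integers(2, max_clusters + 1)
        a = (rng.random((I, J)) < rng.uniform(0.2, 0.8)).astype(np.int8)
        if a.sum(axis=1).all() and a.sum(axis=0).all():
            return IncidenceMatrix(
                tuple(f"h{i}" for i in range(I)),
                tuple(f"v{j}" for j in range(J)),
                a,
            )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_matrix():
    """4 hosts x 4 clusters; cluster v3 is a doubleton, v0-v2 have degree 3."""
    a = np.array([
        [1, 1, 0, 1],
        [1, 0, 1, 1],
        [1, 1, 1, 0],
        [0, 1, 1, 0],
    ], dtype=np.int8)
    return IncidenceMatrix(("h0", "h1", "h2", "h3"),
                           ("v0", "v1", "v2", "v3"), a)


@pytest.fixture
def complete_uniform():
    """Complete 4 hosts x 3 clusters network: the extreme-generalist case."""
    return IncidenceMatrix(
        ("h0", "h1", "h2", "h3"), ("v0", "v1", "v2"),
        np.ones((4, 3), dtype=np.int8),
    )


@pytest.fixture
def specialist_matrix():
    """Host h_spec exclusively linked to cluster v_rare (used by nobody else),
    embedded among 4 hosts sharing 3 common clusters."""
    ids = ("h_spec", "h1", "h2", "h3", "h4")
    clusters = ("v_rare", "c1", "c2", "c3")
    a = np.array([
        [1, 0, 0, 0],
        [0, 1, 1, 1],
        [0, 1, 1, 1],
        [0, 1, 1, 1],
        [0, 1, 1, 1],
    ], dtype=np.int8)
    return IncidenceMatrix(ids, clusters, a)
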