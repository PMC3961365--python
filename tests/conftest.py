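import numpy as np
import pytest

from seednet.network import InteractionNetwork
from seednet.ontology import OntologyDag


@pytest.fixture
def triangle():
    return InteractionNetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path_abc():
    return InteractionNetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def diamond_dag():
    """root <- A, root <- B, A <- C, B <- C (two parent paths into C)."""
    return OntologyDag(
        {
            "root": [],
            "A": [("root", "is_a")],
            "B": [("root", "is_a")],
            "C": [("A", "is_a"), ("B", "is_a")],
        }
    )


@pytest.fixture
def annotated_dag():
    """Small two-branch DAG with protein annotations on the leaves.

        root <- mid1 <- leaf1, leaf2 (leaf2 also part_of mid2)
        root <- mid2 <- leaf3
    """
    parents = {
        "root": [],
        "mid1": [("root", "is_a")],
        "mid2": [("root", "is_a")],
        "leaf1": [("mid1", "is_a")],
        "leaf2": [("mid1", "is_a"), ("mid2", "part_of")],
        "leaf3": [("mid2", "is_a")],
    }
    annotations = {
        "p1": {"leaf1"},
        "p2": {"leaf1", "leaf2"},
        "p3": {"leaf3"},
        "p4": {"mid2"},
        "p5": {"leaf2"},
    }
    return OntologyDag(parents, annotations=annotations)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def two_cluster_similarity(
    n_per_cluster: int = 30,
    p_in: float = 0.25,
    mixing: float = 0.1,
    n_labeled_per_side: int = 4,
    seed: int = 11,
):
    """Planted two-community adjacency similarity with UP/DOWN labels.

    Cross-community edge probability is ``mixing * p_in``.  Returns
    (W, index, labels, truth) where truth maps every protein to its planted
    direction.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_cluster
    names = [f"P{i:03d}" for i in range(n)]
    cluster = np.array([0] * n_per_cluster + [1] * n_per_cluster)
    W = np.eye(n)
    p_out = mixing * p_in
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if cluster[i] == cluster[j] else p_out
            if rng.random() < p:
                W[i, j] = W[j, i] = 1.0
    # guarantee each community is internally connected via a ring
    for c in (0, 1):
        members = np.flatnonzero(cluster == c)
        for a, b in zip(members, np.roll(members, -1)):
            W[a, b] = W[b, a] = 1.0
    labels = {}
    for k in range(n_labeled_per_side):
        labels[names[k]] = 1
        labels[names[n_per_cluster + k]] = 0
    truth = {names[i]: ("UP" if cluster[i] == 0 else "DOWN") for i in range(n)}
    return W, names, labels, truth
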