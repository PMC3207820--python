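"""Shared fixtures: small hand-checkable networks and random-graph helpers."""

import numpy as np
import pytest

from lumpchain import Network, Partition, TransitionModel


@pytest.fixture
def barbell():
    """Two unit-weight triangles joined by a single edge (nodes a..f)."""
    W = np.zeros((6, 6))
    for tri in ((0, 1, 2), (3, 4, 5)):
        for i in tri:
            for j in tri:
                if i != j:
                    W[i, j] = 1.0
    W[2, 3] = W[3, 2] = 1.0
    return Network(tuple("abcdef"), W, directed=False)


@pytest.fixture
def barbell_partition(barbell):
    return Partition.from_clusters(barbell.node_labels, [list("abc"), list("def")])


@pytest.fixture
def path3():
    """Undirected path 1-2-3 with unit weights."""
    W = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return Network(("1", "2", "3"), W, directed=False)


@pytest.fixture
def cycle3():
    """Directed 3-cycle 0 -> 1 -> 2 -> 0."""
    W = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
    return Network(("0", "1", "2"), W, directed=True)


@pytest.fixture
def four_cycle():
    W = np.zeros((4, 4))
    for i in range(4):
        W[i, (i + 1) % 4] = W[(i + 1) % 4, i] = 1.0
    return Network(tuple("abcd"), W, directed=False)


def random_strongly_connected_digraph(rng, n, p=0.3, weighted=True):
    """Random digraph made strongly connected by a random spanning cycle."""
    W = np.where(rng.random((n, n)) < p,
                 rng.random((n, n)) + 0.1 if weighted else 1.0, 0.0)
    np.fill_diagonal(W, 0.0)
    perm = rng.permutation(n)
    for k in range(n):
        a, b = perm[k], perm[(k + 1) % n]
        if W[a, b] == 0:
            W[a, b] = 1.0
    return Network(tuple(str(i) for i in range(n)), W, directed=True)


def random_connected_undirected(rng, n, p=0.4, weighted=True):
    """Random undirected weighted graph, connected via a spanning cycle."""
    upper = np.triu(rng.random((n, n)) < p, k=1)
    vals = rng.random((n, n)) + 0.1 if weighted else np.ones((n, n))
    W = np.where(upper, vals, 0.0)
    perm = rng.permutation(n)
    for k in range(n):
        a, b = sorted((perm[k], perm[(k + 1) % n]))
        if a != b and W[a, b] == 0:
            W[a, b] = 1.0
    W = W + W.T
    return Network(tuple(str(i) for i in range(n)), W, directed=False)


def random_partition(rng, node_labels, q):
    """Uniform random partition with every one of the q clusters nonempty."""
    n = len(node_labels)
    assignment = np.concatenate([np.arange(q), rng.integers(0, q, size=n - q)])
    rng.shuffle(assignment)
    return Partition(node_labels, assignment)


@pytest.fixture
def model_of():
    def build(net):
        return TransitionModel.from_network(net)

    return build
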