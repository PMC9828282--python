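import numpy as np
import pytest

from multiplexpsn import IdentityMatrix, OrganismSet, threshold_graph


def matrix_from_identity(ids, pairs, default=0.0, diag=100.0, name="layer"):
    """IdentityMatrix from {(i, j): w} over organism indices."""
    n = len(ids)
    w = np.full((n, n), default, dtype=float)
    for (i, j), v in pairs.items():
        w[i, j] = w[j, i] = v
    np.fill_diagonal(w, diag)
    return IdentityMatrix(name, OrganismSet(tuple(ids)), w)


def graph_from_edges(ids, edges, name="layer", sigma=50.0):
    """Unweighted LayerGraph with exactly the given edges."""
    mat = matrix_from_identity(ids, {e: 90.0 for e in edges}, name=name)
    return threshold_graph(mat, sigma)


def random_identity_matrix(rng, n, name="layer"):
    w = rng.uniform(0, 100, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 100.0)
    return IdentityMatrix(name, OrganismSet(tuple(f"o{i}" for i in range(n))), w)


def random_layer(rng, n, p=0.4, name="layer"):
    """Random Erdos-Renyi-style unweighted layer over named organisms."""
    adj = rng.random((n, n)) < p
    adj = np.triu(adj, 1)
    edges = {(int(i), int(j)): 90.0 for i, j in zip(*np.nonzero(adj))}
    return graph_from_edges([f"o{i}" for i in range(n)], edges, name=name)


@pytest.fixture
def two_triangles_bridge():
    """Two triangles a-b-c and d-e-f joined by the bridge c-d."""
    edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]
    return graph_from_edges(list("abcdef"), edges)


@pytest.fixture
def two_disjoint_triangles():
    edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]
    return graph_from_edges(list("abcdef"), edges)
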