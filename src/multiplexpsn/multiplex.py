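"""Assembly of the L-layer multiplex from thresholded layer graphs.

Every organism is a node in every layer, including organisms with no
intra-layer edge there (isolated replicas).  Replicas of one organism are
pairwise coupled by unweighted inter-layer edges across *all* layer pairs
(a full clique of L(L-1)/2 couplings per organism).  Global nodes follow
the usual enumeration: organism i (1-based) in layer alpha (1-based) is
node (alpha-1)*n + i.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import InputError
from .identity import OrganismSet
from .psn import LayerGraph

#: an intra-layer edge: (layer index alpha, i, j) -- all 0-based, i < j
IntraEdge = tuple[int, int, int]


@dataclasses.dataclass
class Partition:
    """Organism-level community assignment.

    Labels are consecutive integers starting at 1, ordered by each
    community's smallest organism index, so labelling is deterministic.
    ``isolated`` lists organisms with no intra-layer edge in any layer of
    the multiplex they came from; they always sit in singleton communities.
    """

    assignment: dict[str, int]
    modularity: float | None = None
    isolated: tuple[str, ...] = ()

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def communities(self) -> list[tuple[str, ...]]:
        """Communities as tuples of organism ids, ordered by label."""
        by_label: dict[int, list[str]] = {}
        for o, lab in self.assignment.items():
            by_label.setdefault(lab, []).append(o)
        return [tuple(by_label[lab]) for lab in sorted(by_label)]

    def members(self, label: int) -> tuple[str, ...]:
        return tuple(o for o, lab in self.assignment.items() if lab == label)


@dataclasses.dataclass
class MultiplexNetwork:
    """L thresholded layers over a shared organism set plus full inter-layer coupling."""

    organisms: OrganismSet
    layers: list[LayerGraph]

    def __post_init__(self):
        if not self.layers:
            raise InputError("multiplex needs at least one layer")
        for g in self.layers:
            if g.organisms.ids != self.organisms.ids:
                raise InputError(
                    f"layer {g.layer_name}: organism set differs from the multiplex's"
                )

    @property
    def n(self) -> int:
        return len(self.organisms)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def intra_edges(self) -> list[IntraEdge]:
        """All intra-layer edges as (alpha, i, j), 0-based, i < j, sorted."""
        out: list[IntraEdge] = []
        for a, g in enumerate(self.layers):
            out.extend((a, i, j) for i, j in g.edges())
        return out

    def inter_edges(self) -> Iterable[tuple[tuple[int, int], tuple[int, int]]]:
        """Inter-layer couplings ((alpha, i), (beta, i)) for alpha < beta."""
        for i in range(self.n):
            for a, b in itertools.combinations(range(self.n_layers), 2):
                yield ((a, i), (b, i))

    def global_index(self, alpha: int, i: int) -> int:
        """1-based global node number (alpha-1)*n + i for 1-based alpha, i."""
        if not (1 <= alpha <= self.n_layers and 1 <= i <= self.n):
            raise InputError(f"(alpha={alpha}, i={i}) out of range")
        return (alpha - 1) * self.n + i

    def from_global_index(self, g: int) -> tuple[int, int]:
        """Inverse of :meth:`global_index` (both 1-based)."""
        if not 1 <= g <= self.n * self.n_layers:
            raise InputError(f"global index {g} out of range")
        alpha, i = divmod(g - 1, self.n)
        return alpha + 1, i + 1

    def isolated_organisms(self) -> tuple[str, ...]:
        """Organisms with zero intra-layer edges in every layer (the C0 set)."""
        deg = np.zeros(self.n, dtype=int)
        for g in self.layers:
            deg += g.adjacency.sum(axis=1)
        return tuple(self.organisms.ids[i] for i in np.nonzero(deg == 0)[0])


def build_multiplex(layers: Sequence[LayerGraph]) -> MultiplexNetwork:
    """Couple thresholded layers into a multiplex (full inter-layer cliques)."""
    layers = list(layers)
    if not layers:
        raise InputError("build_multiplex: no layers")
    organisms = layers[0].organisms
    return MultiplexNetwork(organisms, layers)


def organism_adjacency(
    m: MultiplexNetwork, removed_intra: Iterable[IntraEdge] = ()
) -> np.ndarray:
    """Organism-level edge multiplicity: number of layers linking each pair."""
    removed = set(removed_intra)
    counts = np.zeros((m.n, m.n), dtype=int)
    for a, g in enumerate(m.layers):
        adj = g.adjacency.copy()
        for (ra, ri, rj) in removed:
            if ra == a:
                adj[ri, rj] = adj[rj, ri] = False
        counts += adj
    return counts


def organism_components(
    m: MultiplexNetwork, removed_intra: Iterable[IntraEdge] = ()
) -> Partition:
    """Connected components of the multiplex, projected to organism level.

    Inter-layer couplings are never removed, so all replicas of an organism
    share a component; components of the global graph are exactly the
    components of the organism-level union graph across layers.
    """
    counts = organism_adjacency(m, removed_intra)
    _, labels = connected_components(csr_matrix((counts > 0).astype(np.int8)), directed=False)
    return _partition_from_labels(m, labels)


def _partition_from_labels(m: MultiplexNetwork, labels: np.ndarray) -> Partition:
    """Canonical Partition (labels ordered by smallest member index)."""
    order: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order) + 1
    assignment = {m.organisms.ids[i]: order[labels[i]] for i in range(m.n)}
    return Partition(assignment, isolated=m.isolated_organisms())


def write_edge_list(m: MultiplexNetwork, path) -> None:
    """Edge list with 1-based global node numbers; columns src, dst, type, layer."""
    with open(path, "w") as fh:
        fh.write("src_global\tdst_global\ttype\tlayer\n")
        for a, i, j in m.intra_edges:
            fh.write(
                f"{m.global_index(a + 1, i + 1)}\t{m.global_index(a + 1, j + 1)}"
                f"\tintra\t{m.layers[a].layer_name}\n"
            )
        for (a, i), (b, _) in m.inter_edges():
            fh.write(
                f"{m.global_index(a + 1, i + 1)}\t{m.global_index(b + 1, i + 1)}"
                f"\tinter\t-\n"
            )
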