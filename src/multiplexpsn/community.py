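"""Divisive multiplex community detection by edge-betweenness removal.

The classical Girvan-Newman procedure removes, one at a time, the edge with
the largest shortest-path betweenness, recomputing betweenness after every
removal, and reads community structure off the fragmentation history.  Its
multiplex generalisation implemented here operates on the global graph of
``n * L`` replica nodes: betweenness is computed over intra-layer edges *and*
the unweighted inter-layer couplings (all unit length), but only intra-layer
edges are candidates for removal -- couplings persist, so the replicas of an
organism always stay together and the fragmentation history lives at
organism level.  A removal in one layer therefore reroutes shortest paths
through the other layers, which is what makes the procedure genuinely
multiplex rather than L independent runs.

Modularity along the trace is the multilayer (Mucha-style) modularity with
resolution gamma and inter-layer coupling omega, evaluated on the original
thresholded multiplex with the partition induced by current connectivity
(the classical convention: the null model is not re-fit to the pruned
graph).  With a single layer it reduces exactly to the familiar

    Q = (1/2m) sum_ij [A_ij - k_i k_j / 2m] delta(C_i, C_j).

Betweenness is recomputed only inside the connected component touched by
the last removal (scores elsewhere are unaffected); the scorer itself runs
in igraph's C core, since the schedule recomputes after every single
removal.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import igraph as ig
import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import InputError, SelectionError
from .identity import IdentityMatrix, OrganismSet, symmetrize
from .multiplex import (
    IntraEdge,
    MultiplexNetwork,
    Partition,
    build_multiplex,
    organism_components,
)
from .psn import LayerGraph

_TIE_TOL = 1e-9


# ---------------------------------------------------------------------------
# betweenness


def _component_betweenness(
    m: MultiplexNetwork,
    adj: list[np.ndarray],
    organisms_subset: Sequence[int],
) -> dict[IntraEdge, float]:
    """Edge betweenness of intra edges among the replicas of a subset of organisms.

    ``adj`` holds the *current* per-layer adjacency.  The subgraph induced by
    the subset's replicas contains all their intra edges plus the full
    inter-layer clique per organism; because couplings keep replicas
    together, a connected component of the global graph is always the full
    replica set of a set of organisms, so restricting to such a set is exact.
    """
    sub = [int(x) for x in organisms_subset]
    L = m.n_layers
    local = {o: k for k, o in enumerate(sub)}
    nv = len(sub) * L

    edges: list[tuple[int, int]] = []
    keys: list[IntraEdge] = []
    for a in range(L):
        block = adj[a][np.ix_(sub, sub)]
        iu, ju = np.nonzero(np.triu(block, 1))
        for i, j in zip(iu.tolist(), ju.tolist()):
            edges.append((a * len(sub) + i, a * len(sub) + j))
            keys.append((a, sub[i], sub[j]))
    n_intra = len(edges)
    for k in range(len(sub)):
        for a in range(L):
            for b in range(a + 1, L):
                edges.append((a * len(sub) + k, b * len(sub) + k))

    if n_intra == 0:
        return {}
    g = ig.Graph(n=nv, edges=edges)
    scores = g.edge_betweenness()
    return {keys[t]: float(scores[t]) for t in range(n_intra)}


def edge_betweenness(
    m: MultiplexNetwork, removed_intra: Iterable[IntraEdge] = ()
) -> dict[IntraEdge, float]:
    """Shortest-path betweenness of every remaining intra-layer edge.

    Computed on the full global graph (intra + inter edges, unit length);
    each unordered replica pair in the same component contributes 1 split
    equally over its shortest paths.
    """
    removed = set(removed_intra)
    adj = [g.adjacency.copy() for g in m.layers]
    for a, i, j in removed:
        adj[a][i, j] = adj[a][j, i] = False
    return _component_betweenness(m, adj, range(m.n))


# ---------------------------------------------------------------------------
# modularity


def _labels_for(graph_organisms: OrganismSet, partition: Partition | Mapping[str, int]) -> np.ndarray:
    assignment = partition.assignment if isinstance(partition, Partition) else partition
    try:
        return np.array([assignment[o] for o in graph_organisms.ids])
    except KeyError as exc:
        raise InputError(f"partition does not cover organism {exc.args[0]!r}") from exc


def modularity_single(graph: LayerGraph, partition: Partition | Mapping[str, int]) -> float:
    """Newman modularity Q of a partition on a single unweighted layer.

    Q = (1/2m) sum_ij [A_ij - k_i k_j / 2m] delta(C_i, C_j); 0 for an
    edgeless graph by convention.
    """
    labels = _labels_for(graph.organisms, partition)
    A = graph.adjacency.astype(float)
    k = A.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    _, lab_idx = np.unique(labels, return_inverse=True)
    intra = 0.0
    for c in range(lab_idx.max() + 1):
        sel = lab_idx == c
        intra += A[np.ix_(sel, sel)].sum()
    k_c = np.bincount(lab_idx, weights=k)
    return float((intra - (k_c**2).sum() / two_m) / two_m)


def modularity_multiplex(
    m: MultiplexNetwork,
    partition: Partition | Mapping[str, int],
    gamma: float = 1.0,
    omega: float = 1.0,
) -> float:
    """Multilayer modularity with resolution gamma and coupling omega.

    Q = (1/2mu) sum_{ij,ab} [ (A_ij^a - gamma k_i^a k_j^a / 2m_a) d_ab
                              + d_ij * omega * (1 - d_ab) ] delta(g_i^a, g_j^b)

    where 2mu is the total strength including couplings.  The partition is
    at organism level, so every replica of an organism shares its label and
    the coupling term contributes n * L * (L-1) * omega in full.  Layers
    with no edges contribute no null term.
    """
    labels = _labels_for(m.organisms, partition)
    _, lab_idx = np.unique(labels, return_inverse=True)
    n_comm = lab_idx.max() + 1
    total = 0.0
    two_mu = 0.0
    for g in m.layers:
        A = g.adjacency.astype(float)
        k = A.sum(axis=1)
        two_m = k.sum()
        two_mu += two_m
        if two_m == 0:
            continue
        intra = 0.0
        for c in range(n_comm):
            sel = lab_idx == c
            intra += A[np.ix_(sel, sel)].sum()
        k_c = np.bincount(lab_idx, weights=k, minlength=n_comm)
        total += intra - gamma * (k_c**2).sum() / two_m
    coupling = m.n * m.n_layers * (m.n_layers - 1) * omega
    two_mu += coupling
    total += coupling
    if two_mu == 0:
        return 0.0
    return float(total / two_mu)


# ---------------------------------------------------------------------------
# the removal trace


@dataclasses.dataclass
class StepRecord:
    edge: IntraEdge
    betweenness: float
    n_communities: int
    modularity: float


@dataclasses.dataclass
class SplitEvent:
    """A step at which an organism-level community broke apart."""

    step: int  # 1-based index into the removal sequence
    parent: tuple[str, ...]
    children: tuple[tuple[str, ...], ...]


@dataclasses.dataclass
class RemovalTrace:
    multiplex: MultiplexNetwork
    steps: list[StepRecord]
    events: list[SplitEvent]
    #: partition before any removal (index 0) and after each event (index k)
    partitions: list[Partition]
    gamma: float
    omega: float
    complete: bool

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def community_counts(self) -> list[int]:
        return [s.n_communities for s in self.steps]


def multing(
    m: MultiplexNetwork,
    gamma: float = 1.0,
    omega: float = 1.0,
    stop_at_n_communities: int | None = None,
    max_steps: int | None = None,
) -> RemovalTrace:
    """Iterative removal of the highest-betweenness intra-layer edge.

    After each removal the organism-level components, and the multilayer
    modularity of the induced partition, are recorded.  Ties on the maximal
    betweenness (within 1e-9 relative) are broken lexicographically on
    (layer index, smaller endpoint, larger endpoint), making traces
    bit-reproducible.  By default the loop runs until no intra-layer edge
    remains; ``stop_at_n_communities`` / ``max_steps`` truncate it.
    """
    if not m.intra_edges:
        raise InputError("multing: multiplex has no intra-layer edges")
    n, L = m.n, m.n_layers
    adj = [g.adjacency.copy() for g in m.layers]
    counts = np.zeros((n, n), dtype=int)
    for a in range(L):
        counts += adj[a]

    initial = organism_components(m)
    comp_labels = _labels_array(initial, m.organisms)
    isolated = initial.isolated
    q0 = modularity_multiplex(m, initial, gamma, omega)
    initial = Partition(dict(initial.assignment), modularity=q0, isolated=isolated)

    scores: dict[IntraEdge, float] = {}
    for lab in np.unique(comp_labels):
        members = np.nonzero(comp_labels == lab)[0]
        if len(members) > 1:
            scores.update(_component_betweenness(m, adj, members))

    steps: list[StepRecord] = []
    events: list[SplitEvent] = []
    partitions: list[Partition] = [initial]
    q = q0
    n_comm = initial.n_communities
    ids = m.organisms.ids

    while scores:
        if stop_at_n_communities is not None and n_comm >= stop_at_n_communities:
            break
        if max_steps is not None and len(steps) >= max_steps:
            break
        best = max(scores.values())
        tol = _TIE_TOL * max(1.0, abs(best))
        edge = min(e for e, s in scores.items() if s >= best - tol)
        score = scores.pop(edge)
        a, i, j = edge
        adj[a][i, j] = adj[a][j, i] = False
        counts[i, j] -= 1
        counts[j, i] -= 1

        comp_members = np.nonzero(comp_labels == comp_labels[i])[0]
        split_children = None
        if counts[i, j] == 0:
            reach = _reachable_within(counts, comp_members, i)
            if j not in reach:
                rest = np.array(sorted(set(comp_members.tolist()) - reach), dtype=int)
                part_a = np.array(sorted(reach), dtype=int)
                new_label = comp_labels.max() + 1
                comp_labels[rest] = new_label
                split_children = (part_a, rest)

        if split_children is not None:
            n_comm += 1
            parent = tuple(ids[x] for x in comp_members)
            children = tuple(
                tuple(ids[x] for x in child) for child in split_children
            )
            part = _partition_from_comp_labels(m, comp_labels, isolated)
            q = modularity_multiplex(m, part, gamma, omega)
            part.modularity = q
            partitions.append(part)
            events.append(SplitEvent(len(steps) + 1, parent, children))

        steps.append(StepRecord(edge, score, n_comm, q))

        # refresh betweenness inside the touched component (both halves if split)
        for e in [e for e in scores if comp_labels[e[1]] == comp_labels[i] or comp_labels[e[1]] == comp_labels[j]]:
            del scores[e]
        for members in (
            split_children
            if split_children is not None
            else (np.nonzero(comp_labels == comp_labels[i])[0],)
        ):
            if len(members) > 1:
                scores.update(_component_betweenness(m, adj, members))

    complete = not scores and all(not a.any() for a in adj)
    return RemovalTrace(m, steps, events, partitions, gamma, omega, complete)


def _labels_array(partition: Partition, organisms: OrganismSet) -> np.ndarray:
    return np.array([partition.assignment[o] for o in organisms.ids])


def _partition_from_comp_labels(
    m: MultiplexNetwork, comp_labels: np.ndarray, isolated: tuple[str, ...]
) -> Partition:
    order: dict[int, int] = {}
    for lab in comp_labels:
        if lab not in order:
            order[lab] = len(order) + 1
    assignment = {m.organisms.ids[i]: order[comp_labels[i]] for i in range(m.n)}
    return Partition(assignment, isolated=isolated)


def _reachable_within(counts: np.ndarray, members: np.ndarray, start: int) -> set[int]:
    """BFS over the organism union graph restricted to one old component."""
    allowed = set(members.tolist())
    seen = {start}
    frontier = [start]
    while frontier:
        u = frontier.pop()
        for v in np.nonzero(counts[u] > 0)[0].tolist():
            if v in allowed and v not in seen:
                seen.add(v)
                frontier.append(v)
    return seen


def girvan_newman_trace(layer: LayerGraph, **kwargs) -> RemovalTrace:
    """Classical single-layer Girvan-Newman as the L=1 special case."""
    return multing(build_multiplex([layer]), **kwargs)


# ---------------------------------------------------------------------------
# partition selection


def best_partition(
    trace: RemovalTrace,
    strategy: str = "max_q",
    event_k: int | None = None,
    community_count: int | None = None,
) -> Partition:
    """Pick a partition off the trace.

    - ``max_q``: recorded partition with the greatest modularity (earliest
      on ties).
    - ``before_event``: partition immediately before split event ``event_k``
      (1-based; event 1 -> the initial partition).
    - ``at_community_count``: first recorded partition with exactly
      ``community_count`` organism-level communities.
    """
    if strategy == "max_q":
        qs = [p.modularity for p in trace.partitions]
        return trace.partitions[int(np.argmax(qs))]
    if strategy == "before_event":
        if event_k is None or not 1 <= event_k <= len(trace.events):
            raise SelectionError(f"before_event: no event {event_k}")
        return trace.partitions[event_k - 1]
    if strategy == "at_community_count":
        for p in trace.partitions:
            if p.n_communities == community_count:
                return p
        raise SelectionError(
            f"at_community_count: count {community_count} never reached "
            f"(recorded counts {[p.n_communities for p in trace.partitions]})"
        )
    raise SelectionError(f"unknown strategy {strategy!r}")


def partition_before_group_split(trace: RemovalTrace, group: Sequence[str]) -> Partition:
    """Partition immediately before the event that separated ``group``.

    The reference event is the first one after which the group's members sit
    in communities free of non-members (the branch-out of the group).  Used
    to read modularity 'immediately before the branching out' of a clade of
    interest, e.g. the mitochondrial block.
    """
    gset = set(group)
    for k, part in enumerate(trace.partitions):
        by_label: dict[int, set[str]] = {}
        for o, lab in part.assignment.items():
            by_label.setdefault(lab, set()).add(o)
        clean = all(comm <= gset or not (comm & gset) for comm in by_label.values())
        if clean and k > 0:
            return trace.partitions[k - 1]
        if clean and k == 0:
            return trace.partitions[0]
    raise SelectionError("group never branches out along the recorded trace")


def departure_steps(trace: RemovalTrace, community: Sequence[str]) -> dict[str, int]:
    """Step index at which each organism left the main lineage of ``community``.

    The main lineage starts at the initial community holding the plurality
    of ``community`` members; at every split of the lineage the child with
    most members continues it, and all organisms in the other child are
    recorded as departing at that event's step.
    """
    cset = set(community)
    lineage = max(
        (set(comm) for comm in trace.partitions[0].communities()),
        key=lambda s: len(s & cset),
    )
    out: dict[str, int] = {}
    for ev in trace.events:
        if set(ev.parent) != lineage:
            continue
        kept = max(ev.children, key=lambda ch: (len(set(ch) & cset), len(ch)))
        for child in ev.children:
            if child is not kept:
                for o in child:
                    out[o] = ev.step
        lineage = set(kept)
    return out


# ---------------------------------------------------------------------------
# dendrogram


@dataclasses.dataclass
class DendroNode:
    height: int  # split step index (0 for the root of the initial forest)
    children: list["DendroNode"]
    organism: str | None = None  # set on leaves

    @property
    def is_leaf(self) -> bool:
        return self.organism is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.organism]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclasses.dataclass
class Dendrogram:
    root: DendroNode
    complete: bool

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())


def build_dendrogram(trace: RemovalTrace, final_height: int | None = None) -> Dendrogram:
    """Rooted tree of the fragmentation history.

    An internal node is a bifurcation event; its height is the removal step
    at which the community split (so heights strictly increase along any
    root-to-leaf path).  A leaf's height is the step at which its organism
    became a singleton.  With a complete trace the leaves are exactly the n
    organisms; on a truncated trace, communities that never fully fragmented
    are closed off as multifurcations at the final step height (unresolved).
    """
    if final_height is None:
        final_height = trace.n_steps
    open_nodes: dict[frozenset, DendroNode] = {}

    def make(comm: tuple[str, ...], height: int) -> DendroNode:
        if len(comm) == 1:
            return DendroNode(height, [], organism=comm[0])
        # height is provisional: overwritten by this community's own split event
        node = DendroNode(height, [])
        open_nodes[frozenset(comm)] = node
        return node

    initial = trace.partitions[0].communities()
    roots = [make(c, 0) for c in initial]
    root = roots[0] if len(roots) == 1 else DendroNode(0, roots)

    for ev in trace.events:
        key = frozenset(ev.parent)
        node = open_nodes.pop(key)
        node.height = ev.step
        node.children = [make(c, ev.step) for c in ev.children]

    for key, node in sorted(open_nodes.items(), key=lambda kv: sorted(kv[0])):
        node.height = final_height
        node.children = [
            DendroNode(final_height, [], organism=o) for o in sorted(key)
        ]
    return Dendrogram(root, trace.complete)


def _escape_newick(label: str) -> str:
    if any(c in label for c in " \t()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(
    d: Dendrogram,
    with_support: Mapping[frozenset, float] | None = None,
    branch_lengths: bool = True,
) -> str:
    """Serialise a dendrogram to Newick.

    Internal node labels carry the split step (``s<step>``); when a support
    mapping (clade leaf-set -> percentage) is supplied and covers a clade,
    the support percentage is used as that node's label instead.  Branch
    lengths, when enabled, are height differences in removal steps.
    """

    def render(node: DendroNode, parent_height: int) -> str:
        length = f":{node.height - parent_height}" if branch_lengths else ""
        if node.is_leaf:
            return f"{_escape_newick(node.organism)}{length}"
        inner = ",".join(render(c, node.height) for c in node.children)
        label = f"s{node.height}"
        if with_support is not None:
            clade = frozenset(node.leaves())
            if clade in with_support:
                label = f"{with_support[clade]:g}"
        return f"({inner}){_escape_newick(label)}{length}"

    return render(d.root, 0) + ";"


# ---------------------------------------------------------------------------
# estimator


class MultiplexGirvanNewman(ClusterMixin, BaseEstimator):
    """Multiplex divisive community detection as a clusterer.

    Fits on a list of per-ortholog identity matrices (``IdentityMatrix`` or
    square ndarrays in percent units): symmetrizes and harmonizes them,
    selects per-layer thresholds at dissimilarity peaks (or applies given
    ones), assembles the multiplex, runs the betweenness-removal loop and
    selects a partition.

    Parameters
    ----------
    thresholds : "auto", float or sequence of float, default "auto"
        Per-layer identity thresholds; "auto" selects them at dissimilarity
        peaks via :class:`~multiplexpsn.psn.ThresholdSelector`.
    threshold_mode : {"split_guided", "max_peak"}, default "split_guided"
        Peak-selection rule when thresholds="auto".
    probe : sequence of str, optional
        Probe organisms for split-guided selection (defaults to the
        organisms of taxonomy class "Eukaryota").
    gamma, omega : float, default 1.0
        Resolution and inter-layer coupling of the multilayer modularity.
    strategy : {"max_q", "before_event", "at_community_count"}, default "max_q"
        How the reported partition is picked off the removal trace.
    event_k, community_count : int, optional
        Arguments of the respective strategies.
    stop_at_n_communities, max_steps : int, optional
        Early-termination of the removal loop (default: run to completion).

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Community label per organism, aligned with ``organisms_.ids``.
    organisms_ : OrganismSet
    thresholds_ : ndarray of shape (L,)
    multiplex_ : MultiplexNetwork
    trace_ : RemovalTrace
    partition_ : Partition
    modularity_ : float
    n_communities_ : int
    isolated_ : tuple of str
    """

    def __init__(
        self,
        thresholds="auto",
        threshold_mode="split_guided",
        probe=None,
        gamma=1.0,
        omega=1.0,
        strategy="max_q",
        event_k=None,
        community_count=None,
        stop_at_n_communities=None,
        max_steps=None,
    ):
        self.thresholds = thresholds
        self.threshold_mode = threshold_mode
        self.probe = probe
        self.gamma = gamma
        self.omega = omega
        self.strategy = strategy
        self.event_k = event_k
        self.community_count = community_count
        self.stop_at_n_communities = stop_at_n_communities
        self.max_steps = max_steps

    def _coerce(self, X) -> list[IdentityMatrix]:
        from .identity import harmonize_layers

        mats = []
        for k, x in enumerate(X):
            if isinstance(x, IdentityMatrix):
                mats.append(x)
            else:
                arr = np.asarray(x, dtype=float)
                if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
                    raise InputError(f"layer {k}: expected a square matrix")
                width = len(str(arr.shape[0]))
                ids = tuple(f"org_{i + 1:0{width}d}" for i in range(arr.shape[0]))
                mats.append(IdentityMatrix(f"layer_{k + 1}", OrganismSet(ids), arr))
        mats = [symmetrize(mm) for mm in mats]
        _, mats = harmonize_layers(
            mats, taxonomy=mats[0].organisms.taxonomy
        )
        return mats

    def fit(self, X, y=None):
        from .psn import ThresholdSelector, threshold_graph

        matrices = self._coerce(list(X))
        if self.thresholds == "auto":
            sel = ThresholdSelector(mode=self.threshold_mode, probe=self.probe)
            layers = sel.fit_transform(matrices)
            self.thresholds_ = sel.thresholds_
        else:
            thr = np.broadcast_to(np.asarray(self.thresholds, dtype=float), (len(matrices),))
            layers = [threshold_graph(mm, s) for mm, s in zip(matrices, thr)]
            self.thresholds_ = thr.copy()
        self.multiplex_ = build_multiplex(layers)
        self.trace_ = multing(
            self.multiplex_,
            gamma=self.gamma,
            omega=self.omega,
            stop_at_n_communities=self.stop_at_n_communities,
            max_steps=self.max_steps,
        )
        self.partition_ = best_partition(
            self.trace_,
            strategy=self.strategy,
            event_k=self.event_k,
            community_count=self.community_count,
        )
        self.organisms_ = self.multiplex_.organisms
        self.labels_ = np.array(
            [self.partition_.assignment[o] for o in self.organisms_.ids]
        )
        self.modularity_ = self.partition_.modularity
        self.n_communities_ = self.partition_.n_communities
        self.isolated_ = self.partition_.isolated
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def dendrogram_(self) -> Dendrogram:
        return build_dendrogram(self.trace_)
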