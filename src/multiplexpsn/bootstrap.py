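"""Identity-score bootstrap for community support.

Rather than resampling alignment columns, each replicate perturbs the
pairwise identity scores themselves: one layer is chosen uniformly at
random, and every pair's identity w (percent) is replaced by
``k * 100 / Y`` with ``k ~ Binomial(Y, w / 100)``, where Y is that layer's
alignment length.  High identities therefore fluctuate less than low ones,
mimicking the behaviour of similarity scores under traditional sequence
resampling.  All other layers are left untouched; each layer is then
re-thresholded at its *original* sigma_th and the community detection is
re-run, and support for a named organism group is the percentage of
replicates in which the group is recovered.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .errors import DomainError, InputError
from .identity import IdentityMatrix
from .multiplex import Partition, build_multiplex
from .psn import threshold_graph


@dataclasses.dataclass
class BootstrapConfig:
    """Replication settings; thresholds and Y come from the original run."""

    per_layer_Y: Mapping[str, int]
    thresholds: Mapping[str, float]
    n_reps: int = 1000
    seed: int | None = None
    #: partition depth per replicate: number of organism-level communities at
    #: which the removal loop stops and the partition is read (None = max-Q
    #: over a complete trace)
    community_count: int | None = None
    gamma: float = 1.0
    omega: float = 1.0
    #: perturb every layer per replicate instead of one (sensitivity mode)
    perturb_all_layers: bool = False

    def __post_init__(self):
        for name, y in self.per_layer_Y.items():
            if y < 1:
                raise DomainError(f"layer {name}: alignment length Y={y} must be >= 1")
        for name, s in self.thresholds.items():
            if not 0 <= s <= 100:
                raise DomainError(f"layer {name}: threshold {s} outside [0, 100]")


@dataclasses.dataclass
class BootstrapSummary:
    n_reps: int
    group_support: dict[str, float]
    replicate_partitions: list[Partition] | None = None


def resample_matrix(
    matrix: IdentityMatrix, Y: int, rng: np.random.Generator
) -> IdentityMatrix:
    """Binomial resampling of every unordered identity pair; diagonal untouched.

    One draw per pair keeps the matrix symmetric.  Absent organisms (zero
    rows) stay absent since Binomial(Y, 0) = 0.
    """
    if Y < 1:
        raise DomainError(f"Y={Y} must be >= 1")
    w = matrix.values
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    p = w[iu, ju] / 100.0
    k = rng.binomial(Y, p)
    out = w.copy()
    out[iu, ju] = out[ju, iu] = k * 100.0 / Y
    return IdentityMatrix(matrix.layer_name, matrix.organisms, out)


def bootstrap_replicate(
    layers: Sequence[IdentityMatrix],
    cfg: BootstrapConfig,
    rng: np.random.Generator,
    return_matrices: bool = False,
):
    """One replicate: perturb one random layer, re-threshold all at the
    original sigma_th, rebuild the multiplex, rerun the removal loop."""
    from .community import best_partition, multing

    layers = list(layers)
    if cfg.perturb_all_layers:
        chosen = set(range(len(layers)))
    else:
        chosen = {int(rng.integers(len(layers)))}
    resampled = [
        resample_matrix(mat, int(cfg.per_layer_Y[mat.layer_name]), rng)
        if k in chosen
        else mat
        for k, mat in enumerate(layers)
    ]
    graphs = [
        threshold_graph(mat, cfg.thresholds[mat.layer_name]) for mat in resampled
    ]
    trace = multing(
        build_multiplex(graphs),
        gamma=cfg.gamma,
        omega=cfg.omega,
        stop_at_n_communities=cfg.community_count,
    )
    if cfg.community_count is not None:
        # deepest recorded partition at (or nearest below) the requested depth
        part = trace.partitions[-1]
    else:
        part = best_partition(trace, strategy="max_q")
    if return_matrices:
        return part, resampled
    return part


def run_bootstrap(
    layers: Sequence[IdentityMatrix],
    cfg: BootstrapConfig,
    groups: Mapping[str, Sequence[str]] | None = None,
    criterion: str = "exact",
) -> BootstrapSummary:
    """Full bootstrap: ``cfg.n_reps`` replicates driven by a single seeded RNG."""
    rng = np.random.default_rng(cfg.seed)
    partitions = [bootstrap_replicate(layers, cfg, rng) for _ in range(cfg.n_reps)]
    support = {}
    if groups:
        support = {
            name: group_support(partitions, members, criterion=criterion)
            for name, members in groups.items()
        }
    return BootstrapSummary(cfg.n_reps, support, partitions)


def _group_in_partition(part: Partition, group: set[str], criterion: str) -> bool:
    labels = set()
    for o in group:
        if o not in part.assignment:
            raise InputError(f"unknown organism {o!r} in group")
        labels.add(part.assignment[o])
    if len(labels) != 1:
        return False
    if criterion == "containment":
        return True
    if criterion == "exact":
        (lab,) = labels
        return set(part.members(lab)) == group
    raise DomainError(f"unknown support criterion {criterion!r}")


def group_support(
    partitions: Sequence[Partition], group: Sequence[str], criterion: str = "exact"
) -> float:
    """Percentage of partitions in which the group is recovered.

    ``exact``: the group's members form a community on their own (no
    outsider shares the label).  ``containment``: the group sits inside a
    single community, possibly with outsiders.
    """
    gset = set(group)
    if not partitions:
        raise InputError("group_support: no partitions")
    if not gset:
        raise InputError("group_support: empty group")
    hits = sum(_group_in_partition(p, gset, criterion) for p in partitions)
    return 100.0 * hits / len(partitions)


def sister_support(
    partitions: Sequence[Partition],
    group_a: Sequence[str],
    group_b: Sequence[str],
    criterion: str = "exact",
) -> float:
    """Support for two groups forming separate, individually clean communities.

    Operationalises a sister placement at the chosen partition depth: in a
    replicate both groups must be recovered (per ``criterion``) with
    distinct community labels.
    """
    a, b = set(group_a), set(group_b)
    if a & b:
        raise InputError("sister_support: groups overlap")
    if not a or not b:
        raise InputError("sister_support: empty group")
    hits = 0
    for p in partitions:
        if not (_group_in_partition(p, a, criterion) and _group_in_partition(p, b, criterion)):
            continue
        if p.assignment[next(iter(a))] != p.assignment[next(iter(b))]:
            hits += 1
    return 100.0 * hits / len(partitions)
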