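"""Threshold families of protein-similarity networks and threshold selection.

For each ortholog layer, an unweighted graph family is obtained by sweeping
an identity threshold sigma over the integer grid [0, 100]: organisms i, j
are linked at sigma iff ``w_ij >= sigma`` (both present, i != j).  A
dissimilarity between the graphs at consecutive thresholds,
``delta(sigma, sigma + step)``, traces how the network reorganises as edges
are pruned; sharp peaks of delta mark the break-up of modules, and the
working threshold of a layer is taken at such a peak.

The dissimilarity implemented here compares the all-pairs shortest-path
(neighbourhood order) matrices of the two graphs in L1, with disconnected
pairs capped at Lambda = n and normalisation by n(n-1).  Component splits
therefore produce sharp, easily detected peaks.  The measure is pluggable:
:func:`dissimilarity_profile` accepts any callable with the same signature.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from sklearn.base import BaseEstimator

from .errors import DomainError, InputError, SelectionError
from .identity import IdentityMatrix, OrganismSet


@dataclasses.dataclass
class LayerGraph:
    """Unweighted graph of one layer at a fixed identity threshold."""

    layer_name: str
    organisms: OrganismSet
    sigma: float
    adjacency: np.ndarray  # (n, n) bool, symmetric, zero diagonal

    @property
    def n(self) -> int:
        return len(self.organisms)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.adjacency)) // 2

    def edges(self) -> list[tuple[int, int]]:
        iu, ju = np.nonzero(np.triu(self.adjacency, 1))
        return list(zip(iu.tolist(), ju.tolist()))


@dataclasses.dataclass
class DissimilarityProfile:
    """delta(sigma, sigma+step) over the integer threshold grid, with peaks.

    ``delta[k]`` compares the graphs at ``sigma_grid[k]`` and
    ``sigma_grid[k] + step``; ``peaks`` are the sigma values at strict local
    maxima of delta (plateau ties resolved to the smallest sigma).
    """

    layer_name: str
    sigma_grid: np.ndarray
    delta: np.ndarray
    step: int
    peaks: list[int]
    #: source matrix, kept so split-guided selection can re-threshold
    matrix: IdentityMatrix | None = None


def threshold_graph(matrix: IdentityMatrix, sigma: float) -> LayerGraph:
    """Binary adjacency: edge iff ``w_ij >= sigma``, both organisms present."""
    if not 0 <= sigma <= 100:
        raise DomainError(f"sigma={sigma} outside [0, 100]")
    present = matrix.present
    adj = (matrix.values >= sigma) & np.outer(present, present)
    np.fill_diagonal(adj, False)
    return LayerGraph(matrix.layer_name, matrix.organisms, sigma, adj)


def threshold_family(matrix: IdentityMatrix) -> list[LayerGraph]:
    """The 101 graphs at every integer sigma in [0, 100] (nested in sigma)."""
    return [threshold_graph(matrix, s) for s in range(101)]


def neighborhood_matrix(graph: LayerGraph) -> np.ndarray:
    """Shortest-path length between all pairs; disconnected pairs get cap n."""
    n = graph.n
    d = shortest_path(csr_matrix(graph.adjacency.astype(np.int8)), unweighted=True)
    d[np.isinf(d)] = n
    np.fill_diagonal(d, 0)
    return d


def dissimilarity(g1: LayerGraph, g2: LayerGraph) -> float:
    """L1 distance between neighbourhood-order matrices, normalised by n(n-1)."""
    if g1.organisms.ids != g2.organisms.ids:
        raise InputError("dissimilarity: graphs have different organism sets")
    n = g1.n
    if n < 2:
        return 0.0
    d1, d2 = neighborhood_matrix(g1), neighborhood_matrix(g2)
    return float(np.abs(d1 - d2).sum() / (n * (n - 1)))


def find_peaks_grid(delta: np.ndarray) -> list[int]:
    """Strict local maxima of a sequence on an integer grid.

    A plateau counts as a single peak at its smallest index; boundary
    plateaus (touching either end of the grid) are not peaks.
    """
    peaks: list[int] = []
    k = 0
    m = len(delta)
    while k < m:
        j = k
        while j + 1 < m and delta[j + 1] == delta[k]:
            j += 1
        left_lower = k > 0 and delta[k - 1] < delta[k]
        right_lower = j + 1 < m and delta[j + 1] < delta[k]
        if left_lower and right_lower:
            peaks.append(k)
        k = j + 1
    return peaks


def dissimilarity_profile(
    matrix: IdentityMatrix,
    step: int = 1,
    measure: Callable[[LayerGraph, LayerGraph], float] = dissimilarity,
) -> DissimilarityProfile:
    """delta between the graphs at sigma and sigma+step for sigma = 0..100-step."""
    if step < 1:
        raise DomainError(f"step={step} must be >= 1")
    sigma_grid = np.arange(101)
    if measure is dissimilarity:
        # fast path: one shortest-path matrix per sigma, reused for both sides
        n = len(matrix.organisms)
        dist = {}
        for s in range(101):
            g = threshold_graph(matrix, s)
            dist[s] = neighborhood_matrix(g)
        norm = n * (n - 1) if n > 1 else 1
        delta = np.array(
            [np.abs(dist[s] - dist[s + step]).sum() / norm for s in range(101 - step)]
        )
    else:
        graphs = {s: threshold_graph(matrix, s) for s in range(101)}
        delta = np.array(
            [measure(graphs[s], graphs[s + step]) for s in range(101 - step)]
        )
    peaks = [int(sigma_grid[k]) for k in find_peaks_grid(delta)]
    return DissimilarityProfile(matrix.layer_name, sigma_grid, delta, step, peaks, matrix)


def _probe_split_sigma(matrix: IdentityMatrix, probe_idx: np.ndarray) -> int | None:
    """Smallest sigma at which no component mixes probe and non-probe organisms."""
    n = len(matrix.organisms)
    probe_mask = np.zeros(n, dtype=bool)
    probe_mask[probe_idx] = True
    for s in range(101):
        g = threshold_graph(matrix, s)
        _, labels = connected_components(csr_matrix(g.adjacency.astype(np.int8)), directed=False)
        mixed = any(
            probe_mask[labels == lab].any() and (~probe_mask[labels == lab]).any()
            for lab in np.unique(labels)
        )
        if not mixed:
            return s
    return None


def select_threshold(
    profile: DissimilarityProfile,
    mode: str = "split_guided",
    split_probe: Sequence[str] | None = None,
    manual_value: float | None = None,
) -> float:
    """Pick the working threshold sigma_th for a layer.

    - ``split_guided``: the peak immediately preceding the sigma at which the
      probe organisms (e.g. the eukaryotes) disconnect from the rest of their
      component -- the threshold of interest sits just before that split.
    - ``max_peak``: the sigma of the globally largest delta peak.
    - ``manual``: pass-through of ``manual_value``.
    """
    if mode == "manual":
        if manual_value is None:
            raise SelectionError("manual mode requires a value", profile)
        if not 0 <= manual_value <= 100:
            raise DomainError(f"sigma={manual_value} outside [0, 100]")
        return float(manual_value)
    if not profile.peaks:
        raise SelectionError(
            f"{profile.layer_name}: no dissimilarity peaks found", profile
        )
    if mode == "max_peak":
        best = max(profile.peaks, key=lambda s: (profile.delta[s], -s))
        return float(best)
    if mode == "split_guided":
        if split_probe is None or len(split_probe) == 0:
            raise SelectionError("split_guided mode requires a probe organism set", profile)
        if profile.matrix is None:
            raise SelectionError("profile does not carry its source matrix", profile)
        probe_idx = profile.matrix.organisms.indices(split_probe)
        split_sigma = _probe_split_sigma(profile.matrix, probe_idx)
        if split_sigma is None:
            raise SelectionError(
                f"{profile.layer_name}: probe never disconnects on the grid", profile
            )
        below = [p for p in profile.peaks if p < split_sigma]
        if not below:
            raise SelectionError(
                f"{profile.layer_name}: no peak precedes the probe split at "
                f"sigma={split_sigma}",
                profile,
            )
        return float(max(below))
    raise SelectionError(f"unknown selection mode {mode!r}", profile)


class ThresholdSelector(BaseEstimator):
    """Per-layer identity-threshold selection at dissimilarity peaks.

    Parameters
    ----------
    mode : {"split_guided", "max_peak", "manual"}
        Selection rule, see :func:`select_threshold`.
    probe : sequence of str, optional
        Probe organisms for split-guided selection.  When omitted, all
        organisms whose taxonomy class is ``"Eukaryota"`` are used.
    manual_values : sequence of float, optional
        One sigma per layer for manual mode.
    step : int, default 1
        Grid spacing of the dissimilarity profile.

    Attributes
    ----------
    thresholds_ : ndarray of shape (L,)
        Selected sigma_th per layer.
    profiles_ : list of DissimilarityProfile
    """

    def __init__(self, mode="split_guided", probe=None, manual_values=None, step=1):
        self.mode = mode
        self.probe = probe
        self.manual_values = manual_values
        self.step = step

    def fit(self, X: Sequence[IdentityMatrix], y=None):
        matrices = list(X)
        if not matrices:
            raise InputError("ThresholdSelector.fit: no layers given")
        self.profiles_ = [dissimilarity_profile(m, step=self.step) for m in matrices]
        thresholds = []
        for k, prof in enumerate(self.profiles_):
            probe = self.probe
            if probe is None and self.mode == "split_guided":
                probe = matrices[k].organisms.by_class("Eukaryota")
            manual = None
            if self.manual_values is not None:
                manual = self.manual_values[k]
            thresholds.append(
                select_threshold(prof, mode=self.mode, split_probe=probe, manual_value=manual)
            )
        self.thresholds_ = np.array(thresholds)
        return self

    def transform(self, X: Sequence[IdentityMatrix]) -> list[LayerGraph]:
        """Threshold each layer at its selected sigma_th."""
        if not hasattr(self, "thresholds_"):
            raise InputError("ThresholdSelector is not fitted")
        return [threshold_graph(m, s) for m, s in zip(X, self.thresholds_)]

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
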