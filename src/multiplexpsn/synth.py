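"""Synthetic multilayer identity matrices with planted community structure.

The generator emulates the shape of per-ortholog percent-identity matrices
over a shared organism set: symmetric, diagonal 100, block-structured by
planted community, with within- and between-block identities drawn from
truncated normal distributions in percent units, independently per layer.
Optionally some organisms are absent from some layers (zeroed rows/columns
and diagonal -- the isolated-node rule), so that every pipeline stage is
testable without external data.

This is test scaffolding: real identity matrices are produced by aligners,
and their entries are strongly correlated through the underlying phylogeny
rather than independent draws; see the methods note for what that implies.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import truncnorm

from .errors import DomainError, InputError
from .identity import IdentityMatrix, OrganismSet


@dataclasses.dataclass
class PlantedSpec:
    """Planted-block specification for one family of layers.

    ``blocks`` maps block name -> ordered organism ids.  Identity level
    between a pair of organisms is controlled by their block pair:
    ``pair_levels[(A, A)]`` for within-block pairs and
    ``pair_levels[(A, B)]`` (order-insensitive) for between-block pairs,
    each a ``(mean, sd)`` in percent units; missing entries fall back to
    ``within`` / ``between`` defaults.
    """

    blocks: Mapping[str, Sequence[str]]
    n_layers: int
    within: tuple[float, float] = (80.0, 3.0)
    between: tuple[float, float] = (40.0, 3.0)
    pair_levels: Mapping[tuple[str, str], tuple[float, float]] | None = None
    missing_per_layer: Mapping[int, Sequence[str]] | None = None
    layer_names: Sequence[str] | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.n_layers < 1:
            raise InputError("n_layers must be >= 1")
        if any(len(v) == 0 for v in self.blocks.values()):
            raise InputError("blocks must be non-empty")
        all_ids = [o for ids in self.blocks.values() for o in ids]
        if len(set(all_ids)) != len(all_ids):
            raise InputError("organism appears in more than one block")
        for mean, sd in self._all_levels():
            if not 0 <= mean <= 100:
                raise DomainError(f"identity mean {mean} outside [0, 100]")
            if sd < 0:
                raise DomainError(f"identity sd {sd} must be >= 0")
        if self.layer_names is not None and len(self.layer_names) != self.n_layers:
            raise InputError("layer_names length must equal n_layers")

    def _all_levels(self):
        levels = [self.within, self.between]
        if self.pair_levels:
            levels.extend(self.pair_levels.values())
        return levels

    def level(self, block_a: str, block_b: str) -> tuple[float, float]:
        if self.pair_levels:
            for key in ((block_a, block_b), (block_b, block_a)):
                if key in self.pair_levels:
                    return self.pair_levels[key]
        return self.within if block_a == block_b else self.between

    @property
    def organisms(self) -> tuple[str, ...]:
        return tuple(o for ids in self.blocks.values() for o in ids)

    def block_of(self) -> dict[str, str]:
        return {o: name for name, ids in self.blocks.items() for o in ids}


def _draw_truncated(mean: float, sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a, b = (0.0 - mean) / sd, (100.0 - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate(spec: PlantedSpec, taxonomy=None) -> list[IdentityMatrix]:
    """Draw the L layers; deterministic for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    ids = spec.organisms
    n = len(ids)
    organisms = OrganismSet(ids, taxonomy)
    block_of = spec.block_of()
    names = list(
        spec.layer_names
        if spec.layer_names is not None
        else (f"layer_{k + 1}" for k in range(spec.n_layers))
    )

    # group upper-triangle pairs by block pair so each class is one vector draw
    iu, ju = np.triu_indices(n, k=1)
    pair_class: dict[tuple[str, str], list[int]] = {}
    for t, (i, j) in enumerate(zip(iu, ju)):
        a, b = sorted((block_of[ids[i]], block_of[ids[j]]))
        pair_class.setdefault((a, b), []).append(t)

    out = []
    for layer_idx, layer_name in enumerate(names):
        vals = np.empty(len(iu))
        for (a, b), slots in pair_class.items():
            mean, sd = spec.level(a, b)
            vals[slots] = _draw_truncated(mean, sd, len(slots), rng)
        w = np.zeros((n, n))
        w[iu, ju] = w[ju, iu] = vals
        np.fill_diagonal(w, 100.0)
        if spec.missing_per_layer and layer_idx in spec.missing_per_layer:
            absent = organisms.indices(spec.missing_per_layer[layer_idx])
            w[absent, :] = 0.0
            w[:, absent] = 0.0
        out.append(IdentityMatrix(layer_name, organisms, w))
    return out


# ---------------------------------------------------------------------------
# the study-shaped fixture

#: ortholog layer names and typical mature-protein alignment lengths (aa)
LAYER_LENGTHS = {
    "Cob": 380,
    "Cox2": 250,
    "Cox3": 260,
    "Nad1": 320,
    "Nad4": 480,
    "Nad5": 600,
    "Nad6": 200,
    "Nad9": 190,
}

_EUKARYOTES = ["Phyto", "March", "Virid", "Reclino", "Hemi", "Salin"]

#: alphaproteobacterial orders and their representative counts
_ALPHA_ORDERS = [
    ("Rickettsiales", 17),
    ("Rhodobacterales", 15),
    ("Rhodospirillales", 15),
    ("Rhizobiales", 13),
    ("Sphingomonadales", 4),
    ("Caulobacterales", 3),
    ("Magnetococcales", 2),
    ("Kordiimonadales", 1),
    ("Parvularculales", 1),
    ("Unclassified", 1),
]


def paper_shaped_fixture(
    seed: int | None = None,
) -> tuple[list[IdentityMatrix], dict[str, tuple[str, str]]]:
    """An 86-organism, 8-layer fixture shaped like the mitochondrial study.

    Blocks: 6 eukaryotes (mitochondrial sequences), 72 Alphaproteobacteria,
    4 Betaproteobacteria and 4 Gammaproteobacteria (outgroups).  The
    17 Rickettsiales inside the alpha block form an early-diverging
    sub-block: their identities to *all* alphas (each other included) sit
    below the within-alpha level, so at the selected thresholds they hang
    off the alpha community by few edges and peel off first during edge
    removal, without forming a competing sub-community -- emulating the
    early, leaf-by-leaf divergence reported for that order.

    Identity levels (percent, sd 3): within blocks 72-80; eukaryote to the
    alpha core 55 (the endosymbiotic affinity that keeps mitochondrial
    sequences attached to the alpha cluster until high thresholds); all
    other between-class pairs 38-48; the Rickettsiales-like sub-block is
    uniformly diverged -- 58 to any alpha (each other included) and 48 to
    the eukaryotes -- so its members do not straddle two communities.

    Returns the 8 layers plus a taxonomy table id -> (class, order).
    """
    euk = _EUKARYOTES
    alpha: list[str] = []
    taxonomy: dict[str, tuple[str, str]] = {o: ("Eukaryota", "-") for o in euk}
    rick: list[str] = []
    for order, count in _ALPHA_ORDERS:
        for k in range(count):
            name = f"{order[:6]}_{k + 1:02d}"
            alpha.append(name)
            taxonomy[name] = ("Alphaproteobacteria", order)
            if order == "Rickettsiales":
                rick.append(name)
    beta = [f"Beta_{k + 1}" for k in range(4)]
    gamma = [f"Gamma_{k + 1}" for k in range(4)]
    taxonomy.update({o: ("Betaproteobacteria", "-") for o in beta})
    taxonomy.update({o: ("Gammaproteobacteria", "-") for o in gamma})

    alpha_main = [o for o in alpha if o not in rick]
    blocks = {
        "eukaryote": euk,
        "rickettsiales": rick,
        "alpha_main": alpha_main,
        "beta": beta,
        "gamma": gamma,
    }
    sd = 3.0
    pair_levels = {
        ("eukaryote", "eukaryote"): (72.0, sd),
        ("alpha_main", "alpha_main"): (78.0, sd),
        ("rickettsiales", "rickettsiales"): (58.0, sd),
        ("rickettsiales", "alpha_main"): (58.0, sd),
        ("beta", "beta"): (80.0, sd),
        ("gamma", "gamma"): (80.0, sd),
        ("eukaryote", "alpha_main"): (55.0, sd),
        ("eukaryote", "rickettsiales"): (48.0, sd),
        ("eukaryote", "beta"): (38.0, sd),
        ("eukaryote", "gamma"): (38.0, sd),
        ("alpha_main", "beta"): (40.0, sd),
        ("alpha_main", "gamma"): (40.0, sd),
        ("rickettsiales", "beta"): (40.0, sd),
        ("rickettsiales", "gamma"): (40.0, sd),
        ("beta", "gamma"): (45.0, sd),
    }
    spec = PlantedSpec(
        blocks=blocks,
        n_layers=len(LAYER_LENGTHS),
        pair_levels=pair_levels,
        layer_names=list(LAYER_LENGTHS),
        seed=seed,
    )
    return generate(spec, taxonomy=taxonomy), taxonomy


def planted_blocks(taxonomy: Mapping[str, tuple[str, str]]) -> dict[str, tuple[str, ...]]:
    """The four planted class-level blocks of the fixture, from its taxonomy."""
    out: dict[str, list[str]] = {}
    for o, (cls, _) in taxonomy.items():
        out.setdefault(cls, []).append(o)
    return {cls: tuple(ids) for cls, ids in out.items()}
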