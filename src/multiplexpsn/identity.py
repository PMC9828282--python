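"""Percent-identity matrices: reading, computing from alignments, symmetrizing.

Each ortholog layer is summarised by a square matrix ``W`` whose entry
``w_ij`` is the percentage of amino-acid identity between the aligned
sequences of organisms ``i`` and ``j`` (0-100).  An organism absent from a
layer is kept as an isolated node: its row, column *and* diagonal entry are
zero, so presence in the layer is recoverable from the matrix alone
(present organisms carry ``w_ii = 100``).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DomainError, FormatError, InputError

GAP_CHARS = frozenset("-.")


@dataclasses.dataclass(frozen=True)
class OrganismSet:
    """Ordered, unique organism identifiers shared by all layers.

    The position of an id in ``ids`` is the canonical enumeration
    ``i = 1..n`` used by every layer and by the multiplex node numbering.
    ``taxonomy`` optionally maps an id to a ``(class, order)`` pair used for
    reporting and for picking probe groups (e.g. all eukaryotes).
    """

    ids: tuple[str, ...]
    taxonomy: Mapping[str, tuple[str, str]] | None = None

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("organism ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, organism: str) -> int:
        return self.ids.index(organism)

    def indices(self, organisms: Sequence[str]) -> np.ndarray:
        pos = {o: i for i, o in enumerate(self.ids)}
        try:
            return np.array([pos[o] for o in organisms], dtype=int)
        except KeyError as exc:  # pragma: no cover - message only
            raise InputError(f"unknown organism {exc.args[0]!r}") from exc

    def by_class(self, class_label: str) -> tuple[str, ...]:
        """Organisms whose taxonomy class equals ``class_label`` (case-insensitive)."""
        if self.taxonomy is None:
            return ()
        return tuple(
            o
            for o in self.ids
            if o in self.taxonomy
            and self.taxonomy[o][0].lower() == class_label.lower()
        )

    def by_order(self, order_label: str) -> tuple[str, ...]:
        if self.taxonomy is None:
            return ()
        return tuple(
            o
            for o in self.ids
            if o in self.taxonomy
            and self.taxonomy[o][1].lower() == order_label.lower()
        )


@dataclasses.dataclass
class AlignmentSet:
    """A multiple sequence alignment for one ortholog layer."""

    layer_name: str
    sequences: dict[str, str]
    #: number of alignment columns (the Y of the identity bootstrap)
    length: int = 0

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if not self.sequences:
            raise AlignmentError(f"{self.layer_name}: empty alignment")
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.layer_name}: aligned sequences have unequal lengths {sorted(lengths)}"
            )
        (y,) = lengths
        if y == 0:
            raise AlignmentError(f"{self.layer_name}: zero-length alignment")
        self.length = y


@dataclasses.dataclass
class IdentityMatrix:
    """Square percent-identity matrix for one ortholog layer."""

    layer_name: str
    organisms: OrganismSet
    values: np.ndarray  # (n, n) float, percent units

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.organisms)
        if self.values.shape != (n, n):
            raise FormatError(
                f"{self.layer_name}: matrix shape {self.values.shape} does not match "
                f"{n} organisms"
            )
        if np.any(self.values < 0) or np.any(self.values > 100):
            raise DomainError(f"{self.layer_name}: identity values must lie in [0, 100]")

    @property
    def n(self) -> int:
        return len(self.organisms)

    @property
    def present(self) -> np.ndarray:
        """Boolean mask of organisms present in this layer (diagonal == 100)."""
        return np.diag(self.values) > 0

    def is_symmetric(self, tol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.values - self.values.T) <= tol))


def read_identity_matrix(path, dialect: str = "tsv", layer_name: str | None = None) -> IdentityMatrix:
    """Read a labeled square identity matrix from TSV (default) or CSV.

    The file carries organism labels as both header row and first column.
    The matrix is returned exactly as stored -- in particular it is *not*
    symmetrized; call :func:`symmetrize` explicitly.
    """
    path = Path(path)
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise FormatError(f"unknown dialect {dialect!r} (expected 'tsv' or 'csv')")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as {dialect}: {exc}") from exc
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: matrix is not square (shape {df.shape})")
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if len(set(rows)) != len(rows) or len(set(cols)) != len(cols):
        raise FormatError(f"{path}: duplicate organism labels")
    if rows != cols:
        raise FormatError(f"{path}: row and column labels differ")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise FormatError(f"{path}: non-numeric or missing entries")
    if (values < 0).any() or (values > 100).any():
        raise DomainError(f"{path}: identity values outside [0, 100]")
    name = layer_name if layer_name is not None else path.stem
    return IdentityMatrix(name, OrganismSet(tuple(rows)), values)


def write_identity_matrix(matrix: IdentityMatrix, path, dialect: str = "tsv") -> None:
    """Write a labeled square matrix; round-trips through :func:`read_identity_matrix`."""
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise FormatError(f"unknown dialect {dialect!r}")
    df = pd.DataFrame(matrix.values, index=matrix.organisms.ids, columns=matrix.organisms.ids)
    df.to_csv(path, sep=sep)


def read_alignment(path, fmt: str = "fasta", layer_name: str | None = None) -> AlignmentSet:
    """Read a FASTA or Clustal multiple alignment via Biopython."""
    from Bio import AlignIO

    path = Path(path)
    aln = AlignIO.read(str(path), fmt)
    name = layer_name if layer_name is not None else path.stem
    return AlignmentSet(name, {rec.id: str(rec.seq) for rec in aln})


def percent_identity(aln: AlignmentSet, gap_mode: str = "all_columns") -> IdentityMatrix:
    """Pairwise percent identity from an alignment.

    ``w_ij`` is 100 x (columns where i and j carry the same non-gap residue)
    divided by a denominator controlled by ``gap_mode``:

    - ``all_columns`` (default): the full alignment length Y.  Columns where
      either sequence is gapped count toward the denominator but never match.
    - ``pairwise_ungapped``: only columns where neither i nor j is gapped.
      (Clustal-style convention; exposed because identity tools differ.)
    """
    if gap_mode not in ("all_columns", "pairwise_ungapped"):
        raise DomainError(f"unknown gap_mode {gap_mode!r}")
    if len(aln.sequences) < 2:
        raise AlignmentError(f"{aln.layer_name}: need at least 2 sequences")
    ids = tuple(aln.sequences)
    arr = np.array([list(aln.sequences[o]) for o in ids])
    n, y = arr.shape
    gap = np.isin(arr, list(GAP_CHARS))
    w = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gap[i] & ~gap[j]
            matches = np.count_nonzero(both & (arr[i] == arr[j]))
            denom = y if gap_mode == "all_columns" else np.count_nonzero(both)
            w[i, j] = w[j, i] = 100.0 * matches / denom if denom else 0.0
    return IdentityMatrix(aln.layer_name, OrganismSet(ids), w)


def symmetrize(matrix: IdentityMatrix) -> IdentityMatrix:
    """Replace each pair ``w_ij, w_ji`` by their arithmetic mean; diagonal untouched."""
    w = matrix.values
    sym = (w + w.T) / 2.0
    np.fill_diagonal(sym, np.diag(w))
    return IdentityMatrix(matrix.layer_name, matrix.organisms, sym)


def harmonize_layers(
    matrices: Sequence[IdentityMatrix],
    taxonomy: Mapping[str, tuple[str, str]] | None = None,
) -> tuple[OrganismSet, list[IdentityMatrix]]:
    """Expand every layer to the union of organism ids in a single canonical order.

    The canonical order is first-appearance order across the layers as given.
    An organism absent from a layer becomes an isolated node there: its whole
    row/column, including the diagonal, is zero.
    """
    if not matrices:
        raise InputError("harmonize_layers: no matrices given")
    union: list[str] = []
    seen: set[str] = set()
    for m in matrices:
        for o in m.organisms.ids:
            if o not in seen:
                seen.add(o)
                union.append(o)
    if not union:
        raise InputError("harmonize_layers: empty organism union")
    organisms = OrganismSet(tuple(union), taxonomy)
    n = len(union)
    out: list[IdentityMatrix] = []
    for m in matrices:
        expanded = np.zeros((n, n))
        idx = organisms.indices(m.organisms.ids)
        expanded[np.ix_(idx, idx)] = m.values
        out.append(IdentityMatrix(m.layer_name, organisms, expanded))
    return organisms, out


def read_taxonomy(path) -> dict[str, tuple[str, str]]:
    """Read a TSV taxonomy table with columns organism, class, order."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    try:
        o, c, r = (cols.index(k) for k in ("organism", "class", "order"))
    except ValueError as exc:
        raise FormatError(
            f"{path}: taxonomy table needs columns organism/class/order"
        ) from exc
    return {
        str(row.iloc[o]): (str(row.iloc[c]), str(row.iloc[r]))
        for _, row in df.iterrows()
    }


def write_taxonomy(taxonomy: Mapping[str, tuple[str, str]], path) -> None:
    df = pd.DataFrame(
        [(o, c, r) for o, (c, r) in taxonomy.items()],
        columns=["organism", "class", "order"],
    )
    df.to_csv(path, sep="\t", index=False)
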