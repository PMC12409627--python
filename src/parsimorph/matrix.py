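"""Discrete morphological character matrices.

A :class:`CharacterMatrix` is a taxa x characters grid of *state sets*.
Each cell is either MISSING (``None``, from a ``?`` or ``-`` token) or a
non-empty frozenset of integer states drawn from the 0-9 alphabet.
Polymorphic ``(ab)`` and uncertain ``{ab}`` observations are both stored as
the set ``{a, b}``: downstream parsimony scoring is free to pick whichever
member state minimizes tree length, i.e. ambiguity is resolved most
parsimoniously.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

#: Sentinel for an unscored cell ("?" or "-").
MISSING = None

#: The state alphabet is capped at the ten digit symbols 0-9.
MAX_STATES = 10

Cell = "frozenset[int] | None"


@dataclass
class CharacterMeta:
    """Per-character metadata.

    ``index`` is the 1-based character number used in all reports,
    matching the conventional "char. 36: 2 > 1" style of morphological
    systematics. ``ordered`` marks additive characters (linear |a-b|
    transformation cost); everything else is unordered (Fitch).
    """

    index: int
    ordered: bool = False
    label: str = ""


def _as_cell(value) -> Cell:
    if value is MISSING:
        return MISSING
    cell = frozenset(int(s) for s in value)
    if not cell:
        raise ValueError("state set may not be empty; use MISSING for '?'")
    if any(s < 0 or s >= MAX_STATES for s in cell):
        raise ValueError(f"states must lie in 0..{MAX_STATES - 1}, got {sorted(cell)}")
    return cell


class CharacterMatrix:
    """Taxa x characters grid of state sets with per-character metadata."""

    def __init__(
        self,
        taxa: Sequence[str],
        cells: Sequence[Sequence[Cell]],
        char_meta: Sequence[CharacterMeta] | None = None,
    ):
        self.taxa: list[str] = list(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon labels: {dupes}")
        if not self.taxa:
            raise ValueError("matrix must contain at least one taxon")
        self.cells: list[list[Cell]] = [[_as_cell(c) for c in row] for row in cells]
        if len(self.cells) != len(self.taxa):
            raise ValueError("one cell row required per taxon")
        ncols = {len(row) for row in self.cells}
        if len(ncols) != 1:
            raise ValueError("all taxa must have the same number of characters")
        self._n_char = ncols.pop()
        if self._n_char == 0:
            raise ValueError("matrix must contain at least one character")
        if char_meta is None:
            char_meta = [CharacterMeta(index=j + 1) for j in range(self._n_char)]
        self.char_meta: list[CharacterMeta] = list(char_meta)
        if len(self.char_meta) != self._n_char:
            raise ValueError("char_meta length must equal the character count")

    # -- basic views ---------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_char(self) -> int:
        return self._n_char

    def row(self, taxon: str) -> list[Cell]:
        return self.cells[self.taxa.index(taxon)]

    def column(self, j: int) -> list[Cell]:
        """Column ``j`` (0-based) as a list of cells, one per taxon."""
        return [row[j] for row in self.cells]

    def observed_states(self, j: int) -> frozenset:
        """Union of all non-MISSING cell sets in column ``j`` (0-based)."""
        out: set[int] = set()
        for row in self.cells:
            if row[j] is not MISSING:
                out |= row[j]
        return frozenset(out)

    def ordered_flags(self) -> list[bool]:
        return [cm.ordered for cm in self.char_meta]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CharacterMatrix)
            and self.taxa == other.taxa
            and self.cells == other.cells
            and [ (c.index, c.ordered) for c in self.char_meta ]
            == [ (c.index, c.ordered) for c in other.char_meta ]
        )

    def __repr__(self) -> str:
        return f"<CharacterMatrix {self.n_taxa} taxa x {self.n_char} characters>"


def prune_taxa(m: CharacterMatrix, drop: Iterable[str]) -> CharacterMatrix:
    """Remove taxa (e.g. fossils) from the matrix, keeping characters as-is.

    The order of the remaining taxa is preserved. Dropping every taxon is
    rejected; unknown labels raise with the full list of offenders.
    """
    drop = set(drop)
    unknown = drop - set(m.taxa)
    if unknown:
        raise ValueError(f"taxa not in matrix: {sorted(unknown)}")
    keep = [t for t in m.taxa if t not in drop]
    if not keep:
        raise ValueError("cannot drop every taxon: empty matrix")
    rows = [m.cells[m.taxa.index(t)] for t in keep]
    return CharacterMatrix(keep, rows, [CharacterMeta(c.index, c.ordered, c.label) for c in m.char_meta])


def drop_invariant_characters(m: CharacterMatrix) -> tuple[CharacterMatrix, list[int]]:
    """Remove characters whose minimum conceivable length is zero.

    A character is invariant when every non-MISSING cell set can be covered
    by a single state -- this includes columns that look variable only
    through overlapping polymorphisms (e.g. {0}, {0,1}), and all-MISSING
    columns. Pruning taxa routinely produces such columns, which carry no
    information under parsimony and are removed before computing homoplasy
    indices. Returns the reduced matrix and the 1-based original indices of
    the dropped characters.
    """
    from .parsimony import min_steps  # local import to avoid a cycle

    keep_j: list[int] = []
    dropped: list[int] = []
    for j in range(m.n_char):
        if min_steps(m.column(j)) > 0:
            keep_j.append(j)
        else:
            dropped.append(m.char_meta[j].index)
    if not keep_j:
        raise ValueError("all characters invariant: empty matrix")
    rows = [[row[j] for j in keep_j] for row in m.cells]
    meta = [
        CharacterMeta(m.char_meta[j].index, m.char_meta[j].ordered, m.char_meta[j].label)
        for j in keep_j
    ]
    return CharacterMatrix(m.taxa, rows, meta), dropped
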