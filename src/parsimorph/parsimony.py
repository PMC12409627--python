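"""Parsimony scoring of discrete characters on fixed topologies.

The engine is a vectorized Sankoff-style dynamic program over per-node cost
vectors, one column of costs per state (0-9), computed for all characters at
once. With unit transformation costs it is exactly Fitch parsimony for
unordered characters (including the soft-polytomy generalization for
multifurcating nodes); with linear ``|a-b|`` costs it scores ordered
(additive) characters. A MISSING leaf carries zero cost over the whole
character alphabet and therefore never forces a step; a polymorphic or
uncertain cell carries zero cost over its member states, so the most
parsimonious member is the one used in the step count.

Per-character quantities follow the classical homoplasy bookkeeping:

* ``s_i`` -- observed steps of character *i* on the given topology;
* ``m_i`` -- minimum steps over all topologies and ambiguity resolutions
  (for an unordered character: size of a minimum hitting set of the cell
  state-sets, minus one);
* ``g_i`` -- maximum steps over topologies (attained on the star topology):
  number of scored cells minus the largest achievable single-state count,
  with ambiguous cells resolved to *minimize* that largest count;
* ``e_i = s_i - m_i`` -- extra (homoplastic) steps.

Ensemble sums S, M, G of these feed the consistency index CI = M/S, the
retention index RI = (G-S)/(G-M), and the relative homoplasy index.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .matrix import MISSING, MAX_STATES, CharacterMatrix

if TYPE_CHECKING:  # pragma: no cover
    import dendropy

INF = 1 << 30


# ---------------------------------------------------------------------------
# encoding and generic tree arrays
# ---------------------------------------------------------------------------

class _Encoded:
    """Leaf cost tensors for one matrix."""

    __slots__ = ("leafcost", "alphabet", "ordered", "any_ordered", "n_char")

    def __init__(self, m: CharacterMatrix, treat_unordered: bool = False):
        C = m.n_char
        self.n_char = C
        self.ordered = np.array(
            [False] * C if treat_unordered else m.ordered_flags(), dtype=bool
        )
        self.any_ordered = bool(self.ordered.any())
        alphabet = np.zeros((C, MAX_STATES), dtype=bool)
        for j in range(C):
            obs = m.observed_states(j)
            if not obs:
                obs = {0}  # all-MISSING column: degenerate single-state alphabet
            if self.ordered[j]:
                lo, hi = min(obs), max(obs)
                alphabet[j, lo : hi + 1] = True  # additive chars may pass through gaps
            else:
                alphabet[j, sorted(obs)] = True
        self.alphabet = alphabet
        leafcost = np.full((m.n_taxa, C, MAX_STATES), INF, dtype=np.int64)
        for i, row in enumerate(m.cells):
            for j, cell in enumerate(row):
                if cell is MISSING:
                    leafcost[i, j, alphabet[j]] = 0
                else:
                    leafcost[i, j, sorted(cell)] = 0
        self.leafcost = leafcost


def _child_min(down: np.ndarray, enc: _Encoded) -> np.ndarray:
    """min_t(down[t] + cost(t, s)) for every state s, vectorized over chars."""
    out = np.minimum(down, down.min(axis=1, keepdims=True) + 1)
    if enc.any_ordered:
        f = down.copy()
        for s in range(1, MAX_STATES):
            np.minimum(f[:, s], f[:, s - 1] + 1, out=f[:, s])
        for s in range(MAX_STATES - 2, -1, -1):
            np.minimum(f[:, s], f[:, s + 1] + 1, out=f[:, s])
        out = np.where(enc.ordered[:, None], f, out)
    return out


def _tree_arrays(t: "dendropy.Tree", taxa: list[str]):
    """Postorder arrays (children lists, node order, leaf->matrix row)."""
    nodes = list(t.postorder_node_iter())
    index = {id(n): k for k, n in enumerate(nodes)}
    row_of = {label: i for i, label in enumerate(taxa)}
    children: list[list[int]] = [[] for _ in nodes]
    leaf_row = [-1] * len(nodes)
    seen: list[str] = []
    for n in nodes:
        k = index[id(n)]
        for c in n.child_nodes():
            children[k].append(index[id(c)])
        if n.is_leaf():
            label = n.taxon.label if n.taxon is not None else None
            if label is None:
                raise ValueError("tree has an unlabeled leaf")
            if label not in row_of:
                raise ValueError(f"tree leaf {label!r} not in matrix")
            seen.append(label)
            leaf_row[k] = row_of[label]
    if len(seen) != len(set(seen)):
        dupes = sorted({x for x in seen if seen.count(x) > 1})
        raise ValueError(f"duplicate leaf labels in tree: {dupes}")
    missing = set(taxa) - set(seen)
    if missing:
        raise ValueError(f"matrix taxa absent from tree: {sorted(missing)}")
    return children, list(range(len(nodes))), leaf_row, nodes


def _down_pass(children, order, leaf_row, enc: _Encoded):
    down: list[np.ndarray | None] = [None] * len(order)
    cmin: list[np.ndarray | None] = [None] * len(order)
    for v in order:
        kids = children[v]
        if kids:
            d = cmin[kids[0]].copy()
            for k in kids[1:]:
                d += cmin[k]
            if leaf_row[v] >= 0:  # a leaf used as root still carries its own cost
                d += enc.leafcost[leaf_row[v]]
        else:
            d = enc.leafcost[leaf_row[v]].copy()
        down[v] = d
        cmin[v] = _child_min(d, enc)
    return down, cmin


def _up_pass(children, order, leaf_row, enc: _Encoded, down, cmin):
    up: list[np.ndarray | None] = [None] * len(order)
    root = order[-1]
    up[root] = np.zeros_like(down[root])
    for v in reversed(order):
        for k in children[v]:
            resid = down[v] - cmin[k] + up[v]
            up[k] = _child_min(resid, enc)
    return up


def char_lengths(m: CharacterMatrix, t: "dendropy.Tree", *, treat_unordered: bool = False,
                 _enc: _Encoded | None = None) -> np.ndarray:
    """Observed steps ``s_i`` for every character on topology ``t``."""
    enc = _enc if _enc is not None else _Encoded(m, treat_unordered)
    children, order, leaf_row, _ = _tree_arrays(t, m.taxa)
    down, _ = _down_pass(children, order, leaf_row, enc)
    return down[order[-1]].min(axis=1)


# ---------------------------------------------------------------------------
# per-column step bounds
# ---------------------------------------------------------------------------

def _masks(column) -> list[int]:
    out = []
    for cell in column:
        if cell is not MISSING:
            mask = 0
            for s in cell:
                mask |= 1 << s
            out.append(mask)
    return out


def min_steps(column, ordered: bool = False) -> int:
    """Minimum steps of a character over all topologies and resolutions.

    Unordered: exact minimum hitting-set over the <=10 states (so a column
    variable only through overlapping polymorphisms correctly scores 0).
    Ordered: width of the shortest state interval intersecting every cell.
    """
    masks = _masks(column)
    if not masks:
        return 0
    if ordered:
        best = MAX_STATES
        for lo in range(MAX_STATES):
            for hi in range(lo, lo + best):
                if hi >= MAX_STATES:
                    break
                window = ((1 << (hi - lo + 1)) - 1) << lo
                if all(mk & window for mk in masks):
                    best = min(best, hi - lo)
                    break
        return best
    union = 0
    for mk in masks:
        union |= mk
    states = [s for s in range(MAX_STATES) if union >> s & 1]
    for r in range(1, len(states) + 1):
        for combo in combinations(states, r):
            cover = 0
            for s in combo:
                cover |= 1 << s
            if all(mk & cover for mk in masks):
                return r - 1
    raise AssertionError("unreachable: union always hits every cell")


def max_steps(column, n_taxa: int | None = None) -> int:
    """Maximum steps of an unordered character over topologies (star length).

    Equal to ``n_scored`` minus the largest single-state count achievable
    when ambiguous cells are resolved so as to *minimize* that largest
    count. The minimal achievable maximum load over states is computed
    exactly from the Hall condition on the bipartite cell->state assignment:
    ``max over state subsets T of ceil(#cells confined to T / |T|)``.
    """
    masks = _masks(column)
    if not masks:
        return 0
    n_scored = len(masks)
    from collections import Counter

    count = Counter(masks)
    union = 0
    for mk in masks:
        union |= mk
    # enumerate the non-empty submasks of the observed-state union
    best = 1
    sub = union
    while sub:
        size = bin(sub).count("1")
        within = sum(c for mk, c in count.items() if mk & ~sub == 0)
        need = -(-within // size)  # ceil
        if need > best:
            best = need
        sub = (sub - 1) & union
    return n_scored - best


# ---------------------------------------------------------------------------
# public results
# ---------------------------------------------------------------------------

@dataclass
class StepCounts:
    """Per-character step counts on one topology, plus ensemble sums."""

    char_indices: list[int]  # 1-based character numbers
    s: np.ndarray
    m: np.ndarray
    g: np.ndarray

    @property
    def e(self) -> np.ndarray:
        return self.s - self.m

    @property
    def S(self) -> int:
        return int(self.s.sum())

    @property
    def M(self) -> int:
        return int(self.m.sum())

    @property
    def G(self) -> int:
        return int(self.g.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "char": self.char_indices,
                "s": self.s.astype(int),
                "m": self.m.astype(int),
                "g": self.g.astype(int),
                "e": self.e.astype(int),
            }
        )


def tree_length(
    m: CharacterMatrix, t: "dendropy.Tree", *, treat_unordered: bool = False
) -> StepCounts:
    """Score matrix ``m`` on topology ``t``.

    The tree's leaf set must equal the matrix's taxon set exactly (restrict
    scaffolds first). Multifurcating trees are scored as soft polytomies;
    this can differ from resolve-then-minimize behaviour of some programs.
    """
    s = char_lengths(m, t, treat_unordered=treat_unordered)
    ordered = [False] * m.n_char if treat_unordered else m.ordered_flags()
    mm = np.array(
        [min_steps(m.column(j), ordered=ordered[j]) for j in range(m.n_char)],
        dtype=np.int64,
    )
    gg = np.array([max_steps(m.column(j)) for j in range(m.n_char)], dtype=np.int64)
    return StepCounts([cm.index for cm in m.char_meta], s, mm, gg)


class MPRStates:
    """Per-node most-parsimonious-reconstruction state sets for one character.

    ``of(node)`` returns the set of states assignable to that node in at
    least one optimal reconstruction; ``total`` is the character's step
    count on the topology.
    """

    def __init__(self, by_node: dict, total: int):
        self._by_node = by_node
        self.total = total

    def of(self, node) -> frozenset:
        return self._by_node[id(node)]

    def items(self):
        return self._by_node.items()


def mpr_states(m: CharacterMatrix, t: "dendropy.Tree", char_index: int,
               *, treat_unordered: bool = False) -> MPRStates:
    """MPR state sets of character ``char_index`` (1-based) on ``t``."""
    try:
        j = [cm.index for cm in m.char_meta].index(char_index)
    except ValueError:
        raise IndexError(f"character {char_index} not in matrix") from None
    sub = CharacterMatrix(
        m.taxa, [[row[j]] for row in m.cells], [m.char_meta[j]]
    )
    enc = _Encoded(sub, treat_unordered)
    children, order, leaf_row, nodes = _tree_arrays(t, m.taxa)
    down, cmin = _down_pass(children, order, leaf_row, enc)
    up = _up_pass(children, order, leaf_row, enc, down, cmin)
    total = int(down[order[-1]][0].min())
    by_node = {}
    for k, node in enumerate(nodes):
        score = down[k][0] + up[k][0]
        states = frozenset(
            int(s) for s in range(MAX_STATES)
            if enc.alphabet[0, s] and score[s] == total
        )
        by_node[id(node)] = states
    return MPRStates(by_node, total)


def ensemble_lengths(m: CharacterMatrix, trees, *, treat_unordered: bool = False) -> np.ndarray:
    """Total length of ``m`` on each of several topologies (shared encoding)."""
    enc = _Encoded(m, treat_unordered)
    return np.array(
        [int(char_lengths(m, t, _enc=enc).sum()) for t in trees], dtype=np.int64
    )
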