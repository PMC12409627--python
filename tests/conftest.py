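"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's dynamic-programming
engine: tree lengths are recomputed by exhaustive enumeration over
internal-node state assignments, and small-n searches are checked against
enumeration of every labeled binary topology.
"""
from __future__ import annotations

import copy
import random
from itertools import product

import pytest

from parsimorph import MISSING, CharacterMatrix, CharacterMeta, parse_newick
from parsimorph.trees import _N, _to_newick


# ---------------------------------------------------------------------------
# exhaustive oracles
# ---------------------------------------------------------------------------

def brute_force_length(m: CharacterMatrix, tree, j: int, k: int = 4) -> int:
    """Minimum steps of column ``j`` by enumerating internal assignments.

    Leaves contribute min-cost resolutions of their state sets given the
    adjacent internal state, so ambiguity resolution is included in the
    minimization. Cost is |a-b| for ordered characters, 0/1 otherwise.
    """
    ordered = m.char_meta[j].ordered
    cost = (lambda a, b: abs(a - b)) if ordered else (lambda a, b: int(a != b))
    cell_of = dict(zip(m.taxa, (row[j] for row in m.cells)))
    internal = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    best = None
    for assign in product(range(k), repeat=len(internal)):
        state = {id(n): s for n, s in zip(internal, assign)}
        total = 0
        for n in internal:
            for c in n.child_nodes():
                if c.is_leaf():
                    cell = cell_of[c.taxon.label]
                    allowed = range(k) if cell is MISSING else sorted(cell)
                    total += min(cost(state[id(n)], s) for s in allowed)
                else:
                    total += cost(state[id(n)], state[id(c)])
        if best is None or total < best:
            best = total
    return best


def brute_force_matrix_length(m: CharacterMatrix, tree, k: int = 4) -> int:
    return sum(brute_force_length(m, tree, j, k) for j in range(m.n_char))


def all_topologies(labels):
    """Every labeled unrooted binary topology on ``labels`` ((2n-5)!! trees)."""
    labels = list(labels)
    root = _N()
    root.children = [_N(labels[0]), _N(labels[1]), _N(labels[2])]
    shapes = [root]
    for lab in labels[3:]:
        grown = []
        for shape in shapes:
            n_edges = len(_edges_of(shape))
            for i in range(n_edges):
                s2 = copy.deepcopy(shape)
                parent, child = _edges_of(s2)[i]
                mid, leaf = _N(), _N(lab)
                mid.children = [child, leaf]
                parent.children[parent.children.index(child)] = mid
                grown.append(s2)
        shapes = grown
    return [parse_newick(_to_newick(s) + ";") for s in shapes]


def _edges_of(root):
    out = []
    stack = [root]
    while stack:
        n = stack.pop()
        for c in n.children:
            out.append((n, c))
            stack.append(c)
    return out


# ---------------------------------------------------------------------------
# random inputs
# ---------------------------------------------------------------------------

def random_matrix(
    rng: random.Random,
    taxa,
    n_char: int,
    k: int = 4,
    *,
    missing_prob: float = 0.1,
    ambig_prob: float = 0.1,
    ordered_prob: float = 0.0,
) -> CharacterMatrix:
    rows = []
    for _ in taxa:
        row = []
        for _j in range(n_char):
            u = rng.random()
            if u < missing_prob:
                row.append(MISSING)
            elif u < missing_prob + ambig_prob:
                row.append(frozenset(rng.sample(range(k), 2)))
            else:
                row.append(frozenset({rng.randrange(k)}))
        rows.append(row)
    meta = [
        CharacterMeta(j + 1, ordered=rng.random() < ordered_prob)
        for j in range(n_char)
    ]
    return CharacterMatrix(list(taxa), rows, meta)


@pytest.fixture
def quartet():
    return parse_newick("((A,B),(C,D));")


@pytest.fixture
def quartet_matrix():
    return CharacterMatrix(list("ABCD"), [[{0}], [{0}], [{1}], [{1}]])
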