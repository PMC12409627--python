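"""Heuristic maximum-parsimony search with optional backbone constraints.

Desk-scale stand-in for the large TNT-style analyses: random-addition
starts followed by steepest-descent branch swapping (NNI or SPR, SPR by
default), under equal weights (minimize total steps) or implied weights
(minimize F = sum e_i/(e_i + k)). A backbone constraint -- possibly
multifurcating and possibly covering only part of the taxa -- is honored
throughout: every partial and final topology displays it. The "new
technology" arsenal (sectorial searches, ratchet, drift, fusion) is
deliberately not replicated, so exact shortest-length reproduction on large
matrices is best-effort.

Ties at attachment and swap are accepted in first-found order under the
seeded RNG; the result is deterministic given the seed.
"""
from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from .matrix import CharacterMatrix
from .parsimony import _down_pass, _Encoded, _tree_arrays, min_steps
from .trees import Topology, bipartitions, leaf_labels, parse_newick


# ---------------------------------------------------------------------------
# lightweight unrooted tree: adjacency dict + leaf labels
# ---------------------------------------------------------------------------

def _copy(adj):
    return {u: list(vs) for u, vs in adj.items()}


def _edges(adj):
    return [(u, v) for u, vs in adj.items() for v in vs if u < v]


def _postorder_arrays(adj, leaf_label, row_of):
    nodes = list(adj)
    root = next((u for u in nodes if len(adj[u]) > 1), nodes[0])
    order, children, leaf_row = [], {}, {}
    stack = [(root, None, False)]
    while stack:
        u, parent, done = stack.pop()
        kids = [v for v in adj[u] if v != parent]
        if done or not kids:
            order.append(u)
            children[u] = kids
            leaf_row[u] = row_of[leaf_label[u]] if u in leaf_label else -1
        else:
            stack.append((u, parent, True))
            for v in kids:
                stack.append((v, u, False))
    index = {u: i for i, u in enumerate(order)}
    ch = [[index[v] for v in children[u]] for u in order]
    lr = [leaf_row[u] for u in order]
    return ch, list(range(len(order))), lr


def _char_steps(adj, leaf_label, row_of, enc) -> np.ndarray:
    ch, order, lr = _postorder_arrays(adj, leaf_label, row_of)
    down, _ = _down_pass(ch, order, lr, enc)
    return down[order[-1]].min(axis=1)


def _splits(adj, leaf_label):
    """Canonical non-trivial splits (side without the smallest label)."""
    labels = set(leaf_label.values())
    ref = min(labels)
    n = len(labels)
    out = set()
    # reuse the postorder machinery with identity leaf rows
    row_of = {lab: i for i, lab in enumerate(sorted(labels))}
    ch, order, lr = _postorder_arrays(adj, leaf_label, row_of)
    inv = sorted(labels)
    sets: list[frozenset] = [frozenset()] * len(order)
    for k in order:
        if not ch[k]:
            sets[k] = frozenset({inv[lr[k]]})
        else:
            sets[k] = frozenset().union(*(sets[c] for c in ch[k]))
        side = sets[k]
        if ref in side:
            side = frozenset(labels) - side
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return frozenset(out)


def _restrict_split_set(splits, universe, subset):
    subset = frozenset(subset)
    ref = min(subset)
    out = set()
    for side in splits:
        s = side & subset
        if ref in s:
            s = subset - s
        if 2 <= len(s) <= len(subset) - 2:
            out.add(s)
    return frozenset(out)


def _attach(adj, leaf_label, counter, edge, label):
    """New tree with ``label`` attached in the middle of ``edge``."""
    u, v = edge
    a2 = _copy(adj)
    mid, leaf = counter, counter + 1
    a2[u] = [mid if x == v else x for x in a2[u]]
    a2[v] = [mid if x == u else x for x in a2[v]]
    a2[mid] = [u, v, leaf]
    a2[leaf] = [mid]
    l2 = dict(leaf_label)
    l2[leaf] = label
    return a2, l2, counter + 2


def _to_topology(adj, leaf_label) -> Topology:
    root = next(u for u in adj if len(adj[u]) > 1)

    def rec(u, parent):
        kids = [v for v in adj[u] if v != parent]
        if not kids:
            return leaf_label[u]
        return "(" + ",".join(rec(v, u) for v in kids) + ")"

    return parse_newick(rec(root, None) + ";")


def _spr_neighbors(adj, leaf_label):
    """Yield SPR rearrangements as new (adj, leaf_label) pairs."""
    for u, v in list(_edges(adj)) + [(b, a) for a, b in _edges(adj)]:
        # prune the subtree on the v side of edge (u, v)
        rest = [x for x in adj[u] if x != v]
        if len(rest) != 2:
            continue  # u must be internal and become suppressible
        a, b = rest
        base = _copy(adj)
        del base[u]
        base[a] = [b if x == u else x for x in base[a]]
        base[b] = [a if x == u else x for x in base[b]]
        base[v] = [x for x in base[v] if x != u]
        # nodes reachable from v form the pruned subtree
        pruned = {v}
        stack = [v]
        while stack:
            x = stack.pop()
            for y in base.get(x, []):
                if y not in pruned:
                    pruned.add(y)
                    stack.append(y)
        host_edges = [
            (x, y) for x, y in _edges(base) if x not in pruned and y not in pruned
        ]
        for x, y in host_edges:
            if (x, y) == (min(a, b), max(a, b)):
                continue  # re-inserting on the original edge restores the tree
            n2 = _copy(base)
            n2[x] = [u if z == y else z for z in n2[x]]
            n2[y] = [u if z == x else z for z in n2[y]]
            n2[u] = [x, y, v]
            n2[v] = n2[v] + [u]
            yield n2, leaf_label


def _nni_neighbors(adj, leaf_label):
    for u, v in _edges(adj):
        if len(adj[u]) != 3 or len(adj[v]) != 3:
            continue
        us = [x for x in adj[u] if x != v]
        vs = [x for x in adj[v] if x != u]
        for i in (0, 1):
            a, b = us[0], vs[i]
            n2 = _copy(adj)
            n2[u] = [b if x == a else x for x in n2[u]]
            n2[v] = [a if x == b else x for x in n2[v]]
            n2[a] = [v if x == u else x for x in n2[a]]
            n2[b] = [u if x == v else x for x in n2[b]]
            yield n2, leaf_label


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

@dataclass
class SearchConfig:
    criterion: str = "equal"          # "equal" or "implied"
    k: float = 12.0                   # concavity constant for implied weights
    n_replicates: int = 10
    swap: str = "SPR"                 # "SPR" or "NNI"
    max_trees: int = 500
    constraint: Topology | None = None
    seed: int = 0
    collapse_zero: bool = True        # collapse min-length-0 branches pre-consensus

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.criterion not in ("equal", "implied"):
            raise ValueError("criterion must be 'equal' or 'implied'")
        if self.criterion == "implied" and self.k <= 0:
            raise ValueError("concavity constant k must be positive")
        if self.swap not in ("SPR", "NNI"):
            raise ValueError("swap must be 'SPR' or 'NNI'")


@dataclass
class SearchResult:
    best_score: float
    trees: list[Topology]
    consensus: Topology
    log: list[dict] = field(default_factory=list)


def search(m: CharacterMatrix, cfg: SearchConfig) -> SearchResult:
    """Random-addition + branch-swapping parsimony search on ``m``."""
    rng = random.Random(cfg.seed)
    enc = _Encoded(m, treat_unordered=False)
    row_of = {t: i for i, t in enumerate(m.taxa)}
    ordered = m.ordered_flags()

    constraint_splits = None
    constraint_universe = None
    if cfg.constraint is not None:
        cleaves = set(leaf_labels(cfg.constraint))
        extra = cleaves - set(m.taxa)
        if extra:
            raise ValueError(f"constraint taxa not in matrix: {sorted(extra)}")
        constraint_splits = bipartitions(cfg.constraint)
        constraint_universe = frozenset(cleaves)

    def objective(steps: np.ndarray, mvec: np.ndarray) -> float:
        if cfg.criterion == "equal":
            return float(steps.sum())
        e = (steps - mvec).astype(float)
        return float((e / (e + cfg.k)).sum())

    def compatible(adj, leaf_label) -> bool:
        if constraint_splits is None:
            return True
        present = set(leaf_label.values()) & constraint_universe
        if len(present) < 3:
            return True
        want = _restrict_split_set(constraint_splits, constraint_universe, present)
        have = _restrict_split_set(_splits(adj, leaf_label), set(leaf_label.values()), present)
        return want <= have

    full_mvec = np.array(
        [min_steps(m.column(j), ordered=ordered[j]) for j in range(m.n_char)],
        dtype=np.int64,
    )

    best_score = math.inf
    best: dict[frozenset, tuple] = {}
    log: list[dict] = []

    for rep in range(cfg.n_replicates):
        order = list(m.taxa)
        rng.shuffle(order)
        adj = {0: [3], 1: [3], 2: [3], 3: [0, 1, 2]}
        leaf_label = {0: order[0], 1: order[1], 2: order[2]}
        counter = 4
        if not compatible(adj, leaf_label):  # only possible with a 3-leaf constraint
            raise RuntimeError("initial triplet violates the constraint")
        for label in order[3:]:
            chosen = None
            chosen_score = math.inf
            sub_rows = [row_of[x] for x in leaf_label.values()] + [row_of[label]]
            mvec = np.array(
                [
                    min_steps([m.cells[i][j] for i in sub_rows], ordered=ordered[j])
                    for j in range(m.n_char)
                ],
                dtype=np.int64,
            )
            for edge in _edges(adj):
                cand = _attach(adj, leaf_label, counter, edge, label)
                if not compatible(cand[0], cand[1]):
                    continue
                sc = objective(_char_steps(cand[0], cand[1], row_of, enc), mvec)
                if sc < chosen_score:
                    chosen_score = sc
                    chosen = cand
            if chosen is None:
                raise RuntimeError(
                    f"no constraint-compatible attachment for taxon {label!r}"
                )
            adj, leaf_label, counter = chosen
        score = objective(_char_steps(adj, leaf_label, row_of, enc), full_mvec)
        start_score = score
        neighbors = _spr_neighbors if cfg.swap == "SPR" else _nni_neighbors
        iters = 0
        improved = True
        while improved:
            improved = False
            iters += 1
            for n_adj, n_lab in neighbors(adj, leaf_label):
                if not compatible(n_adj, n_lab):
                    continue
                sc = objective(_char_steps(n_adj, n_lab, row_of, enc), full_mvec)
                if sc < score - 1e-12:
                    adj, leaf_label, score = _copy(n_adj), dict(n_lab), sc
                    improved = True
                    break  # first-found strict improvement, then re-enumerate
        log.append({"replicate": rep, "start": start_score, "final": score, "iterations": iters})
        key = _splits(adj, leaf_label)
        if score < best_score - 1e-12:
            best_score = score
            best = {key: (adj, leaf_label)}
        elif abs(score - best_score) <= 1e-12 and key not in best and len(best) < cfg.max_trees:
            best[key] = (adj, leaf_label)

    trees = [_to_topology(a, l) for a, l in best.values()]
    if cfg.collapse_zero:
        trees = [collapse_zero_length_branches(m, t) for t in trees]
    cons = strict_consensus(trees) if len(trees) > 1 else trees[0]
    return SearchResult(best_score=best_score, trees=trees, consensus=cons, log=log)


def strict_consensus(trees) -> Topology:
    """Tree containing exactly the splits shared by every input tree."""
    trees = list(trees)
    if not trees:
        raise ValueError("no trees given")
    universes = [frozenset(leaf_labels(t)) for t in trees]
    if len(set(universes)) != 1:
        raise ValueError("trees have differing leaf sets")
    universe = universes[0]
    common = bipartitions(trees[0])
    for t in trees[1:]:
        common &= bipartitions(t)
    ref = min(universe)

    def build(leafset, splits):
        inner = [s for s in splits if s < leafset]
        maximal = [s for s in inner if not any(s < o for o in inner)]
        used = frozenset().union(*maximal) if maximal else frozenset()
        parts = [build(s, [x for x in inner if x <= s]) for s in maximal]
        parts += sorted(leafset - used)
        if len(parts) == 1:
            return parts[0]
        return "(" + ",".join(parts) + ")"

    body = build(universe - {ref}, list(common))
    if body.startswith("("):
        newick = f"({ref},{body[1:-1]});"
    else:
        newick = f"({ref},{body});"
    return parse_newick(newick)


def collapse_zero_length_branches(
    m: CharacterMatrix, t: Topology, *, treat_unordered: bool = False
) -> Topology:
    """Collapse internal branches whose minimum optimized length is zero.

    A branch has minimum length zero when, for *every* character, some
    most-parsimonious reconstruction places no change on it (TNT's
    "rule 1" collapsing). Applied to best trees before consensus building.
    """
    from .parsimony import _up_pass

    t2 = t.clone(depth=1)
    enc = _Encoded(m, treat_unordered)
    children, order, leaf_row, nodes = _tree_arrays(t2, m.taxa)
    down, cmin = _down_pass(children, order, leaf_row, enc)
    up = _up_pass(children, order, leaf_row, enc, down, cmin)
    root = order[-1]
    total = down[root].min(axis=1)
    parent = [-1] * len(order)
    for k in order:
        for c in children[k]:
            parent[c] = k
    to_collapse = []
    root_kids = children[root]
    for k in order:
        if not children[k] or k == root:
            continue  # leaves keep their branches; root has no parent branch
        p = parent[k]
        if p == root and len(root_kids) == 2:
            o = next(c for c in root_kids if c != k)
            forced = down[k] + down[o]
        else:
            forced = down[k] + (down[p] - cmin[k]) + up[p]
        if bool((forced.min(axis=1) == total).all()):
            to_collapse.append(nodes[k])
    for node in to_collapse:
        node.edge.collapse()
    return parse_newick(t2.as_string(schema="newick"))
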