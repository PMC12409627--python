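"""Synthetic character matrices with controlled phylogenetic signal.

Two generation modes on a known tree with branch lengths (expected
substitutions per character at unit rate):

* ``mk`` -- each character draws a rate multiplier from a gamma
  distribution (mean 1, shape ``gamma_shape``), a state count k from
  ``states_per_char``, and evolves down the tree under the symmetric
  k-state Mk chain (Jukes-Cantor-like closed form for the per-branch
  transition probability). Higher rates produce more homoplasy.
* ``homoplasy_free`` -- each character marks a single randomly chosen
  internal edge: binary states constant on each side of the edge, so every
  character has exactly one change on the generating tree (s_i = m_i = 1,
  CI = RI = 1, RHI = 0).

Afterwards, a fraction of cells is set MISSING completely at random, and a
fraction of the remaining cells is widened to a two-state polymorphism
containing the true state. The per-character true ancestral assignments and
change counts are returned alongside the matrix, so parsimony's
lower-bound property (s_i <= true changes) is directly checkable.
"""
from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import pandas as pd

from .matrix import MISSING, CharacterMatrix, CharacterMeta
from .parsimony import char_lengths
from .trees import Topology, leaf_labels, random_topology, write_newick

#: Morphological matrices are dominated by binary characters; the default
#: state-count distribution reflects that (2-5 states).
DEFAULT_STATE_DIST = {2: 0.60, 3: 0.25, 4: 0.10, 5: 0.05}


@dataclass
class SimulationConfig:
    tree: Topology
    n_chars: int = 100
    mode: str = "mk"                              # "mk" or "homoplasy_free"
    rate: float = 1.0                             # global rate multiplier
    gamma_shape: float = 1.0                      # among-character rate variation
    states_per_char: dict = field(default_factory=lambda: dict(DEFAULT_STATE_DIST))
    missing_fraction: float = 0.0
    polymorphic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_chars < 1:
            raise ValueError("n_chars must be >= 1")
        if not (0 <= self.missing_fraction < 1 and 0 <= self.polymorphic_fraction < 1):
            raise ValueError("fractions must lie in [0, 1)")
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.mode not in ("mk", "homoplasy_free"):
            raise ValueError("mode must be 'mk' or 'homoplasy_free'")


def sim_tree(n_taxa: int, seed: int, *, edge_length: float = 0.3) -> Topology:
    """Random uniform topology with constant branch lengths, for simulations."""
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    t = random_topology(labels, seed)
    for e in t.edges():
        if e.head_node is not t.seed_node:
            e.length = edge_length
    return t


def _p_same(k: int, subs: float) -> float:
    """Probability an Mk chain ends in its starting state after ``subs``
    expected substitutions."""
    return 1.0 / k + (k - 1.0) / k * math.exp(-subs * k / (k - 1.0))


def simulate_matrix(cfg: SimulationConfig):
    """Generate (CharacterMatrix, truth) under ``cfg``. Deterministic by seed.

    ``truth`` records, per character, the state at every node (keyed by the
    leaf label or by ``n<i>`` postorder labels for internal nodes) and the
    true number of changes on the generating tree.
    """
    rng = random.Random(cfg.seed)
    t = cfg.tree
    nodes = list(t.postorder_node_iter())
    names = {}
    n_internal = 0
    for nd in nodes:
        if nd.is_leaf():
            names[id(nd)] = nd.taxon.label
        else:
            names[id(nd)] = f"n{n_internal}"
            n_internal += 1
    taxa = leaf_labels(t)
    root = t.seed_node

    assignments: list[dict] = []
    changes: list[int] = []
    cells: dict[str, list] = {lab: [] for lab in taxa}

    if cfg.mode == "homoplasy_free":
        internal_edges = [
            nd for nd in t.preorder_node_iter()
            if nd is not root and not nd.is_leaf()
        ]
        if not internal_edges:
            raise ValueError(
                "homoplasy_free mode needs at least one internal edge "
                "(the tree is a star)"
            )

    for _ in range(cfg.n_chars):
        state: dict[int, int] = {}
        nchanges = 0
        if cfg.mode == "mk":
            k = rng.choices(
                list(cfg.states_per_char), weights=list(cfg.states_per_char.values())
            )[0]
            r = cfg.rate * rng.gammavariate(cfg.gamma_shape, 1.0 / cfg.gamma_shape)
            state[id(root)] = rng.randrange(k)
            for nd in t.preorder_node_iter():
                if nd is root:
                    continue
                length = nd.edge.length if nd.edge.length is not None else 0.0
                parent_state = state[id(nd.parent_node)]
                if rng.random() < _p_same(k, r * length):
                    state[id(nd)] = parent_state
                else:
                    others = [s for s in range(k) if s != parent_state]
                    state[id(nd)] = rng.choice(others)
                if state[id(nd)] != parent_state:
                    nchanges += 1
        else:
            mark = rng.choice(internal_edges)
            below = {id(x) for x in mark.preorder_iter()}
            for nd in t.preorder_node_iter():
                state[id(nd)] = 1 if id(nd) in below else 0
            nchanges = 1
        assignments.append({names[id(nd)]: state[id(nd)] for nd in nodes})
        changes.append(nchanges)
        for lf in t.leaf_node_iter():
            cells[lf.taxon.label].append(frozenset({state[id(lf)]}))

    # inject MISSING (MCAR), then widen some scored cells to polymorphisms
    k_of_char = [
        max(max(c) for c in (cells[lab][j] for lab in taxa)) + 1
        if any(cells[lab][j] for lab in taxa) else 2
        for j in range(cfg.n_chars)
    ]
    for lab in taxa:
        for j in range(cfg.n_chars):
            if rng.random() < cfg.missing_fraction:
                cells[lab][j] = MISSING
            elif rng.random() < cfg.polymorphic_fraction:
                true = next(iter(cells[lab][j]))
                k = max(k_of_char[j], 2)
                other = rng.randrange(k - 1)
                if other >= true:
                    other += 1
                cells[lab][j] = frozenset({true, other})

    matrix = CharacterMatrix(
        taxa,
        [cells[lab] for lab in taxa],
        [CharacterMeta(j + 1) for j in range(cfg.n_chars)],
    )
    truth = {
        "mode": cfg.mode,
        "seed": cfg.seed,
        "tree": write_newick(t),
        "assignments": assignments,
        "changes": changes,
    }
    return matrix, truth


def truth_score(matrix: CharacterMatrix, truth: dict, tree: Topology) -> pd.DataFrame:
    """Observed vs true change counts per character on the generating tree.

    Parsimony never overestimates: ``s <= true_changes`` holds per
    character, with equality in homoplasy_free mode.
    """
    if len(truth["changes"]) != matrix.n_char:
        raise ValueError("truth record does not match the matrix's characters")
    s = char_lengths(matrix, tree)
    return pd.DataFrame(
        {
            "char": [cm.index for cm in matrix.char_meta],
            "true_changes": truth["changes"],
            "s": s.astype(int),
        }
    )
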