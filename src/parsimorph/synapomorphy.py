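"""Synapomorphy mapping: per-branch character-state transitions on a tree.

A character optimizes a change on the branch from parent to child when the
two nodes' MPR state sets differ. The change is *unambiguous* when the sets
are disjoint (every most-parsimonious reconstruction places a change on the
branch); otherwise it is reported but flagged ambiguous. Because transition
polarity depends on root placement, the caller designates an outgroup taxon
used to orient the tree (default: the matrix's first taxon).

Reports use the conventional ``char. N: a > b`` notation, with multi-state
MPR sets printed as ``{a,b} > c``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, CharacterMatrix
from .parsimony import MAX_STATES, _down_pass, _Encoded, _tree_arrays, _up_pass
from .trees import Topology, is_binary, leaf_labels


def _fmt_states(states: frozenset) -> str:
    if len(states) == 1:
        return str(next(iter(states)))
    return "{" + ",".join(str(s) for s in sorted(states)) + "}"


@dataclass(frozen=True)
class Transition:
    clade: frozenset          # leaf set of the child side of the branch
    char_index: int           # 1-based character number
    from_states: frozenset
    to_states: frozenset
    unambiguous: bool

    def __str__(self) -> str:
        return (
            f"char. {self.char_index}: "
            f"{_fmt_states(self.from_states)} > {_fmt_states(self.to_states)}"
        )


@dataclass
class SynapomorphyReport:
    transitions: list[Transition]

    def for_clade(self, clade) -> list[Transition]:
        clade = frozenset(clade)
        return [tr for tr in self.transitions if tr.clade == clade]

    def unambiguous(self) -> list[Transition]:
        return [tr for tr in self.transitions if tr.unambiguous]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clade": [",".join(sorted(tr.clade)) for tr in self.transitions],
                "char": [tr.char_index for tr in self.transitions],
                "from": [_fmt_states(tr.from_states) for tr in self.transitions],
                "to": [_fmt_states(tr.to_states) for tr in self.transitions],
                "unambiguous": [tr.unambiguous for tr in self.transitions],
            }
        )


def _rooted_at_outgroup(t: Topology, outgroup: str) -> Topology:
    t2 = t.clone(depth=1)
    leaf = None
    for lf in t2.leaf_node_iter():
        if lf.taxon.label == outgroup:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"outgroup {outgroup!r} not a leaf of the tree")
    t2.reroot_at_edge(leaf.edge, update_bipartitions=False)
    t2.suppress_unifurcations()
    return t2


def map_synapomorphies(
    m: CharacterMatrix,
    t: Topology,
    *,
    outgroup: str | None = None,
    treat_unordered: bool = False,
) -> SynapomorphyReport:
    """All per-branch state transitions of ``m`` optimized on ``t``.

    ``t`` must be fully resolved (polytomies make branch-wise optimization
    ill-defined; resolve first or run per resolution). Characters entirely
    MISSING within a clade yield no report on that clade's branches.
    """
    if set(leaf_labels(t)) != set(m.taxa):
        diff = set(leaf_labels(t)) ^ set(m.taxa)
        raise ValueError(f"tree/matrix taxon mismatch: {sorted(diff)}")
    if not is_binary(t):
        raise ValueError(
            "reference tree has polytomies: resolve it (or map per resolution) "
            "before synapomorphy optimization"
        )
    if outgroup is None:
        outgroup = m.taxa[0]
    t2 = _rooted_at_outgroup(t, outgroup)

    enc = _Encoded(m, treat_unordered)
    children, order, leaf_row, nodes = _tree_arrays(t2, m.taxa)
    down, cmin = _down_pass(children, order, leaf_row, enc)
    up = _up_pass(children, order, leaf_row, enc, down, cmin)
    root = order[-1]
    total = down[root].min(axis=1)  # (C,)

    # per node: optimal-state mask, clade leaf set, any-scored-in-clade mask
    opt: list[np.ndarray] = [None] * len(order)  # type: ignore[list-item]
    clade: list[frozenset] = [frozenset()] * len(order)
    scored: list[np.ndarray] = [None] * len(order)  # type: ignore[list-item]
    for k in order:
        opt[k] = (down[k] + up[k] == total[:, None]) & enc.alphabet
        if leaf_row[k] >= 0 and not children[k]:
            label = m.taxa[leaf_row[k]]
            clade[k] = frozenset({label})
            scored[k] = np.array(
                [cell is not MISSING for cell in m.cells[leaf_row[k]]]
            )
        else:
            clade[k] = frozenset().union(*(clade[c] for c in children[k]))
            scored[k] = np.logical_or.reduce([scored[c] for c in children[k]])

    out: list[Transition] = []
    for k in order:
        for c in children[k]:
            pmask, cmask = opt[k], opt[c]
            for j in range(enc.n_char):
                if not scored[c][j]:
                    continue  # character unobserved across the whole clade
                pj, cj = pmask[j], cmask[j]
                if np.array_equal(pj, cj):
                    continue
                from_states = frozenset(int(s) for s in range(MAX_STATES) if pj[s])
                to_states = frozenset(int(s) for s in range(MAX_STATES) if cj[s])
                out.append(
                    Transition(
                        clade=clade[c],
                        char_index=m.char_meta[j].index,
                        from_states=from_states,
                        to_states=to_states,
                        unambiguous=pj.dot(cj) == 0,
                    )
                )
    out.sort(key=lambda tr: (sorted(tr.clade), tr.char_index))
    return SynapomorphyReport(out)


@dataclass
class CladeConsistency:
    """Unambiguous stem transitions of one clade across reference trees."""

    table: pd.DataFrame        # char/from/to with supporting reference names
    absent_in: list[str]       # references where the clade is not monophyletic

    @property
    def consistent(self) -> pd.DataFrame:
        """Transitions present in every reference containing the clade."""
        return self.table[self.table["in_all"]]


def consistent_synapomorphies(
    m: CharacterMatrix,
    refs: dict,
    clade,
    *,
    outgroup: str | None = None,
    treat_unordered: bool = False,
) -> CladeConsistency:
    """Intersect a clade's unambiguous stem synapomorphies across scaffolds.

    ``refs`` maps reference names to topologies sharing the matrix's taxa.
    For each reference in which ``clade`` is monophyletic, the unambiguous
    transitions on the clade's stem branch are collected; each distinct
    transition is tagged with its supporting references and with whether it
    appears in *all* clade-bearing references.
    """
    clade = frozenset(clade)
    support: dict[tuple, set] = {}
    absent: list[str] = []
    present: list[str] = []
    for name, t in refs.items():
        report = map_synapomorphies(
            m, t, outgroup=outgroup, treat_unordered=treat_unordered
        )
        stem = report.for_clade(clade)
        if not any(tr.clade == clade for tr in report.transitions):
            # the clade may be monophyletic yet change-free; distinguish
            labels = {frozenset(c) for c in _all_clades(t, outgroup or m.taxa[0])}
            if clade not in labels:
                absent.append(name)
                continue
        present.append(name)
        for tr in stem:
            if tr.unambiguous:
                key = (tr.char_index, tr.from_states, tr.to_states)
                support.setdefault(key, set()).add(name)
    rows = []
    for (char, f, to), names in sorted(support.items()):
        rows.append(
            {
                "char": char,
                "from": _fmt_states(f),
                "to": _fmt_states(to),
                "supported_by": ",".join(sorted(names)),
                "n_refs": len(names),
                "in_all": len(names) == len(present),
            }
        )
    table = pd.DataFrame(rows, columns=["char", "from", "to", "supported_by", "n_refs", "in_all"])
    return CladeConsistency(table=table, absent_in=absent)


def _all_clades(t: Topology, outgroup: str):
    t2 = _rooted_at_outgroup(t, outgroup)
    for n in t2.postorder_node_iter():
        if not n.is_leaf():
            yield frozenset(lf.taxon.label for lf in n.leaf_iter())
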