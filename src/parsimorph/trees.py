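"""Topology handling: Newick I/O, random topologies, pruning, bipartitions.

Trees are represented as :class:`dendropy.Tree` objects. Parsimony and
distance computations treat them as *unrooted* leaf-labeled topologies:
branch lengths and support annotations present in input files are parsed
and ignored for scoring (a notice is logged).
"""
from __future__ import annotations

import logging
import random
from typing import Iterable, Sequence

import dendropy

log = logging.getLogger(__name__)

Topology = dendropy.Tree


def parse_newick(text: str) -> Topology:
    """Parse one Newick string into a topology."""
    try:
        t = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy's parse errors are not ValueErrors
        raise ValueError(f"invalid Newick: {exc}") from exc
    labels = leaf_labels(t)
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")
    if any(e.length is not None for e in t.edges()):
        log.info("branch lengths present in input tree; ignored for scoring")
    return t


def read_newick(path) -> Topology:
    with open(path) as fh:
        return parse_newick(fh.read())


def read_newick_list(path) -> list[Topology]:
    """Read a multi-tree Newick file."""
    trees = dendropy.TreeList.get(
        path=str(path), schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    return [parse_newick(t.as_string(schema="newick")) for t in trees]


def write_newick(t: Topology) -> str:
    return (
        t.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
    )


def leaf_labels(t: Topology) -> list[str]:
    return [lf.taxon.label for lf in t.leaf_node_iter()]


def is_binary(t: Topology) -> bool:
    """True when every internal node has unrooted degree exactly 3.

    A degree-2 root (rooted binary Newick) is accepted: suppressing it
    yields an unrooted binary tree.
    """
    seed = t.seed_node
    for n in t.preorder_node_iter():
        deg = len(n.child_nodes()) + (0 if n is seed else 1)
        if n.is_leaf():
            continue
        if n is seed:
            if deg not in (2, 3):
                return False
        elif deg != 3:
            return False
    return True


# ---------------------------------------------------------------------------
# random topologies (uniform over labeled binary shapes)
# ---------------------------------------------------------------------------

class _N:
    __slots__ = ("label", "children")

    def __init__(self, label=None):
        self.label = label
        self.children = []


def _to_newick(node: _N) -> str:
    if not node.children:
        return node.label
    return "(" + ",".join(_to_newick(c) for c in node.children) + ")"


def random_topology(labels: Sequence[str], rng_seed) -> Topology:
    """Uniform random fully-resolved unrooted topology on ``labels``.

    Leaves are attached sequentially, each to an edge chosen uniformly from
    the current tree; after all n leaves this yields every one of the
    (2n-5)!! labeled binary topologies with equal probability. Used as the
    null-topology sampler for the relative homoplasy index. Deterministic
    given ``rng_seed`` (an int or a ``random.Random``).
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be unique")
    rng = rng_seed if isinstance(rng_seed, random.Random) else random.Random(rng_seed)
    root = _N()
    root.children = [_N(labels[0]), _N(labels[1]), _N(labels[2])]
    # every non-root node stands for the edge above it
    edges: list[tuple[_N, _N]] = [(root, c) for c in root.children]
    for label in labels[3:]:
        parent, child = edges[rng.randrange(len(edges))]
        mid = _N()
        leaf = _N(label)
        mid.children = [child, leaf]
        parent.children[parent.children.index(child)] = mid
        edges.append((mid, child))
        edges.append((mid, leaf))
        edges[edges.index((parent, child))] = (parent, mid)
    return parse_newick(_to_newick(root) + ";")


def restrict_to(t: Topology, keep: Iterable[str]) -> Topology:
    """Induced topology on the taxa in ``keep`` (degree-2 nodes suppressed)."""
    keep = set(keep)
    have = set(leaf_labels(t))
    unknown = keep - have
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    if len(keep) < 3:
        raise ValueError("need at least 3 retained taxa")
    if keep == have:
        return parse_newick(write_newick(t))
    sub = t.extract_tree_with_taxa_labels(labels=keep)
    return parse_newick(sub.as_string(schema="newick"))


# ---------------------------------------------------------------------------
# bipartitions
# ---------------------------------------------------------------------------

def bipartitions(t: Topology) -> frozenset:
    """Non-trivial splits of the unrooted topology.

    Each split is stored as the frozenset of leaf labels on the side *not*
    containing the lexicographically smallest leaf, so representations are
    canonical across rootings.
    """
    labels = leaf_labels(t)
    universe = frozenset(labels)
    ref = min(labels)
    out = set()
    for n in t.postorder_node_iter():
        if n.is_leaf() or n is t.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in n.leaf_iter())
        if ref in side:
            side = universe - side
        if 2 <= len(side) <= len(universe) - 2:
            out.add(side)
    return frozenset(out)


def displays(t: Topology, backbone: Topology) -> bool:
    """True when ``t`` restricted to the backbone's leaves contains every
    backbone split (the backbone may be multifurcating)."""
    common = set(leaf_labels(backbone)) & set(leaf_labels(t))
    if len(common) < 3:
        return True
    tb = backbone if common == set(leaf_labels(backbone)) else restrict_to(backbone, common)
    tt = restrict_to(t, common)
    return bipartitions(tb) <= bipartitions(tt)


def bipartition_table(t: Topology) -> str:
    """Splits as tab-separated leaf-set pairs, one per line."""
    universe = frozenset(leaf_labels(t))
    lines = []
    for side in sorted(bipartitions(t), key=lambda s: (len(s), sorted(s))):
        other = universe - side
        lines.append(",".join(sorted(side)) + "\t" + ",".join(sorted(other)))
    return "\n".join(lines)
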