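"""Robinson-Foulds distances between topologies.

Raw (unnormalized) symmetric-difference counts over non-trivial
bipartitions, computed on the unrooted view of each tree. Polytomies simply
contribute fewer splits, so a star tree is at distance k from any tree with
k internal splits.
"""
from __future__ import annotations

import pandas as pd

from .trees import Topology, bipartitions, leaf_labels, restrict_to


def rf_distance(a: Topology, b: Topology) -> int:
    """Robinson-Foulds distance |A ^ B| over non-trivial splits."""
    la, lb = set(leaf_labels(a)), set(leaf_labels(b))
    if la != lb:
        raise ValueError(f"leaf sets differ: {sorted(la ^ lb)}")
    return len(bipartitions(a) ^ bipartitions(b))


def format_range(values) -> str:
    """Render a set of distances the way comparative tables do.

    A single value prints as ``"20 (mean = 20)"``; a spread prints as
    ``"118-120 (mean = 118.7)"`` with the mean given to one decimal when
    not integral.
    """
    lo, hi = min(values), max(values)
    mean = sum(values) / len(values)
    mean_s = f"{mean:.10g}" if mean == int(mean) else f"{mean:.1f}"
    span = f"{lo}" if lo == hi else f"{lo}-{hi}"
    return f"{span} (mean = {mean_s})"


def rf_profile(trees, refs, *, tree_names=None, ref_names=None) -> pd.DataFrame:
    """Min/max/mean RF of each tree set against each reference topology.

    ``trees`` may hold several equally optimal trees; each is compared with
    each reference after both are restricted to their common leaf set. The
    result has one row per reference with columns ``min``, ``max``,
    ``mean`` and the formatted ``range`` string.
    """
    trees = list(trees)
    refs = list(refs)
    if not trees or not refs:
        raise ValueError("need at least one tree and one reference")
    if ref_names is None:
        ref_names = [f"ref{i + 1}" for i in range(len(refs))]
    rows = []
    for name, ref in zip(ref_names, refs):
        dists = []
        for t in trees:
            common = set(leaf_labels(t)) & set(leaf_labels(ref))
            if len(common) < 3:
                raise ValueError("fewer than 3 shared taxa between tree and reference")
            ta = restrict_to(t, common) if common != set(leaf_labels(t)) else t
            tb = restrict_to(ref, common) if common != set(leaf_labels(ref)) else ref
            dists.append(rf_distance(ta, tb))
        rows.append(
            {
                "reference": name,
                "min": min(dists),
                "max": max(dists),
                "mean": sum(dists) / len(dists),
                "range": format_range(dists),
            }
        )
    return pd.DataFrame(rows).set_index("reference")
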