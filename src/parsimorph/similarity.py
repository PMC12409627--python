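"""Pairwise taxon-similarity matrices over characters or character subsets.

similarity(a, b) = proportion of characters, among those scored (non-
MISSING) in *both* taxa, whose state sets match. The default match
criterion is non-empty intersection -- a polymorphic {0,1} matches either 0
or 1, consistent with treating ambiguity as uncertainty; an exact
set-equality mode is available. The exported ordered matrix is the numeric
substrate for heatmap figures.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, CharacterMatrix
from .trees import Topology

log = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    taxa: list[str]
    values: np.ndarray          # float, NaN where no comparable characters
    comparable_counts: np.ndarray
    dropped: list[str]          # taxa with zero scored characters in partition

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep="NA")


def _ladder_order(t: Topology) -> list[str]:
    t2 = t.clone(depth=1)
    t2.ladderize()
    return [lf.taxon.label for lf in t2.leaf_node_iter()]


def similarity_matrix(
    m: CharacterMatrix,
    partition=None,
    taxon_order=None,
    *,
    exact: bool = False,
) -> SimilarityMatrix:
    """Pairwise taxon similarity over the characters in ``partition``.

    ``partition`` is a set of 1-based character numbers (default: all).
    Taxa with no scored character in the partition are dropped with a
    logged notice. ``taxon_order`` may be a list of labels or a reference
    topology, whose ladderized leaf sequence then orders rows/columns.
    """
    index_of = {cm.index: j for j, cm in enumerate(m.char_meta)}
    if partition is None:
        cols = list(range(m.n_char))
    else:
        partition = sorted(set(partition))
        if not partition:
            raise ValueError("empty character partition")
        bad = [i for i in partition if i not in index_of]
        if bad:
            raise ValueError(f"characters not in matrix: {bad}")
        cols = [index_of[i] for i in partition]

    taxa = list(m.taxa)
    scored = {
        t: any(m.cells[m.taxa.index(t)][j] is not MISSING for j in cols) for t in taxa
    }
    dropped = [t for t in taxa if not scored[t]]
    for t in dropped:
        log.warning("taxon %r has no scored characters in partition; dropped", t)
    taxa = [t for t in taxa if scored[t]]

    if taxon_order is not None:
        order = (
            _ladder_order(taxon_order)
            if isinstance(taxon_order, Topology)
            else list(taxon_order)
        )
        missing = set(taxa) - set(order)
        if missing:
            raise ValueError(f"taxon_order lacks matrix taxa: {sorted(missing)}")
        taxa = [t for t in order if t in set(taxa)]

    n = len(taxa)
    rows = [m.cells[m.taxa.index(t)] for t in taxa]
    values = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=int)
    for a in range(n):
        for b in range(a, n):
            comp = match = 0
            for j in cols:
                ca, cb = rows[a][j], rows[b][j]
                if ca is MISSING or cb is MISSING:
                    continue
                comp += 1
                hit = (ca == cb) if exact else bool(ca & cb)
                match += hit
            counts[a, b] = counts[b, a] = comp
            if comp:
                values[a, b] = values[b, a] = match / comp
    return SimilarityMatrix(taxa, values, counts, dropped)


def export_heatmap_table(sm: SimilarityMatrix, path) -> None:
    """Write the ordered similarity matrix as TSV (NA where incomparable)."""
    sm.to_tsv(path)
    for t in sm.dropped:
        log.warning("dropped taxon: %s", t)
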