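"""Ensemble homoplasy indices: CI, RI, and the relative homoplasy index.

The consistency index CI = M/S and retention index RI = (G-S)/(G-M) are the
classical ensemble measures (S observed steps, M minimum conceivable steps,
G maximum steps over topologies). Both depend on matrix dimensions and state
frequencies, which hampers comparison across datasets.

The relative homoplasy index (RHI) rescales the observed *excess* steps by
the excess expected when the tree carries no information about the matrix:

    RHI = (S - M) / (D_med - M)

where ``D_med`` is the median total length of the matrix over a null sample
of random fully-resolved topologies on the same taxa. RHI ~ 0 means no
homoplasy beyond the unavoidable minimum; RHI ~ 1 means the fixed tree
explains the data no better than a random one (a signal-free matrix). The
5%/95% quantiles of the null length sample give an interval: because a
*longer* null length makes the ratio smaller, the 95% length quantile yields
the lower bound and the 5% quantile the upper bound.

Following the procedure used for cross-dataset comparison, all characters
are treated as unordered for these indices by default.
"""
from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

import numpy as np

from .matrix import MISSING, CharacterMatrix, CharacterMeta
from .parsimony import StepCounts, _Encoded, char_lengths, tree_length
from .trees import Topology, leaf_labels, random_topology


def ensemble_indices(steps: StepCounts) -> tuple[float, float]:
    """Ensemble (CI, RI) from per-character step counts."""
    S, M, G = steps.S, steps.M, steps.G
    if S == 0:
        raise ValueError("CI undefined: total observed steps S = 0")
    if G == M:
        raise ValueError("RI undefined: G = M (no potential homoplasy in matrix)")
    return M / S, (G - S) / (G - M)


@dataclass
class HomoplasyResult:
    """Ensemble length and homoplasy indices for one matrix-tree pair."""

    L: int
    ci: float
    ri: float
    rhi: float
    rhi_lo: float
    rhi_hi: float
    null_n: int
    seed: int
    null_lengths: np.ndarray = field(repr=False)
    M: int = 0
    G: int = 0

    def to_json(self, **extra) -> str:
        rec = {
            "L": self.L,
            "CI": self.ci,
            "RI": self.ri,
            "RHI": self.rhi,
            "RHI_5": self.rhi_lo,
            "RHI_95": self.rhi_hi,
            "M": self.M,
            "G": self.G,
            "null_n": self.null_n,
            "seed": self.seed,
        }
        rec.update(extra)
        return json.dumps(rec, indent=2, sort_keys=True)


def null_length_sample(
    m: CharacterMatrix,
    null_n: int,
    seed: int,
    *,
    treat_unordered: bool = True,
) -> np.ndarray:
    """Total lengths of ``m`` on ``null_n`` seeded uniform random topologies.

    The topology stream is reproducible: a ``random.Random(seed)`` draws one
    sub-seed per replicate, which seeds the uniform topology sampler.
    """
    rng = random.Random(seed)
    enc = _Encoded(m, treat_unordered)
    out = np.empty(null_n, dtype=np.int64)
    for j in range(null_n):
        t = random_topology(m.taxa, rng.randrange(2**31))
        out[j] = int(char_lengths(m, t, _enc=enc).sum())
    return out


def rhi(
    m: CharacterMatrix,
    t: Topology,
    null_n: int = 1000,
    seed: int = 0,
    *,
    treat_unordered: bool = True,
    point_estimate: str = "median",
) -> HomoplasyResult:
    """Relative homoplasy index of matrix ``m`` given topology ``t``.

    The matrix should already be preprocessed (fossils pruned, invariant
    characters dropped). ``point_estimate`` may be ``"median"`` (default,
    robust) or ``"mean"``. Deterministic given ``seed``.
    """
    if set(leaf_labels(t)) != set(m.taxa):
        diff = set(leaf_labels(t)) ^ set(m.taxa)
        raise ValueError(f"tree/matrix taxon mismatch: {sorted(diff)}")
    steps = tree_length(m, t, treat_unordered=treat_unordered)
    ci, ri = ensemble_indices(steps)
    S, M = steps.S, steps.M
    D = null_length_sample(m, null_n, seed, treat_unordered=treat_unordered)
    center = float(np.median(D)) if point_estimate == "median" else float(np.mean(D))
    q5, q95 = (float(q) for q in np.quantile(D, [0.05, 0.95]))
    if center <= M:
        raise ValueError(
            "degenerate null: median null length does not exceed the minimum "
            f"length (median={center}, M={M})"
        )
    value = (S - M) / (center - M)
    lo = (S - M) / (q95 - M) if q95 > M else float("nan")
    hi = (S - M) / (q5 - M) if q5 > M else float("inf")
    return HomoplasyResult(
        L=S, ci=ci, ri=ri, rhi=value, rhi_lo=lo, rhi_hi=hi,
        null_n=null_n, seed=seed, null_lengths=D, M=M, G=steps.G,
    )


def permute_within_characters(
    m: CharacterMatrix, seed: int, *, keep_missing_fixed: bool = False
) -> CharacterMatrix:
    """Shuffle each column's cells among taxa, without replacement.

    Destroys phylogenetic signal while preserving every column's cell
    multiset (hence each character's marginal state frequencies, minimum
    and maximum step counts). By default MISSING entries are shuffled along
    with the scored cells; with ``keep_missing_fixed`` the missingness
    pattern stays in place and only scored cells are permuted among the
    scored positions.
    """
    rng = random.Random(seed)
    rows = [list(r) for r in m.cells]
    for j in range(m.n_char):
        col = [rows[i][j] for i in range(m.n_taxa)]
        if keep_missing_fixed:
            idx = [i for i, c in enumerate(col) if c is not MISSING]
            vals = [col[i] for i in idx]
            rng.shuffle(vals)
            for i, v in zip(idx, vals):
                col[i] = v
        else:
            rng.shuffle(col)
        for i in range(m.n_taxa):
            rows[i][j] = col[i]
    meta = [CharacterMeta(c.index, c.ordered, c.label) for c in m.char_meta]
    return CharacterMatrix(m.taxa, rows, meta)


@dataclass
class ImpliedWeightsFit:
    """Goloboff implied-weights fit: per-character f_i = e_i / (e_i + k)."""

    k: float
    f: np.ndarray

    @property
    def F(self) -> float:
        return float(self.f.sum())


def implied_weights_fit(steps: StepCounts, k: float = 12) -> ImpliedWeightsFit:
    """Implied-weights misfit of the step counts with concavity constant k.

    F = sum_i e_i/(e_i + k) is the quantity minimized by an implied-weights
    parsimony search; F = 0 iff no character shows extra steps.
    """
    if k <= 0:
        raise ValueError("concavity constant k must be positive")
    e = steps.e.astype(float)
    return ImpliedWeightsFit(k=k, f=e / (e + k))
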