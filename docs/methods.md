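# Methods

## Scope and model

`parsimorph` analyzes matrices of discrete morphological characters
(states 0–9) under maximum parsimony. A matrix cell is a *state set*: a
singleton for an ordinary observation, a larger set for polymorphism or
uncertainty (the two are deliberately not distinguished), or MISSING for
`?`/`-`. Scoring resolves every set most parsimoniously: the member state
that minimizes total steps is the one counted. A MISSING cell spans the
character's whole alphabet and can never force a step.

Trees are unrooted leaf-labeled topologies; branch lengths and support
values in input Newick are parsed and ignored. Multifurcations are accepted
both as scored trees (soft polytomies) and as backbone constraints.

## Parsimony engine

All scoring runs through one vectorized dynamic program over per-node cost
vectors c(v, s) (the minimum cost of the subtree below v given state s at
v), evaluated for every character simultaneously. The child-to-parent
transform is `min_t c(t) + w(t, s)` with w = 0/1 for unordered characters —
which reproduces Fitch parsimony exactly, including on polytomies — and
w = |t − s| for ordered (additive) characters, whose internal states may
pass through unobserved intermediate values. A second, pre-order pass
yields for every node the set of states attainable in at least one
most-parsimonious reconstruction (MPR sets), used for synapomorphy mapping.
Scores are invariant to the internal rooting used by the passes; this is
tested, as is exact agreement with brute-force enumeration over all
internal-state assignments on small trees.

Per-character bounds:

- minimum steps m: size of a minimum hitting set of the cell state-sets
  minus one, found by exact search over the ≤10 states — so a column
  variable only through overlapping polymorphisms correctly gets m = 0.
  For ordered characters m is the width of the shortest state interval
  intersecting every cell. (The package extends m to ordered characters so
  that extra steps e = s − m are never negative; the ensemble indices
  normally treat everything as unordered anyway, see below.)
- maximum steps g: star-topology length, `n_scored` minus the largest
  single-state count achievable when ambiguous cells are assigned to
  *minimize* that count; the minimal achievable maximum load is computed
  exactly from the Hall condition over state subsets. g is defined on
  unordered semantics; for matrices scored with ordered characters the
  ensemble RI is therefore a mild approximation.

## Homoplasy indices

CI = M/S and RI = (G−S)/(G−M) use the ensemble sums over retained
characters. The relative homoplasy index is

    RHI = (S − M) / (median(D) − M)

with D the total lengths of the matrix over `null_n` (default 1000)
topologies drawn *uniformly* from the (2n−5)!! labeled binary topologies by
sequential random attachment. The 5% and 95% quantiles of D (linear
interpolation) give the interval; since longer null trees shrink the ratio,
the 95% length quantile yields the lower bound. The point estimate uses the
null median for robustness; the mean is available as an option. The
uniform sampler is the documented default rather than an asserted
convention — other null generators (e.g. Yule) could be slotted in, and the
sampler is exposed and seeded so the stream is exactly replayable. For
cross-dataset comparability the index functions treat all characters as
unordered by default; per-matrix ordered flags can be honored instead.

Expected preprocessing before computing indices: prune taxa absent from
the reference topology (e.g. fossils), then drop characters whose minimum
steps are zero. The `permute_within_characters` control shuffles each
column among taxa without replacement, preserving the per-column cell
multiset (hence every m and g) while destroying phylogenetic signal; its
RHI should be ≈1, and the tests verify the 5–95% interval covers 1 on
simulated data. By default MISSING entries travel with the shuffle; a flag
keeps the missingness pattern fixed.

Implied-weights fit F = Σ e_i/(e_i + k) with concavity constant k
(default 12) is available both as a descriptive statistic and as the
search objective.

## Tree comparison and synapomorphies

Robinson–Foulds distances are raw symmetric-difference counts over
non-trivial bipartitions on the unrooted view (no normalization);
polytomies just contribute fewer splits. Multi-tree profiles report
min/max/mean per reference after restricting both trees to their common
leaf set, formatted as e.g. `118-120 (mean = 118.7)`.

A branch transition is reported when parent and child MPR sets differ, and
classified *unambiguous* when they are disjoint (every optimal
reconstruction places a change there). This is the disjoint-MPR-set
criterion; the alternative ACCTRAN/DELTRAN-agreement convention used by
some programs can classify borderline cases differently. Transition
polarity needs a root: the caller names an outgroup taxon. Characters
unobserved across an entire clade are never reported within it. The
cross-scaffold intersection utility tags each unambiguous stem transition
of a named clade with the reference topologies supporting it.

Taxon similarity is the proportion of mutually scored characters whose
state sets intersect (set equality available behind a flag); taxa with no
scored character in the chosen partition are dropped with a notice, and
rows can be ordered by a reference tree's ladderized leaf sequence for
heatmap rendering by any plotting layer.

## Search

Random-addition starts (each taxon placed at its best constraint-compatible
edge) followed by steepest-descent branch swapping, SPR by default, NNI as
the cheaper alternative; only strict improvements are accepted, ties in
first-found order under the seeded RNG. Backbone constraints are enforced
by split containment on the restriction to the constraint's taxa, at every
stage. Equally optimal distinct topologies are collected up to `max_trees`
(default 500) keyed by bipartition set; internal branches whose minimum
optimized length is zero (no character forces a change in any MPR) are
collapsed before the strict consensus is assembled. The search is a
deliberate desk-scale approximation: sectorial searches, ratchet, drift and
tree fusion are not replicated, so matching published shortest lengths on
large matrices is best-effort. On small problems the search provably
reaches the exhaustive optimum (tested against enumeration of all
topologies for up to 7 taxa).

## Synthetic data

The simulator emulates the statistical shape of a morphological matrix,
not its anatomy. In `mk` mode each character draws a gamma rate multiplier
(shape 1.0 by default), a state count from a binary-dominated distribution
(2:0.60, 3:0.25, 4:0.10, 5:0.05 — morphological matrices are mostly
binary), and evolves by the symmetric k-state Mk chain along a tree whose
branch lengths are expected substitutions (the default simulation tree uses
0.3 per edge). `homoplasy_free` mode marks one random internal edge per
character, guaranteeing s = m = 1 on the generating tree and hence
CI = RI = 1 and RHI = 0 exactly. Missing cells are injected completely at
random; a fraction of scored cells is widened to a two-state polymorphism
that always contains the true state, keeping the truth record
well-defined. The generator returns true ancestral assignments and change
counts, so parsimony's lower-bound property (s ≤ true changes) is asserted
directly.

What the simulator does *not* model: correlated characters, ascertainment
("variable-only" coding), hierarchically inapplicable characters, or
anatomically structured missingness. Passing tests therefore demonstrate
correctness of the algorithms and calibration of the indices under
idealized conditions, not robustness to those real-data complications.

## Numerical and design choices

- State alphabet capped at ten symbols (0–9); larger alphabets are
  rejected rather than remapped.
- Character numbering is 1-based everywhere a user sees it, matching the
  `char. 36: 2 > 1` reporting convention.
- Cost vectors use 64-bit integers with a large finite "infinity"; no
  floating point enters the step counts. Implied-weight objectives compare
  with a 1e-12 tolerance.
- Problem sizes in the test-suite simulations (up to 8 taxa × 500
  characters for recovery checks, 20–30 taxa for index calibration,
  null samples of 100–500 topologies, 200 brute-force comparison cases)
  were chosen so the whole suite and the acceptance script each run in a
  few minutes on one core while keeping sampling error well inside the
  asserted tolerances.
- All stochastic components (simulation, permutation, null topologies,
  search) are seeded; identical seeds give byte-identical outputs.

## Known limitations

- Step-matrix (Sankoff with arbitrary costs) characters are out of scope;
  only unordered and linearly ordered characters are supported.
- Soft-polytomy scoring of multifurcating trees may differ from programs
  that resolve polytomies before counting.
- g (and hence RI) uses unordered semantics even for ordered characters.
- The heuristic search makes no optimality guarantee beyond small n.
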