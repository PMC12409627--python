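# parsimorph

Parsimony scoring and homoplasy quantification for discrete morphological
character matrices.

Morphological datasets — the only data that can place fossils in a
phylogeny — often conflict sharply with molecular phylogenies, and a key
question for any such matrix is *how much homoplasy* (convergence,
parallelism, reversal) it carries relative to a given reference topology.
`parsimorph` is a toolkit for systematists who want to ask that question
quantitatively: it scores matrices on fixed or searched trees under maximum
parsimony, measures homoplasy with classical and null-calibrated indices,
maps synapomorphies onto molecular scaffold topologies, and compares trees
by Robinson–Foulds distance. A built-in Mk-model simulator makes the whole
pipeline testable end to end without any empirical data.

## The indices

For character *i* on a topology, let *s<sub>i</sub>* be its parsimony steps,
*m<sub>i</sub>* its minimum steps over all topologies and ambiguity
resolutions, and *g<sub>i</sub>* its maximum (star-topology) steps. With
ensemble sums S = Σs, M = Σm, G = Σg:

- **Consistency index** CI = M/S (1 = no homoplasy),
- **Retention index** RI = (G − S)/(G − M) (fraction of potential
  synapomorphy retained),
- **Relative homoplasy index** RHI = (S − M)/(D̃ − M), where D̃ is the
  median length of the matrix over a null sample of uniform random binary
  topologies on the same taxa. RHI ≈ 0 means essentially no homoplasy;
  RHI ≈ 1 means the reference tree explains the matrix no better than a
  random one. The 5%/95% quantiles of the null sample give an interval
  around the point estimate.

Because RHI is normalized by the dataset's own null expectation, it is
comparable across matrices of different sizes and state frequencies, which
CI and RI are not. Unordered characters are scored by Fitch parsimony,
ordered (additive) ones by a linear-cost dynamic program; polymorphic and
uncertain cells contribute their most parsimonious member state, and `?`
and `-` are both total ambiguity.

## Worked example

```python
from parsimorph import drop_invariant_characters, permute_within_characters, rhi
from parsimorph.simulate import SimulationConfig, sim_tree, simulate_matrix

tree = sim_tree(12, seed=1)
matrix, _ = simulate_matrix(SimulationConfig(
    tree=tree, n_chars=100, mode="mk", rate=1.0, seed=2, missing_fraction=0.2))
matrix, dropped = drop_invariant_characters(matrix)
print(f"{matrix.n_taxa} taxa, {matrix.n_char} characters retained "
      f"({len(dropped)} invariant dropped)")
res = rhi(matrix, tree, null_n=200, seed=3)
print(f"L = {res.L}  CI = {res.ci:.3f}  RI = {res.ri:.3f}")
print(f"RHI = {res.rhi:.3f}  [5%, 95%] = [{res.rhi_lo:.3f}, {res.rhi_hi:.3f}]")
perm = permute_within_characters(matrix, seed=4)
print(f"permuted RHI = {rhi(perm, tree, null_n=200, seed=3).rhi:.3f}")
```

prints

```
12 taxa, 87 characters retained (13 invariant dropped)
L = 235  CI = 0.528  RI = 0.410
RHI = 0.750  [5%, 95%] = [0.703, 0.816]
permuted RHI = 1.024
```

Read: at this simulation rate the matrix is strongly homoplastic (CI ≈ 0.5,
RHI 0.75) even on its own generating tree, and destroying the signal by
permuting states within characters pushes RHI to ≈ 1, the signal-free
ceiling.

The same workflows are available from the shell via the `parsimorph`
console script (`score`, `rhi`, `rf`, `search`, `synapo`, `simmatrix`,
`simulate`, `permute`); run `parsimorph --help`.

Matrices are read and written in NEXUS and TNT `xread` dialects, trees in
Newick. Preprocessing helpers cover taxon pruning (e.g. removing fossils
before comparative analyses) and removal of parsimony-invariant characters.

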