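# metanet

Network analysis of evolving metabolism for systems and evolutionary
biologists.  Metabolic enzymes (EC numbers) are organised by KEGG into
pathway *subnetworks* grouped into eleven *mesonetworks*; each SCOP
fold-family domain of an enzyme carries a phylogenomic age — a node
distance *nd* ∈ [0, 1], 0 being most ancient.  `metanet` turns such an
integrated table into a family of age-sliced bipartite networks and
computes the statistical battery that characterises how hierarchy,
modularity and small-world structure build up along the evolutionary
timeline.

## The model

An enzyme inherits its age from its domains: by default the *second
oldest* domain dates the enzyme (a cooption is dated by the accepting
context, not the ancient donor); the *oldest*-domain rule is available
as an alternative.  The [0, 1] timeline is cut into ten eras of width
0.1 (era 1 = [0, 0.1], later bins right-closed).

For each threshold *t* the category–enzyme bipartite graph restricted
to enzymes of age ≤ *t* is built at subnetwork or mesonetwork level
and decomposed into its two one-mode projections, with edge weight
w(u, v) = |N(u) ∩ N(v)|, the number of shared counterpart nodes.
Each slice of each graph is then measured:

* **Degree / diameter** — average degree 2|E|/|V|; diameter of the
  largest connected component (LCC).
* **Discrete power law** — maximum-likelihood exponent α of
  P(x) ∝ x^(−α) for x ≥ xmin (Hurwitz-zeta normalisation), xmin chosen
  to minimise the Kolmogorov–Smirnov distance; goodness-of-fit p-value
  by seeded semi-parametric bootstrap.  α ∈ (2, 3) with p ≥ 0.05 is the
  scale-free band.
* **Bartels rank von Neumann test** — RVN = Σ(Rᵢ−Rᵢ₊₁)² / Σ(Rᵢ−R̄)² on
  the midranks of the LCC degree sequence; E[RVN] = 2 under
  exchangeability; two-sided p from the symmetric Beta approximation
  of RVN/4.  Run on each graph and on a matched Erdős–Rényi graph.
* **Small-world coefficient** — S = (C_g/C_rand)/(L_g/L_rand), where
  C is mean local clustering (degree ≥ 2 nodes), L mean shortest-path
  length, and the null values are means over seeded ER G(n, m) graphs
  matched to the LCC.  S ≫ 1 indicates small-world structure.
* **Fast-greedy modularity** — agglomerative maximum-modularity
  communities (weighted by shared-enzyme counts) and the maximum Q.
* **Hierarchical modularity** — OLS slope of log₁₀ C(k) vs log₁₀ k;
  C(k) ~ k^(−1) is the hierarchical signature.
* **Centralities** — degree, unnormalised betweenness, closeness on
  the LCC with deterministic lexicographic tie-breaking.

Recruitment analyses add the subnetwork × era sharing matrix,
per-threshold mesonetwork link tables, classic Ward clustering
(squared Euclidean dissimilarities of adjacency rows) with a Newick
dendrogram, the scaled modularity-matrix heatmap B = A − kkᵀ/2m, Venn
superkingdom groups (15 nonempty subsets of {A, B, E, V}, with an
absolute-consensus rule for revised EC numbers), and functional /
catalytic-residue distributions.

A seeded generator produces synthetic datasets at the published scale
(11 mesonetworks, ~148 subnetworks, ~1,900 enzymes, biphasic domain
ages peaking in eras 1 and 6–8), so the entire pipeline is testable
without the original database.

## Worked example

```python
from metanet import (SimulationConfig, simulate_structure, assign_all_ages,
                     build_bipartite, project_one_mode, fit_power_law, small_world)

ds = simulate_structure(SimulationConfig(seed=42))
ages = assign_all_ages(ds)
b = build_bipartite(ds, ages, "subnetwork")
fit = fit_power_law([d for _, d in b.graph.degree()], reps=100, seed=42)
sw = small_world(project_one_mode(b, "enzyme"), n_rand=10, seed=42)
```

Running `python examples/04_statistical_battery.py` (which does the
above and more) prints:

```
bipartite degree power law: alpha=2.434 xmin=2 KS=0.0545 p=0.00
Bartels on degree sequence: RVN=1.442 stat=-12.65 p=4.11e-38
enzyme projection small world: C=0.885 L=2.40 C_rand=0.0774 L_rand=1.92 S=9.2
fast-greedy modularity of enzyme projection LCC: Q=0.443
C(k) scaling: slope=-0.02 r2=0.01 (257 degree classes)
```

The bipartite exponent sits in the scale-free band but the KS bootstrap
rejects a strict power law for this synthetic graph; the ordered degree
sequence is strongly non-random (RVN far below 2); the enzyme
projection is markedly small-world (S ≈ 9) and modular (Q ≈ 0.44),
while its flat C(k) reflects the clique-like co-membership structure of
the generator rather than hierarchical scaling.

The other scripts in `examples/` cover dataset simulation and
validation, age assignment and era binning, slicing and projections,
recruitment/annotation analyses, and the one-call pipeline.  The same
pipeline is scriptable from the shell:

```sh
metanet simulate --seed 1 --n-enzymes 500 --out data/
metanet all --seed 1 --out runs/demo
```

## Layout

```
src/metanet/      io, simulate, chronology, netbuild, netstats,
                  recruitment, pipeline, cli
examples/         one short narrative script per capability
tests/            unit, property and acceptance tests
docs/methods.md   models, defaults, numerical choices, limitations
```
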