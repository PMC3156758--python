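# semmod

Gene-module inference that fuses three independent lines of evidence about
every gene pair — co-expression, protein-interaction topology, and Gene
Ontology (GO) semantic similarity — into a single similarity and clusters
genes into modules with affinity propagation. It is aimed at systems
biologists who want modules that are not only tightly co-expressed and
densely interconnected but also strongly associated with known biological
function, because functional annotation enters the module construction
itself rather than only the post-hoc evaluation.

## Method

For every pair of genes *i*, *j* in the universe *V*:

- **Expression similarity** `e_ij`: Pearson correlation between expression
  profiles (pairwise-complete over observed conditions).
- **Topological similarity** `t_ij`: 1 for a direct interaction, otherwise
  `|N(i) ∩ N(j)| / min(k_i, k_j)` — the fraction of the smaller
  neighborhood shared (a classical topological-overlap variant is also
  available).
- **Semantic similarity** `g_ij`: Wang's GO-DAG measure on biological
  process annotations. Each term's S-value profile decays along
  child→parent edges with relation weights (is_a 0.8, part_of 0.6); two
  terms are compared by profile overlap, two genes by best-match averaging
  of their direct annotation sets. `g_ij` is 1 for identically annotated
  genes and 0 when either gene has no annotation.

Each channel is mapped through its empirical CDF over all `n(n-1)/2`
pairs, so a pair's value becomes `Pr(E ≤ e_ij)` etc., and the channels are
multiplied under an independence assumption:

    Pr(E ≤ e_ij, T ≤ t_ij, G ≤ g_ij) = Pr(E ≤ e_ij) · Pr(T ≤ t_ij) · Pr(G ≤ g_ij)

Affinity propagation takes `S_ij = Pr(...) − 1 ∈ [−1, 0]` as input; a
single shared *preference* controls the number of modules and can be
bisection-searched to hit a target module count, or swept to expose the
hierarchical structure of modules. Modules are scored by one-sided Fisher
exact enrichment (uncorrected), term-level sensitivity/specificity and
their harmonic mean *F*, coherency and depth of enriched terms, expression
homogeneity and clustering coefficient. A module can finally be extended
with interaction neighbors from outside the selected gene set, admitted
greedily when they raise the module's mean semantic similarity.

## Worked example

Everything runs on seeded synthetic data with planted modules, so the
example is fully self-contained:

```python
from semmod import *
from semmod.evaluation import fisher_enrichment, enrichment_summary
from sklearn.metrics import adjusted_rand_score

ds = generate_dataset(n_genes=120, n_modules=4, n_conditions=30, seed=1)
e = expression_similarity(ds.expression, ds.universe)
t = topological_overlap(ds.network, ds.universe)
g = pairwise_semantic_matrix(ds.annotations, ds.ontology)
sim = combine(e, t, g)
pref, modules = find_preference(sim, target_k=4)
print(f"preference = {pref:.3f}, modules = {modules.n_modules}")
print(f"ARI vs planted labels = "
      f"{adjusted_rand_score(ds.planted_array(), modules.label_array()):.3f}")
```

prints

```
preference = -15.000, modules = 4
ARI vs planted labels = 0.978
```

i.e. the preference search found a value yielding exactly 4 modules, and
the recovered partition agrees with the planted one almost perfectly
(adjusted Rand index 0.978; 1.0 is identity). Scoring the same modules:

```
sensitivity = 0.706, specificity = 1.000, F = 0.828
homogeneity = 0.754, clustering coefficient = 0.277
```

Every module is enriched for at least one term at p < 1e-4
(specificity 1), 70.6% of the terms annotating the universe are enriched
somewhere, and within-module profiles correlate at 0.75 on average.

The same pipeline is available from the shell:

```sh
semmod simulate --n-genes 120 --n-modules 4 --seed 1 --out-dir data/
semmod run --expression data/expression.tsv --network data/network.tsv \
    --obo data/ontology.obo --gaf data/annotations.gaf \
    --universe data/universe.txt --target-k 4 --out-dir out/
```

`out/` then holds the module assignment, enrichment tables, summary grids
and a provenance record (config, seed, version, input checksums) that
suffices to reproduce the run. Subcommands `similarity`, `integrate`,
`cluster`, `sweep`, `evaluate` and `extend` run individual stages on the
previous stage's files.

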