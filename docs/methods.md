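# Methods

## Similarity channels

The unit of analysis is the unordered gene pair within a user-supplied
universe *V* of genes of interest. Three channels are computed per pair.

**Expression (`e_ij`).** Pearson correlation over pairwise-complete
observations. Pairs sharing fewer than 3 observed conditions, and pairs
involving a zero-variance profile, are set to 0 (no evidence either way)
and logged. Range [−1, 1]; the diagonal is fixed at 1.

**Topology (`t_ij`).** Two modes:

- `direct_one` (default): `t_ij = 1` for a direct interaction, otherwise
  `|N(i) ∩ N(j)| / min(k_i, k_j)` when the smaller degree is positive,
  else 0. This makes any directly interacting pair maximally similar,
  which is the intended behavior of this pipeline: interactions are
  treated as strong evidence, not merely as one shared neighbor.
- `tom_standard`: the classical topological-overlap form
  `(|N(i) ∩ N(j)| + a_ij) / (min(k_i, k_j) + 1 − a_ij)`, for users who
  prefer the smoother score in which a direct edge alone does not
  saturate the similarity.

Neighborhoods are computed on the full interaction network, including
genes outside *V*, before the matrix is restricted to *V*; genes outside
*V* thus still contribute shared-neighbor evidence, mirroring the use of
a global interaction map around a selected gene set. A
`restrict_to_universe` flag computes them on the *V*-induced subgraph
instead.

**Semantics (`g_ij`).** Wang's GO semantic similarity on the
biological_process namespace. A term's S-value profile assigns 1 to the
term and to each ancestor the maximum over child→parent paths of the
product of relation weights (is_a 0.8, part_of 0.6, configurable; only
these two relations carry weights, so regulates-type edges are dropped at
parse time). Term similarity is `Σ_common (S_A + S_B) / (SV(A) + SV(B))`;
gene similarity is the best-match average over the two genes' DIRECT
annotation sets — ancestors already enter through the S-values, so
propagated sets are not used here. A gene without any direct BP
annotation scores 0 against every partner, including itself: absent
evidence of function is treated as no similarity, which also keeps the
channel's empirical CDF well defined. The ontology reader applies the
true-path rule separately for the enrichment statistics, which do use
propagated annotations (the standard convention for term gene-sets).

## Integration

Each channel's strictly-upper-triangle values define an empirical CDF
with the weak inequality `F(x) = #{v ≤ x}/n_pairs`, so the largest
observed value maps to probability 1 and ties share a probability. Channel
probabilities are multiplied under an independence assumption — reasonable
as a first approximation since the three channels derive from disjoint
data sources — giving a joint probability in (0, 1], and the affinity
propagation input is that joint minus 1, in [−1, 0]. Any subset of
channels can be combined (a constant channel is exactly neutral), which
supports ablation experiments.

## Clustering

Standard Frey–Dueck affinity propagation: damped responsibility and
availability sweeps on the shifted similarity with the globally shared
preference on the diagonal. Defaults: damping 0.9, max 1000 iterations,
convergence declared when the exemplar set `{k : r(k,k) + a(k,k) > 0}` is
unchanged for 100 consecutive sweeps. A seeded Gaussian perturbation of
relative scale 1e-12 breaks exact ties that would otherwise oscillate;
the seed is recorded in the output. After convergence, members are
assigned to their most similar exemplar and exemplars keep themselves;
the net similarity (member-to-exemplar similarities plus exemplar
preferences) is reported and, on small separated instances, matches the
exhaustive optimum over exemplar subsets in ≥ 95% of cases (verified in
the test suite). If no exemplar emerges the run aborts with advice to
raise the preference; non-convergence returns the current state flagged
`converged=False`.

`find_preference` bisects the preference on `[n·min(S), 0]` — doubling
the lower bound downward until the module count falls to or below the
target — exploiting the empirically monotone growth of the module count
with the preference; it stops at an exact hit or an interval narrower
than 1e-6 and returns the closest-count assignment (ties favor fewer
modules). `preference_sweep` clusters once per supplied preference;
coarser sets at more negative preferences are, on planted data, near
perfect unions of the finer sets' modules, which the conservation matrix
(per-pair co-clustering counts across sets) makes visible.

## Module scoring

- **Enrichment**: one-sided Fisher exact test (hypergeometric upper
  tail), no multiple-testing correction, term gene-sets from propagated
  annotations restricted to the assignment's universe, terms annotating
  zero universe genes skipped (minimum term size configurable, default 1).
- **Sensitivity / specificity / F**: number of distinct terms enriched in
  ≥ 1 module and number of modules enriched with ≥ 1 term at a threshold
  (default 1e-4), expressed as fractions of the eligible term universe
  and of the module count, so the harmonic mean is scale-consistent; the
  raw counts are reported alongside. A 10^-1…10^-20 threshold grid is
  emitted by `summary_grid`.
- **Coherency / depth**: among a module's enriched terms at p < 1e-5,
  the mean pairwise Wang similarity (needs ≥ 2 terms) and the mean
  shortest-path depth below the namespace root counting is_a and part_of
  edges equally; module averages are taken over modules meeting the
  respective minimum, with the excluded counts reported.
- **Homogeneity / connectivity**: mean within-module Pearson correlation
  (singletons excluded and logged) and mean local clustering coefficient
  of the module-induced subgraph with induced-degree-< 2 nodes
  contributing 0; overall values are unweighted means across modules.
- **Consensus**: for stochastic module sets, the co-clustering frequency
  matrix across runs is cut by average-linkage hierarchical clustering of
  1 − consensus into *k* groups (linkage configurable; average chosen as
  the least shape-biased default), exemplars set to consensus medoids.
- **Overlap**: full cross-tabulation of two module sets with counts and
  row fractions, for comparison against reference gene groupings.

## Module extension

Genes outside the selected set (the candidate pool, *V^C*) with at least
two direct interactions into the module are ranked once by that edge
count (ties broken lexicographically for determinism) and visited in a
single pass. A candidate is admitted iff its mean Wang similarity to all
current module genes strictly exceeds the module's mean pairwise
similarity, recomputed after every admission; equality rejects. Because
the new mean is a weighted average of the old mean and the candidate's
mean, every admission strictly raises the module mean — irrelevant
neighbors cannot accumulate. "More than one gene" is read as ≥ 2 module
interactions. The loop re-enters at the scoring step, not the ranking
step, so rejected candidates are not revisited after later admissions; a
re-scanning variant would admit weakly more genes and is deliberately not
the default. Optionally the same gate is applied to mean expression
correlation when candidate profiles exist (off by default).

## Synthetic data

The generator emulates the joint shape of a stress-response compendium:
`n_genes` split evenly into `n_modules`; expression = module prototype
(independent standard-normal draws per condition) + N(0, sd) gene noise;
network = planted partition (default p_in 0.3, p_out 0.02); ontology =
one root, one is_a chain of `terms_per_module` terms per module, and 5
shared background terms under the root; each gene annotated to a random
term of its module's chain with probability `annotation_fidelity`
(default 0.9), otherwise to a random background term. An
`outsider_fraction` of extra genes is generated outside the universe,
wired to a host module at p_in and annotated like its members — the
synthetic analogue of back nodes for extension tests. Three independent
random streams (expression / network / annotation) derive from the master
seed so toggling one component does not shift the others. The default
recovery fixture is 120 genes, 4 modules, 30 conditions, noise sd 0.5,
seed-reproducible bit for bit, and small enough that the full pipeline
runs in well under a second.

What the generator does **not** emulate: scale-free degree
distributions, realistic GO topology (DAG breadth, multiple parentage,
annotation depth skew), correlated noise across conditions, or
annotation bias toward well-studied genes. Passing the planted-recovery
tests therefore demonstrates that the machinery is correct and that the
integration behaves as designed under controlled evidence, not that the
method attains any particular accuracy on real compendia.

## Numerical choices and degenerate inputs

- ECDF uses the weak inequality, so all-tied channels give probability 1
  everywhere (neutral channel).
- Correlations with < 3 shared conditions or zero variance are 0, not
  NaN, so downstream CDFs stay defined.
- The joint-similarity diagonal is a placeholder; clustering overwrites
  self-similarity with the preference.
- Fisher p-values are clipped into (0, 1]; enrichment rows exist only
  for overlap ≥ 1.
- Unannotated-vs-unannotated gene pairs score 0 semantic similarity (a
  documented choice; the alternative of treating them as identical would
  inflate the channel for exactly the genes with least evidence).
- alt_id ontology identifiers resolve to their primary term; obsolete
  terms and their edges are dropped at parse time.
- GAF rows with a NOT qualifier, an excluded evidence code, an unknown
  term, or a malformed column count are skipped (malformed rows logged
  with their line number); a file with zero usable rows is an error.
- All evidence codes are included by default; an exclusion set (e.g.
  {IEA}) is a configuration option.

## Limitations

- Dense message passing is O(n²) memory and time per sweep; universes
  beyond ~10⁴ genes need a sparse variant, which is out of scope.
- Only the biological_process namespace is exercised by the test suite;
  molecular_function / cellular_component run behind the same switch but
  are untested against any reference behavior.
- The module-count-vs-preference relation is monotone only empirically;
  the bisection search therefore reports the closest achieved count when
  the exact target is unattainable.
- The independence assumption across channels is an approximation; no
  copula or rank-aggregation alternative is provided.
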