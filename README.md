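# ontonet

Ontology annotation analysis for arbitrary annotated entities — protein
domains, genes, RNA families, or anything else that can be annotated with
terms from a rooted directed acyclic graph (DAG). The package provides
three analyses behind one data model:

1. **DAG-aware enrichment** — which ontology terms are over-represented in
   an entity set of interest?
2. **Semantic-similarity networks** — how similar are two entities, judged
   by the information content of the ontology terms they share?
3. **Contact significance** — do two groups of entities occupy the same
   neighbourhood of a similarity network, judged by random walk with
   restart and a permutation null?

Everything works from plain text files (OBO ontologies or term/edge TSVs,
annotation TSVs, entity lists); no database or download is required, and a
synthetic-data generator with planted ground truth makes the whole stack
testable offline.

## The statistics at the core

**Enrichment.** For a background of $N$ annotatable entities, a term
annotating $K$ of them, and an input set of $n$ entities with overlap $x$,
the package computes the upper tail $P(X \ge x)$ under the hypergeometric
distribution, a binomial approximation with $q = K/N$, or a one-sided
Fisher exact test (identical to the hypergeometric tail). Because the
true-path rule makes a term inherit every annotation of its descendants,
raw per-term tests are correlated along the DAG; two decorrelation
algorithms are provided: *elim* (leaves first; a significant term's
entities are removed from its ancestors before they are tested) and
*parent–child* (each term is tested within its parents' annotation
universe). Adjustment across tested terms is Benjamini–Hochberg,
Bonferroni, or Holm.

**Similarity.** The information content of a term is
$IC(t) = -\log_{10}(n_t/N)$ with $n_t$ the propagated annotation count.
Term pairs are scored through their most informative common ancestor
(MICA) with the Resnik, Lin, Schlicker (relevance) or Jiang–Conrath
measure; entity pairs summarise the term-pair matrix between their
most-specific annotations with a best-match statistic (average, maximum,
or complete). All-pairs similarity yields a weighted undirected network;
per-sub-ontology networks can be additively combined into an overall one.

**Contact.** Each seed group (optionally weighted) is diffused over the
network by random walk with restart,
$p = (1-r)\,W p + r\,p_0$, and a group pair is scored by the inner product
of their stationary distributions. Significance is empirical: the walks
are repeated for uniformly resampled seed sets of the same size and weight
multiset, giving a permutation z-score and p-value per pair; pairs below
the BH-adjusted cutoff form the contact network.

## Worked example

```python
import ontonet as on

# a synthetic dataset with a planted enriched term
fx = on.planted_enrichment_fixture(on.FixtureSpec(seed=1))
res = on.enrich(fx.input_ids, fx.anno, fx.dag)
print(fx.planted_term)          # T0011
print(res.table.head(3)[["term_id", "K", "x", "pvalue", "adj_pvalue"]])
```

```
term_id   K   x        pvalue  adj_pvalue
  T0011  15  15  3.854286e-07    0.000011
  T0027   6   6  1.009801e-02    0.141372
  T0023   7   6  4.573805e-02    0.426888
```

The planted term `T0011` annotates 15 of the 40 background entities; all
15 of its annotated entities appear in the 20-entity input, an overlap
with hypergeometric tail probability $3.9\times10^{-7}$ — rank one by a
wide margin, exactly the planted signal. The same objects feed the other
two analyses:

```python
net = on.build_similarity_network(fx.input_ids[:8], fx.anno, fx.dag,
                                  measure="lin", bm="bm_average")
# SimilarityNetwork(8 nodes, 28 edges)

cnet_spec = on.FixtureSpec(seed=1)
g = on.clustered_network(cnet_spec)
seeds, planted_pair = on.planted_contact_seeds(cnet_spec, g)
contacts, sig = on.contact_pipeline(g, seeds, n_perm=1000, rng_seed=1)
print(contacts.zscore.round(2))
```

```
           cluster_a  cluster_b  scatter_a  scatter_b
cluster_a       3.02       0.65      -0.95      -1.28
cluster_b       0.65       3.01      -0.48      -1.15
scatter_a      -0.95      -0.48      -0.95      -1.06
scatter_b      -1.28      -1.15      -1.06       2.98
```

The two groups planted inside the network's dense cluster
(`cluster_a`–`cluster_b`, z = 0.65) attain the highest off-diagonal
z-score, ahead of every pair involving a scattered group.

The same analyses are available from the shell (`ontonet enrich`,
`ontonet simnet`, `ontonet rwr`, `ontonet build`, `ontonet export`,
`ontonet fixtures`); every run writes a manifest (config echo, rng seed,
library versions) next to its output, and identical manifests produce
byte-identical outputs.

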