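# Methods

This note documents the models and procedures implemented in `ontonet`,
the defaults and their rationale, the synthetic data used by the test
suite, and the numerical choices that a user of the results should know
about.

## Data model

An ontology is a set of terms forming a rooted DAG; edges are stored
child → parent and "ancestor" means reachable by repeatedly following
parents. Both `is_a` and `part_of` OBO relations propagate annotations;
other relation types (`regulates`, …) are ignored with a logged count.
Multiple roots are allowed, one per namespace, and edges crossing
namespaces are rejected, matching the convention of analysing each
sub-ontology separately. Structural problems — cycles among non-obsolete
terms, edges naming undefined terms, duplicate ids — abort the load,
because an unsound ontology invalidates everything downstream. Annotation
files, by contrast, are treated as noisy: rows naming unknown entities or
terms are skipped and counted in a load report, duplicates collapse to one
incidence bit, and `alt_id` synonyms map to their canonical term.

Annotations live in a sparse binary entity×term incidence matrix with an
explicit `propagated` flag. Propagation applies the true-path rule — an
entity annotated to a term is annotated to all its ancestors — as a single
sparse matrix product with the ancestor-closure matrix. It is idempotent,
never clears a bit, and drops term columns that remain empty, so every
downstream computation sees only the annotated ("valid") part of the
ontology. Enrichment and IC computation refuse unpropagated stores rather
than silently propagating, keeping the step explicit and auditable.

## Enrichment

Given background size $N$ (default: all annotated entities, intersected
with a user-supplied background when given), term size $K$, input size $n$
and overlap $x$, the raw p-value is the inclusive upper tail
$P(X \ge x)$ — one-sided, over-representation only. Three tests are
offered: the exact hypergeometric tail, a binomial tail with
$q = K/N$ (an approximation that treats draws as independent), and the
one-sided Fisher exact test, which is mathematically identical to the
hypergeometric tail and is kept as an independent code path (scipy's
`fisher_exact` versus `hypergeom.sf`) so each can check the other.

Two DAG decorrelation algorithms re-score terms:

* **elim** — terms are visited leaves first (reverse topological order).
  A term is tested on its annotation set minus any entities eliminated by
  its significant descendants; when its p-value falls below `elim_cutoff`
  (default 0.01) its full annotation set is marked eliminated for all its
  strict ancestors. Elimination is tracked per ancestor, so two
  significant siblings each contribute their sets to the parent (union).
  The reported `K`, `x` and member lists are the counts actually tested,
  keeping rows internally consistent. With a cutoff approaching zero the
  algorithm degenerates to the plain per-term test.
* **parent–child** — each non-root term is tested inside the union of its
  parents' annotated entities rather than the global background, so the
  score measures refinement over the parents; roots keep p = 1 by
  convention. A child annotating exactly its parent's set scores 1.

Defaults (hypergeometric test, no DAG algorithm, BH adjustment, minimum
term size 2) follow common ontology-tool practice; all are configurable,
and the adjustment is always computed across the set of actually tested
terms of the run, which is echoed in the result metadata. Ranking ties
break lexicographically by term id, so results are fully deterministic.

## Information content and similarity

$IC(t) = -\log_{10}(n_t / N)$ with $n_t$ the propagated annotation count
of $t$ and $N$ the number of annotated entities. The base-10 logarithm is
part of the definition, not a display choice; a term covering every entity
has IC 0, a term covering one in ten has IC 1, and IC is non-decreasing
along every root→leaf path because propagated counts are non-increasing.

Term similarity is MICA-based, where the MICA is the common ancestor
(including the two terms themselves) with maximal IC among terms that
carry annotations. With $p_m$ the MICA's annotation frequency:

| measure | formula | range |
|---|---|---|
| resnik | $IC_{MICA}$ | $[0,\infty)$ |
| lin | $2\,IC_{MICA}/(IC_1+IC_2)$, 0/0 → 0 | $[0,1]$ |
| schlicker | $\text{lin}\cdot(1-p_m)$ | $[0,1)$ |
| jiang | $1-\min(1,\,IC_1+IC_2-2\,IC_{MICA})$ | $[0,1]$ |

The Jiang–Conrath distance is clamped into the unit interval so all
bounded measures share a scale. Terms with no common annotated ancestor
(e.g. different namespaces) score 0 with a debug log, not an error.

Entity similarity uses each entity's **most-specific annotations** — the
terms with no annotated descendant for that entity — rather than the full
propagated closure, whose best-match statistics would be dominated by
shallow ancestors shared by everyone. For term sets $T_1, T_2$ and
$b_1(t) = \max_{s \in T_2} sim(t,s)$ (symmetrically $b_2$):

* `bm_average` $= (\sum b_1 + \sum b_2)/(|T_1|+|T_2|)$,
* `bm_max` $= \max(b_1 \cup b_2)$,
* `bm_complete` $= \min(b_1 \cup b_2)$ — "complete" is interpreted as the
  complete-linkage analogue (the weakest best match); this reading is
  recorded in the network metadata rather than silently assumed.

The all-pairs similarity network stores no zero-weight edges and no
self-loops but keeps isolated nodes. There is no hard similarity
threshold; an optional edge filter keeps the heaviest fraction of edges
(`top_fraction`, e.g. 0.5) or those above a floor (`min_weight`). Networks
computed per sub-ontology are combined by elementwise addition of edge
weights over the union of nodes, which is how an overall similarity is
assembled from per-namespace ones.

## Random walk with restart and contact significance

The transition matrix $W$ column-normalises the weighted adjacency — each
node distributes its outgoing mass proportionally to edge weight — and
isolated nodes receive a self-loop to keep $W$ stochastic. The walk
iterates $p \leftarrow (1-r) W p + r p_0$ from the normalised seed
distribution $p_0$ until the L1 step change falls below the tolerance.
Defaults: restart $r = 0.75$ (common network-propagation practice),
tolerance $10^{-10}$, 10 000 iterations maximum — with restart the
iteration contracts at rate $1-r$, so convergence takes a few dozen
iterations in practice. $r = 1$ returns $p_0$ exactly; $r = 0$ is
rejected. The fixed point equals the solution of
$(I - (1-r)W)\,p = r\,p_0$, and the test suite checks the iterative
solution against that direct solve to $10^{-6}$ (L1) on networks up to 50
nodes.

Contact strength between groups $g, h$ is the inner product
$C(g,h) = \sum_v p_g(v)\,p_h(v)$ — symmetric, fast, and monotone in
co-localisation of the two diffusion profiles; the choice is recorded in
the output metadata. The null redraws each group's seeds uniformly from
the network nodes, preserving group size and weight multiset, and repeats
the identical walk `n_perm` times (default 1000). Per pair this yields
$z = (C-\mu)/\sigma$ and the empirical
$p = (1 + \#\{C_{perm} \ge C\})/(1 + n_perm)$ — the add-one estimator
avoids zero p-values. BH adjustment runs across the off-diagonal pairs,
and pairs with adjusted $p$ below the cutoff (default 0.1) form the
contact network, weighted by $z$.

Two known properties of this null deserve emphasis. First, it is not
degree-matched: groups seeded on hubs are compared against typical nodes,
which is the simplest defensible null but can flag hub effects as signal.
Second, the permuted groups are redrawn independently, so on small
networks they frequently share nodes, and shared seeds contribute large
$p_g(v)p_h(v)$ products; the null distribution is therefore heavy-tailed
to the right, and a genuinely co-localised pair can rank first by z-score
while remaining empirically non-significant on a 20-node network. The
tests accordingly assert rank recovery and z calibration, not empirical
significance, at that scale.

Permutation walks are batched into fixed-width column blocks; a worker
count parallelises blocks across threads without changing the
floating-point operations, so serial and parallel runs are byte-identical
— this, plus deriving all randomness from the single `rng_seed`, is what
the run-manifest reproducibility contract rests on.

## Synthetic data

The generator produces the study conditions used throughout the tests:

* **DAG**: 30 terms, single root; term $i$ draws 1–2 parents uniformly
  from earlier terms, guaranteeing acyclicity by construction.
* **Annotations**: 40 entities, each directly annotated to at least one
  term; terms are sampled with probability proportional to depth + ½, so
  deep specific terms are favoured and propagation produces a realistic
  count gradient toward the root. The per-entity annotation count is
  binomial with density 0.08 (≈3 direct annotations).
* **Planted enrichment**: the planted term is the candidate (size within
  [5, half the background]) whose propagated size is closest to the
  drawable signal, `effect × n_input`; the input mixes that fraction
  (default 0.8 of 20) of its annotated entities with uniform background.
* **Contact network**: 20 nodes; a 6-node complete cluster with weights
  near 1 hosts the two planted seed groups; a weak ring plus sparse weak
  edges (weights ≈ 0.1) keeps the rest connected; two 3-node comparison
  groups are scattered outside the cluster. A separate generator draws
  groups uniformly from all nodes — exactly the permutation null — for
  calibration measurements.

All generators are deterministic under their seed. What the synthetic
data does **not** emulate: real annotation-frequency distributions (GO
term sizes are far more skewed), obsolete/alt-id churn of real ontologies,
multi-namespace structure, or degree heterogeneity of real similarity
networks. Passing tests therefore demonstrate algorithmic correctness and
planted-signal recovery under controlled conditions, not biological
performance on any particular corpus.

## Numerical and design choices

* Exact-test preconditions require $0 \le x \le \min(n, K)$; an $x$ at or
  below the hypergeometric support minimum $\max(0, n+K-N)$ returns tail
  probability 1 exactly, avoiding degenerate 2×2 tables.
* Edge-list export writes weights with shortest round-trip `repr` and
  re-imports them with Python's correctly-rounded `float`, making the
  export→import round trip bit-exact (pandas' fast CSV float path is not
  correctly rounded).
* The elim bookkeeping is per-ancestor (each significant descendant adds
  its entities to each strict ancestor's elimination set) rather than a
  single global eliminated pool; the bookkeeping is stated here because
  published descriptions of elim-style algorithms differ in this detail.
* Sorting everywhere (term ids, entity ids, group ids, tie-breaks) is
  lexicographic, so all outputs are order-invariant in their inputs.
* Problem sizes in the test suite and acceptance script (N ≤ 12 exhaustive
  sweeps, ≤ 100-term DAGs, 100 enrichment / 50 contact replicates at 1000
  permutations) were chosen to estimate the measured rates tightly while
  keeping a full run in the tens of seconds on one CPU.

## Limitations

* Only `is_a`/`part_of` propagate; ontologies whose semantics require
  other relations are out of scope.
* No under-representation (depletion) test.
* The contact null is not degree-preserving (see above).
* OWL ontologies and binary serialisation formats are unsupported by
  design; everything is plain text.
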