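"""Information-content semantic similarity and entity similarity networks.

The information content (IC) of a term is the negative base-10 logarithm of
its annotation frequency: IC(t) = -log10(n_t / N), where n_t counts the
entities annotated to t after true-path propagation and N counts all
annotated entities.  Rare (specific) terms are informative; a root covering
every entity has IC 0, and IC is non-decreasing along every root→leaf path.

Term–term similarity is driven by the most informative common ancestor
(MICA) — the shared ancestor, including the terms themselves, with maximal
IC:

* ``resnik``:    IC(MICA)
* ``lin``:       2·IC(MICA) / (IC(t1) + IC(t2)), with 0/0 → 0
* ``schlicker``: lin · (1 − p_MICA)   (the relevance measure)
* ``jiang``:     1 − min(1, IC(t1) + IC(t2) − 2·IC(MICA))

Entity–entity similarity summarises the term-pair matrix between two
entities' most-specific annotations with a best-match (BM) statistic: for
every term of one entity take the maximum similarity to any term of the
other, then combine these best matches by averaging (``bm_average``),
taking the overall maximum (``bm_max``) or the overall minimum
(``bm_complete``, a complete-linkage analogue).  All-pairs computation
yields a weighted undirected similarity network; networks computed per
sub-ontology can be additively combined into an overall network.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .ontology import AnnotationStore, OntologyDAG

logger = logging.getLogger("ontonet")

MEASURES = ("resnik", "lin", "schlicker", "jiang")
BM_METHODS = ("bm_average", "bm_max", "bm_complete")


class SimilarityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# information content
# ---------------------------------------------------------------------------


class TermICTable:
    """Annotation frequency and IC per term of a propagated store."""

    def __init__(self, frequency: pd.Series):
        if ((frequency <= 0) | (frequency > 1)).any():
            raise SimilarityError("term frequencies must lie in (0, 1]")
        self.frequency = frequency.astype(float)
        self.ic = -np.log10(self.frequency) + 0.0  # +0.0 normalises -log10(1) to +0

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.frequency.index

    def __getitem__(self, term_id: str) -> float:
        return float(self.ic[term_id])

    def p(self, term_id: str) -> float:
        return float(self.frequency[term_id])

    def __repr__(self) -> str:  # pragma: no cover
        return f"TermICTable({len(self.frequency)} terms)"


def compute_ic(anno: AnnotationStore) -> TermICTable:
    """IC table from a propagated annotation store.

    N is the number of entities with at least one annotation; propagation
    guarantees every remaining term column is non-zero, so all frequencies
    fall in (0, 1].
    """
    if not anno.propagated:
        raise SimilarityError("IC requires a propagated annotation store")
    n_anno = len(anno.annotated_entities())
    if n_anno == 0:
        raise SimilarityError("no annotated entities")
    counts = anno.term_counts()
    if (counts == 0).any():
        raise SimilarityError("propagated store contains an all-zero term column")
    return TermICTable(counts / n_anno)


# ---------------------------------------------------------------------------
# term similarity
# ---------------------------------------------------------------------------


def mica(t1: str, t2: str, dag: OntologyDAG, ic: TermICTable) -> str | None:
    """Most informative common ancestor of two terms (terms included).

    Only ancestors present in the IC table qualify (others carry no
    annotation).  Returns None when the terms share no scored ancestor,
    e.g. across namespaces.
    """
    anc1 = (dag.ancestors(t1) | {t1})
    anc2 = (dag.ancestors(t2) | {t2})
    common = [a for a in anc1 & anc2 if a in ic]
    if not common:
        return None
    return max(common, key=lambda a: (ic[a], a))


def term_sim(
    t1: str, t2: str, dag: OntologyDAG, ic: TermICTable, measure: str = "lin"
) -> float:
    """IC-based similarity between two terms; symmetric in (t1, t2)."""
    if measure not in MEASURES:
        raise SimilarityError(f"unknown measure {measure!r}; choose from {MEASURES}")
    for t in (t1, t2):
        if t not in ic:
            raise KeyError(f"term {t!r} has no information content (unannotated?)")
    m = mica(t1, t2, dag, ic)
    if m is None:
        logger.debug("terms %s and %s share no annotated ancestor; similarity 0", t1, t2)
        return 0.0
    ic_m, ic1, ic2 = ic[m], ic[t1], ic[t2]
    if measure == "resnik":
        return ic_m
    if measure == "lin":
        denom = ic1 + ic2
        return 2.0 * ic_m / denom if denom > 0 else 0.0
    if measure == "schlicker":
        denom = ic1 + ic2
        lin = 2.0 * ic_m / denom if denom > 0 else 0.0
        return lin * (1.0 - ic.p(m))
    # jiang: unit-interval transform of the IC distance
    return 1.0 - min(1.0, ic1 + ic2 - 2.0 * ic_m)


# ---------------------------------------------------------------------------
# entity similarity
# ---------------------------------------------------------------------------


def most_specific_terms(entity_id: str, anno: AnnotationStore, dag: OntologyDAG) -> set[str]:
    """The entity's annotations with no annotated descendant for that entity.

    Best-match statistics over full propagated closures are dominated by
    shallow ancestors, so entity comparison uses this minimal frontier.
    """
    terms = anno.terms_of_entity(entity_id)
    if not terms:
        raise SimilarityError(f"entity {entity_id!r} has no annotations")
    return {t for t in terms if not (dag.descendants(t) & terms)}


def _bm_scores(
    T1: Sequence[str],
    T2: Sequence[str],
    dag: OntologyDAG,
    ic: TermICTable,
    measure: str,
) -> tuple[np.ndarray, np.ndarray]:
    sim = np.array([[term_sim(a, b, dag, ic, measure) for b in T2] for a in T1])
    return sim.max(axis=1), sim.max(axis=0)  # best match per T1 term, per T2 term


def entity_sim(
    e1: str,
    e2: str,
    anno: AnnotationStore,
    dag: OntologyDAG,
    ic: TermICTable,
    measure: str = "lin",
    bm: str = "bm_average",
) -> float:
    """Best-match similarity between two annotated entities."""
    if bm not in BM_METHODS:
        raise SimilarityError(f"unknown BM method {bm!r}; choose from {BM_METHODS}")
    T1 = sorted(most_specific_terms(e1, anno, dag))
    T2 = sorted(most_specific_terms(e2, anno, dag))
    b1, b2 = _bm_scores(T1, T2, dag, ic, measure)
    if bm == "bm_average":
        return float((b1.sum() + b2.sum()) / (len(T1) + len(T2)))
    if bm == "bm_max":
        return float(max(b1.max(), b2.max()))
    return float(min(b1.min(), b2.min()))


# ---------------------------------------------------------------------------
# similarity networks
# ---------------------------------------------------------------------------


class SimilarityNetwork:
    """Weighted undirected graph over entities; weights are similarities.

    Zero-weight edges are never stored; isolated nodes stay in the node
    set.  ``metadata`` records how the network was built (measure, BM
    variant, namespace, edge filter).
    """

    def __init__(self, graph: nx.Graph, metadata: dict | None = None):
        for u, v, w in graph.edges(data="weight"):
            if u == v:
                raise SimilarityError("self-loops are not allowed")
            if w is None or w < 0:
                raise SimilarityError(f"edge ({u}, {v}) lacks a non-negative weight")
        self.graph = graph
        self.metadata = dict(metadata or {})

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def weight(self, u: str, v: str) -> float:
        if self.graph.has_edge(u, v):
            return float(self.graph[u][v]["weight"])
        return 0.0

    def to_networkx(self) -> nx.Graph:
        return self.graph.copy()

    def matrix(self) -> pd.DataFrame:
        nodes = self.nodes
        m = nx.to_pandas_adjacency(self.graph, nodelist=nodes, weight="weight")
        return m

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SimilarityNetwork({self.graph.number_of_nodes()} nodes, "
            f"{self.graph.number_of_edges()} edges)"
        )


def _apply_edge_filter(graph: nx.Graph, edge_filter) -> nx.Graph:
    """edge_filter: None | ('top_fraction', f) | ('min_weight', w)."""
    if edge_filter is None or edge_filter == "none":
        return graph
    kind, value = edge_filter
    edges = sorted(graph.edges(data="weight"), key=lambda e: (-e[2], e[0], e[1]))
    if kind == "top_fraction":
        if not (0 < value <= 1):
            raise SimilarityError("top_fraction must lie in (0, 1]")
        keep = edges[: int(round(value * len(edges)))]
    elif kind == "min_weight":
        keep = [e for e in edges if e[2] >= value]
    else:
        raise SimilarityError(f"unknown edge filter {kind!r}")
    out = nx.Graph()
    out.add_nodes_from(graph.nodes)
    out.add_weighted_edges_from(keep)
    return out


def build_similarity_network(
    entity_ids: Iterable[str],
    anno: AnnotationStore,
    dag: OntologyDAG,
    measure: str = "lin",
    bm: str = "bm_average",
    edge_filter=None,
    ic: TermICTable | None = None,
) -> SimilarityNetwork:
    """All-pairs best-match similarity network over the given entities.

    Entities without annotations are dropped with a logged report; at least
    two must survive.  ``edge_filter`` optionally keeps only the heaviest
    fraction of edges (``("top_fraction", f)``) or those above a weight
    floor (``("min_weight", w)``).
    """
    ids = list(dict.fromkeys(entity_ids))
    annotated = anno.annotated_entities()
    kept = [e for e in ids if e in annotated]
    dropped = [e for e in ids if e not in annotated]
    if dropped:
        logger.info("similarity network: dropped %d unannotated entities", len(dropped))
    if len(kept) < 2:
        raise SimilarityError("need at least 2 annotated entities for a network")
    ic = ic or compute_ic(anno)

    frontiers = {e: sorted(most_specific_terms(e, anno, dag)) for e in kept}
    # cache term-pair similarities: frontiers overlap heavily across entities
    cache: dict[tuple[str, str], float] = {}

    def tsim(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            cache[key] = term_sim(key[0], key[1], dag, ic, measure)
        return cache[key]

    graph = nx.Graph()
    graph.add_nodes_from(kept)
    for i, u in enumerate(kept):
        for v in kept[i + 1:]:
            T1, T2 = frontiers[u], frontiers[v]
            sim = np.array([[tsim(a, b) for b in T2] for a in T1])
            b1, b2 = sim.max(axis=1), sim.max(axis=0)
            if bm == "bm_average":
                w = float((b1.sum() + b2.sum()) / (len(T1) + len(T2)))
            elif bm == "bm_max":
                w = float(max(b1.max(), b2.max()))
            elif bm == "bm_complete":
                w = float(min(b1.min(), b2.min()))
            else:
                raise SimilarityError(f"unknown BM method {bm!r}; choose from {BM_METHODS}")
            if w > 0:
                graph.add_edge(u, v, weight=w)
    graph = _apply_edge_filter(graph, edge_filter)
    meta = {
        "measure": measure,
        "bm": bm,
        "edge_filter": repr(edge_filter),
        "note": "bm_complete = minimum over all best-match values",
    }
    return SimilarityNetwork(graph, meta)


def combine_networks(nets: Sequence[SimilarityNetwork]) -> SimilarityNetwork:
    """Additively combine networks (e.g. one per sub-ontology).

    The node set is the union; a missing edge contributes weight 0.
    """
    if not nets:
        raise SimilarityError("cannot combine an empty list of networks")
    graph = nx.Graph()
    for net in nets:
        graph.add_nodes_from(net.graph.nodes)
    for net in nets:
        for u, v, w in net.graph.edges(data="weight"):
            if graph.has_edge(u, v):
                graph[u][v]["weight"] += w
            else:
                graph.add_edge(u, v, weight=w)
    meta = {"combined_from": [n.metadata.get("measure", "?") for n in nets]}
    return SimilarityNetwork(graph, meta)
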