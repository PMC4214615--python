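"""Synthetic ontologies, annotations and networks with planted structure.

Every analysis in this package is testable without downloading any real
ontology: this module generates random rooted DAGs, leaf-biased annotation
matrices, entity sets with a planted enriched term, and small weighted
networks with planted seed clusters.  All generators are deterministic
under the spec's rng seed, and every generated object satisfies the
invariants of its container type.

The defaults describe the study conditions used throughout the tests: a
30-term single-root DAG with up to 2 parents per term, 40 annotatable
entities with roughly three direct (leaf-biased) annotations each, an input
set of 20 entities of which 80% are drawn from the planted term's annotated
entities, and a 20-node contact network with one 6-node high-weight cluster
hosting two adjacent seed groups next to two scattered groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .ontology import (
    AnnotationStore,
    EntityTable,
    OntologyDAG,
    Term,
    annotations_from_pairs,
    propagate,
)
from .similarity import SimilarityNetwork

import pandas as pd


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    n_terms: int = 30
    n_entities: int = 40
    max_parents: int = 2
    density: float = 0.08          # per-term direct-annotation probability per entity
    effect: float = 0.8            # fraction of the input drawn from the planted term
    n_input: int = 20
    min_planted_size: int = 5
    cluster_size: int = 6          # planted high-weight cluster in the contact network
    n_network_nodes: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_terms, self.n_entities, self.max_parents, self.n_input) < 1:
            raise ValueError("all counts must be >= 1")
        if not (0 < self.density <= 1) or not (0 < self.effect <= 1):
            raise ValueError("density and effect must lie in (0, 1]")


# ---------------------------------------------------------------------------
# random DAGs and annotations
# ---------------------------------------------------------------------------


def random_dag(spec: FixtureSpec) -> OntologyDAG:
    """Single-root random DAG: term i draws 1..max_parents parents among 0..i-1.

    Construction from earlier terms guarantees acyclicity by design.
    """
    rng = np.random.default_rng(spec.seed)
    ids = [f"T{i:04d}" for i in range(spec.n_terms)]
    terms = [Term(id=tid, name=f"synthetic term {tid}") for tid in ids]
    edges: list[tuple[str, str]] = []
    for i in range(1, spec.n_terms):
        k = int(rng.integers(1, min(spec.max_parents, i) + 1))
        parents = rng.choice(i, size=k, replace=False)
        edges.extend((ids[i], ids[int(p)]) for p in parents)
    return OntologyDAG(terms, edges)


def random_entities(spec: FixtureSpec) -> EntityTable:
    ids = [f"d{i:04d}" for i in range(spec.n_entities)]
    frame = pd.DataFrame(
        {"id": ids, "symbol": [f"D{i}" for i in range(spec.n_entities)],
         "description": [f"synthetic entity {e}" for e in ids]}
    )
    return EntityTable(frame)


def random_annotations(spec: FixtureSpec, dag: OntologyDAG) -> tuple[AnnotationStore, EntityTable]:
    """Leaf-biased direct annotations; every entity gets at least one.

    Terms are sampled with probability proportional to their depth, so
    deeper (more specific) terms are favoured and propagation produces a
    realistic count gradient toward the root.  The returned store is
    unpropagated.
    """
    rng = np.random.default_rng(spec.seed + 1)
    entities = random_entities(spec)
    term_ids = sorted(dag.graph.nodes)
    depth = dag.depths()
    # depth + 1/2 keeps roots sampleable while favouring deep, specific terms
    w = np.array([depth[t] + 0.5 for t in term_ids], dtype=float)
    w = w / w.sum()
    pairs: set[tuple[str, str]] = set()
    for e in entities.ids:
        k = max(1, int(rng.binomial(len(term_ids), spec.density)))
        chosen = rng.choice(len(term_ids), size=min(k, len(term_ids)), replace=False, p=w)
        pairs.update((e, term_ids[int(j)]) for j in chosen)
    return annotations_from_pairs(sorted(pairs), entities.ids), entities


def pick_planted_term(spec: FixtureSpec, anno_prop: AnnotationStore) -> str:
    """Planted term: propagated size closest to the drawable signal size.

    The input draws ``effect * n_input`` entities from the planted term, so
    the term should annotate about that many entities for the stated effect
    to be realisable.  Candidates must annotate at least
    ``min_planted_size`` entities and at most half the background, so the
    term is neither trivial nor near-universal.
    """
    counts = anno_prop.term_counts()
    lo, hi = spec.min_planted_size, max(spec.min_planted_size, spec.n_entities // 2)
    candidates = counts[(counts >= lo) & (counts <= hi)]
    if candidates.empty:
        raise ValueError("no term annotates enough entities to plant a signal")
    target = spec.effect * spec.n_input
    return min(candidates.index, key=lambda t: (abs(candidates[t] - target), t))


def planted_enrichment_input(
    spec: FixtureSpec, anno_prop: AnnotationStore, planted_term: str | None = None
) -> tuple[list[str], str]:
    """Entity set mixing planted-term members with uniform background.

    Draws ``effect * n_input`` entities (capped at the term's size) from
    the planted term's annotated entities and fills the rest uniformly from
    the remaining background.  Returns the input list and the ground-truth
    term id.
    """
    if not anno_prop.propagated:
        raise ValueError("planted input requires a propagated store")
    rng = np.random.default_rng(spec.seed + 2)
    planted = planted_term or pick_planted_term(spec, anno_prop)
    members = sorted(anno_prop.entities_of_term(planted))
    if len(members) < spec.min_planted_size:
        raise ValueError(
            f"planted term {planted!r} annotates only {len(members)} entities "
            f"(< {spec.min_planted_size})"
        )
    n_signal = min(int(round(spec.effect * spec.n_input)), len(members))
    signal = [members[int(i)] for i in rng.choice(len(members), size=n_signal, replace=False)]
    rest = sorted(set(anno_prop.entity_ids) - set(signal))
    n_bg = min(spec.n_input - n_signal, len(rest))
    background = [rest[int(i)] for i in rng.choice(len(rest), size=n_bg, replace=False)]
    return sorted(signal + background), planted


@dataclass
class PlantedEnrichmentFixture:
    dag: OntologyDAG
    entities: EntityTable
    anno: AnnotationStore          # propagated
    input_ids: list[str]
    planted_term: str


def planted_enrichment_fixture(spec: FixtureSpec) -> PlantedEnrichmentFixture:
    """One-call bundle: DAG, entities, propagated annotations, planted input."""
    dag = random_dag(spec)
    anno, entities = random_annotations(spec, dag)
    anno_prop = propagate(anno, dag)
    input_ids, planted = planted_enrichment_input(spec, anno_prop)
    return PlantedEnrichmentFixture(dag, entities, anno_prop, input_ids, planted)


# ---------------------------------------------------------------------------
# contact-network fixtures
# ---------------------------------------------------------------------------


def clustered_network(spec: FixtureSpec) -> SimilarityNetwork:
    """Weighted network with one planted high-weight cluster.

    Nodes v0000..; the first ``cluster_size`` nodes form a complete
    subgraph with weights near 1; the rest of the graph is a sparse random
    background of weak edges (weights near 0.1), wired so the network is
    connected.
    """
    rng = np.random.default_rng(spec.seed + 3)
    n = spec.n_network_nodes
    ids = [f"v{i:04d}" for i in range(n)]
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    c = spec.cluster_size
    for i in range(c):
        for j in range(i + 1, c):
            graph.add_edge(ids[i], ids[j], weight=float(0.9 + 0.1 * rng.random()))
    # weak ring over all nodes keeps the graph connected
    for i in range(n):
        j = (i + 1) % n
        if not graph.has_edge(ids[i], ids[j]):
            graph.add_edge(ids[i], ids[j], weight=float(0.05 + 0.1 * rng.random()))
    # sparse random background edges
    for _ in range(n):
        i, j = rng.choice(n, size=2, replace=False)
        if not graph.has_edge(ids[int(i)], ids[int(j)]):
            graph.add_edge(ids[int(i)], ids[int(j)], weight=float(0.05 + 0.1 * rng.random()))
    return SimilarityNetwork(graph, {"fixture": "clustered_network", "cluster": ids[:c]})


def planted_contact_seeds(spec: FixtureSpec, net: SimilarityNetwork) -> tuple[dict, tuple[str, str]]:
    """Four seed groups: two inside the planted cluster, two scattered.

    Returns the seed spec and the planted pair of group ids whose contact
    should dominate.
    """
    rng = np.random.default_rng(spec.seed + 4)
    nodes = list(net.graph.nodes)
    c = spec.cluster_size
    half = c // 2
    g1 = {nodes[i]: 1.0 for i in range(half)}
    g2 = {nodes[i]: 1.0 for i in range(half, c)}
    outside = np.array(range(c, len(nodes)))
    pick1 = rng.choice(outside, size=min(3, len(outside)), replace=False)
    remaining = np.array(sorted(set(outside) - set(pick1)))
    pick2 = rng.choice(remaining, size=min(3, len(remaining)), replace=False)
    g3 = {nodes[int(i)]: 1.0 for i in pick1}
    g4 = {nodes[int(i)]: 1.0 for i in pick2}
    seeds = {"cluster_a": g1, "cluster_b": g2, "scatter_a": g3, "scatter_b": g4}
    return seeds, ("cluster_a", "cluster_b")


def random_seed_groups(
    net: SimilarityNetwork, n_groups: int, group_size: int, seed: int
) -> dict[str, dict[str, float]]:
    """Seed groups drawn uniformly from all network nodes.

    Matches the permutation null model exactly, so contact z-scores between
    such groups should be centred near 0 with unit spread — the calibration
    check for the contact pipeline.
    """
    rng = np.random.default_rng(seed)
    nodes = list(net.graph.nodes)
    groups: dict[str, dict[str, float]] = {}
    for gi in range(n_groups):
        pick = rng.choice(len(nodes), size=min(group_size, len(nodes)), replace=False)
        groups[f"g{gi}"] = {nodes[int(i)]: 1.0 for i in pick}
    return groups


# ---------------------------------------------------------------------------
# file export
# ---------------------------------------------------------------------------


def write_fixture_files(spec: FixtureSpec, out_dir: str | Path) -> dict[str, str]:
    """Write a full planted fixture as TSV/JSON inputs for the CLI.

    Produces term/edge tables, the entity table, the *unpropagated*
    annotation table, the input entity list and a ground-truth JSON.
    Returns the mapping of artefact name to file path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dag = random_dag(spec)
    anno, entities = random_annotations(spec, dag)
    anno_prop = propagate(anno, dag)
    input_ids, planted = planted_enrichment_input(spec, anno_prop)

    order = sorted(dag.terms)
    terms_df = pd.DataFrame(
        {"id": order,
         "name": [dag.terms[t].name for t in order],
         "namespace": [dag.terms[t].namespace for t in order]}
    )
    edges_df = pd.DataFrame(sorted(dag.edges), columns=["child", "parent"])
    pairs = sorted(
        (e, t) for e in anno.entity_ids for t in anno.terms_of_entity(e)
    )
    anno_df = pd.DataFrame(pairs, columns=["entity", "term"])

    paths = {
        "terms": out / "terms.tsv",
        "edges": out / "edges.tsv",
        "entities": out / "entities.tsv",
        "annotations": out / "annotations.tsv",
        "input": out / "input.txt",
        "truth": out / "truth.json",
    }
    terms_df.to_csv(paths["terms"], sep="\t", index=False)
    edges_df.to_csv(paths["edges"], sep="\t", index=False)
    entities.frame.to_csv(paths["entities"], sep="\t", index=False)
    anno_df.to_csv(paths["annotations"], sep="\t", index=False)
    paths["input"].write_text("\n".join(input_ids) + "\n")
    paths["truth"].write_text(
        json.dumps({"planted_term": planted, "spec": asdict(spec)}, indent=2) + "\n"
    )
    return {k: str(v) for k, v in paths.items()}
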