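"""Ontology DAGs, entity metadata and sparse annotations.

An ontology is a controlled vocabulary whose terms form a rooted directed
acyclic graph (DAG) through ``is_a`` / ``part_of`` relations.  Annotations
link entities (protein domains, genes, RNA families, ...) to terms; the
true-path rule states that an entity annotated to a term is implicitly
annotated to every ancestor of that term, up to the root.  This module
provides the three data containers every analysis builds on —
:class:`OntologyDAG`, :class:`EntityTable` and :class:`AnnotationStore` —
together with their file loaders and the DAG queries (ancestors,
descendants, induced subgraphs, annotation propagation) used downstream.

Conventions
-----------
* Edges are stored child → parent; "ancestor" means reachable by repeatedly
  following parents.
* ``is_a`` and ``part_of`` both propagate; other OBO relationship types are
  ignored with a logged count.
* Multiple roots are allowed (one per namespace); edges crossing namespaces
  are rejected.
* Annotation rows naming unknown identifiers are skipped and reported,
  never fatal; structural errors in the ontology itself abort the load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("ontonet")

#: relationship types that follow the true-path rule
PROPAGATING_RELATIONS = ("is_a", "part_of")


class OntologyError(ValueError):
    """Structural problem in an ontology (cycle, dangling edge, duplicate id)."""


class AnnotationError(ValueError):
    """Contract violation in an annotation store or annotation file."""


# ---------------------------------------------------------------------------
# terms and the DAG
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Term:
    """A single ontology term.

    ``parent_ids`` reflects only propagating relations (is_a/part_of);
    obsolete terms keep no parents.
    """

    id: str
    name: str = ""
    namespace: str = ""
    parent_ids: frozenset[str] = frozenset()
    alt_ids: frozenset[str] = frozenset()
    obsolete: bool = False


class OntologyDAG:
    """A rooted DAG of ontology terms with child→parent edges.

    Parameters
    ----------
    terms
        Mapping or iterable of :class:`Term`.  ``parent_ids`` on the terms
        are ignored in favour of `edges` (and rewritten to match).
    edges
        Iterable of ``(child_id, parent_id)`` pairs.

    Raises
    ------
    OntologyError
        On duplicate/empty ids, edges touching undefined terms, edges
        crossing namespaces, or a cycle among non-obsolete terms.
    """

    def __init__(self, terms: Iterable[Term] | Mapping[str, Term], edges: Iterable[tuple[str, str]]):
        if isinstance(terms, Mapping):
            term_list = list(terms.values())
        else:
            term_list = list(terms)
        self.terms: dict[str, Term] = {}
        for t in term_list:
            if not t.id:
                raise OntologyError("term with empty id")
            if t.id in self.terms:
                raise OntologyError(f"duplicate term id {t.id!r}")
            self.terms[t.id] = t

        self.graph = nx.DiGraph()  # child -> parent, non-obsolete only
        for tid, t in self.terms.items():
            if not t.obsolete:
                self.graph.add_node(tid)

        edge_set: set[tuple[str, str]] = set()
        for child, parent in edges:
            for endpoint in (child, parent):
                if endpoint not in self.terms:
                    raise OntologyError(f"edge ({child!r}, {parent!r}) references undefined term {endpoint!r}")
            if self.terms[child].obsolete or self.terms[parent].obsolete:
                continue  # obsolete terms are loaded but carry no edges
            c_ns, p_ns = self.terms[child].namespace, self.terms[parent].namespace
            if c_ns and p_ns and c_ns != p_ns:
                raise OntologyError(
                    f"edge ({child!r}, {parent!r}) crosses namespaces {c_ns!r} / {p_ns!r}"
                )
            edge_set.add((child, parent))
        self.graph.add_edges_from(edge_set)
        self.edges: frozenset[tuple[str, str]] = frozenset(edge_set)

        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise OntologyError(f"ontology contains a cycle through term {cycle[0][0]!r}")

        # rewrite parent sets from the validated edge relation
        parents: dict[str, set[str]] = {tid: set() for tid in self.terms}
        for child, parent in edge_set:
            parents[child].add(parent)
        for tid, t in list(self.terms.items()):
            self.terms[tid] = replace(t, parent_ids=frozenset(parents[tid]))

        self.root_ids: frozenset[str] = frozenset(
            tid for tid, t in self.terms.items() if not t.obsolete and not parents[tid]
        )
        # alt_id -> canonical id
        self.alt_id_map: dict[str, str] = {}
        for tid, t in self.terms.items():
            for alt in t.alt_ids:
                self.alt_id_map.setdefault(alt, tid)

    # -- queries ------------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def _check(self, term_id: str) -> None:
        if term_id not in self.graph:
            raise KeyError(f"unknown term {term_id!r}")

    def ancestors(self, term_id: str) -> set[str]:
        """Transitive parents of `term_id`, excluding the term itself."""
        self._check(term_id)
        return nx.descendants(self.graph, term_id)  # edges run child->parent

    def descendants(self, term_id: str) -> set[str]:
        """Transitive children of `term_id`, excluding the term itself."""
        self._check(term_id)
        return nx.ancestors(self.graph, term_id)

    def topological_order(self) -> list[str]:
        """Terms ordered so every parent precedes its children."""
        return list(reversed(list(nx.topological_sort(self.graph))))

    def depths(self) -> dict[str, int]:
        """Longest root→term path length per non-obsolete term."""
        depth: dict[str, int] = {}
        for tid in self.topological_order():
            ps = self.terms[tid].parent_ids
            depth[tid] = 1 + max((depth[p] for p in ps), default=-1)
        return depth

    def induced_subgraph(self, term_ids: Iterable[str]) -> "OntologyDAG":
        """Sub-DAG over `term_ids` plus all their ancestors.

        Every original edge between retained terms is kept.
        """
        seeds = set(term_ids)
        for tid in seeds:
            self._check(tid)
        keep = set(seeds)
        for tid in seeds:
            keep |= self.ancestors(tid)
        sub_terms = [self.terms[tid] for tid in keep]
        sub_edges = [(c, p) for c, p in self.edges if c in keep and p in keep]
        return OntologyDAG(sub_terms, sub_edges)

    def to_networkx(self) -> nx.DiGraph:
        """Child→parent DiGraph with name/namespace node attributes."""
        g = nx.DiGraph()
        for tid in self.graph.nodes:
            t = self.terms[tid]
            g.add_node(tid, name=t.name, namespace=t.namespace)
        g.add_edges_from(self.edges)
        return g

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"OntologyDAG({len(self.graph)} terms, {len(self.edges)} edges, "
            f"{len(self.root_ids)} roots)"
        )


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------


def parse_obo(path: str | Path) -> OntologyDAG:
    """Parse an OBO 1.2 flat file into a validated :class:`OntologyDAG`.

    ``is_a`` and ``relationship: part_of`` lines both become child→parent
    edges; other relationship types are counted and ignored.  Obsolete terms
    are loaded but excluded from the edge relation.  ``alt_id`` accessions
    are recorded on the canonical term.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    multigraph = obonet.read_obo(str(path), ignore_obsolete=False)

    defined = {n for n, d in multigraph.nodes(data=True) if "name" in d or d}
    terms: list[Term] = []
    for tid, data in multigraph.nodes(data=True):
        if tid not in defined:
            continue
        terms.append(
            Term(
                id=tid,
                name=data.get("name", ""),
                namespace=data.get("namespace", ""),
                alt_ids=frozenset(data.get("alt_id", [])),
                obsolete=str(data.get("is_obsolete", "")).lower() == "true",
            )
        )

    edges: list[tuple[str, str]] = []
    ignored = 0
    for child, parent, rel in multigraph.edges(keys=True):
        if rel in PROPAGATING_RELATIONS:
            edges.append((child, parent))
        else:
            ignored += 1
    if ignored:
        logger.info("parse_obo(%s): ignored %d non-propagating relationship edges", path.name, ignored)
    return OntologyDAG(terms, edges)


def build_ontology(term_table: str | Path, edge_table: str | Path) -> OntologyDAG:
    """Build an :class:`OntologyDAG` from two TSV files.

    `term_table` needs columns ``id``, ``name``, ``namespace`` (header row
    mandatory); `edge_table` needs ``child``, ``parent``.  Validation is
    identical to :func:`parse_obo`.
    """
    tdf = pd.read_csv(term_table, sep="\t", dtype=str, keep_default_na=False)
    for col in ("id", "name", "namespace"):
        if col not in tdf.columns:
            raise OntologyError(f"term table missing column {col!r}")
    if tdf["id"].duplicated().any():
        dup = tdf.loc[tdf["id"].duplicated(), "id"].iloc[0]
        raise OntologyError(f"duplicate term id {dup!r}")
    terms = [
        Term(id=row.id, name=row.name, namespace=row.namespace)
        for row in tdf.itertuples(index=False)
    ]
    edf = pd.read_csv(edge_table, sep="\t", dtype=str, keep_default_na=False)
    for col in ("child", "parent"):
        if col not in edf.columns:
            raise OntologyError(f"edge table missing column {col!r}")
    edges = list(edf[["child", "parent"]].itertuples(index=False, name=None))
    return OntologyDAG(terms, edges)


# ---------------------------------------------------------------------------
# entities
# ---------------------------------------------------------------------------


class EntityTable:
    """Metadata for annotatable entities (id, symbol, description)."""

    def __init__(self, frame: pd.DataFrame):
        for col in ("id", "symbol", "description"):
            if col not in frame.columns:
                raise ValueError(f"entity table missing column {col!r}")
        if frame["id"].duplicated().any():
            dup = frame.loc[frame["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate entity id {dup!r}")
        if (frame["id"] == "").any():
            raise ValueError("entity with empty id")
        self.frame = frame.reset_index(drop=True)
        self.ids: list[str] = list(self.frame["id"])
        self._index = {e: i for i, e in enumerate(self.ids)}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EntityTable":
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return cls(frame)

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._index

    def __len__(self) -> int:
        return len(self.ids)

    def __repr__(self) -> str:  # pragma: no cover
        return f"EntityTable({len(self)} entities)"


def build_entities(path: str | Path) -> EntityTable:
    """Load entity metadata from a TSV with columns id, symbol, description."""
    return EntityTable.from_tsv(path)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


@dataclass
class LoadReport:
    """Counts from loading an annotation file."""

    n_rows: int = 0
    n_kept: int = 0
    n_duplicates: int = 0
    n_unknown_term: int = 0
    n_unknown_entity: int = 0
    n_alt_mapped: int = 0

    @property
    def n_skipped(self) -> int:
        return self.n_unknown_term + self.n_unknown_entity

    def log(self) -> None:
        logger.info(
            "annotations: %d rows, %d kept, %d duplicate, %d skipped "
            "(%d unknown term, %d unknown entity), %d alt_id-mapped",
            self.n_rows, self.n_kept, self.n_duplicates, self.n_skipped,
            self.n_unknown_term, self.n_unknown_entity, self.n_alt_mapped,
        )


class AnnotationStore:
    """Sparse binary entity×term incidence plus a propagation flag."""

    def __init__(
        self,
        entity_ids: list[str],
        term_ids: list[str],
        incidence: sp.spmatrix,
        propagated: bool = False,
        report: LoadReport | None = None,
    ):
        self.entity_ids = list(entity_ids)
        self.term_ids = list(term_ids)
        self.incidence = sp.csr_matrix(incidence, dtype=np.int8)
        self.incidence.data[:] = 1
        if self.incidence.shape != (len(self.entity_ids), len(self.term_ids)):
            raise AnnotationError("incidence shape does not match id lists")
        self.propagated = propagated
        self.report = report
        self._eindex = {e: i for i, e in enumerate(self.entity_ids)}
        self._tindex = {t: i for i, t in enumerate(self.term_ids)}

    # -- queries ------------------------------------------------------------

    def entities_of_term(self, term_id: str) -> set[str]:
        j = self._tindex[term_id]
        rows = self.incidence.getcol(j).nonzero()[0]
        return {self.entity_ids[i] for i in rows}

    def terms_of_entity(self, entity_id: str) -> set[str]:
        i = self._eindex[entity_id]
        cols = self.incidence.getrow(i).nonzero()[1]
        return {self.term_ids[j] for j in cols}

    def term_counts(self) -> pd.Series:
        """Number of annotated entities per term."""
        counts = np.asarray(self.incidence.sum(axis=0)).ravel()
        return pd.Series(counts, index=self.term_ids)

    def annotated_entities(self) -> set[str]:
        rows = np.asarray(self.incidence.sum(axis=1)).ravel()
        return {e for e, c in zip(self.entity_ids, rows) if c > 0}

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"AnnotationStore({len(self.entity_ids)} entities x {len(self.term_ids)} terms, "
            f"{self.incidence.nnz} annotations, propagated={self.propagated})"
        )


def build_annotations(
    anno_table: str | Path,
    dag: OntologyDAG,
    entities: EntityTable,
) -> AnnotationStore:
    """Load a two-column (entity, term) TSV into an unpropagated store.

    Rows naming unknown entities or terms are dropped and counted in the
    attached :class:`LoadReport`; duplicate rows collapse to one incidence
    bit; terms given by an ``alt_id`` are mapped to their canonical id.
    """
    frame = pd.read_csv(anno_table, sep="\t", dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise AnnotationError("annotation file must have at least 2 columns (entity, term)")
    ecol, tcol = frame.columns[:2]
    report = LoadReport(n_rows=len(frame))
    pairs: set[tuple[str, str]] = set()
    for entity, term in frame[[ecol, tcol]].itertuples(index=False, name=None):
        if term not in dag.terms:
            mapped = dag.alt_id_map.get(term)
            if mapped is None:
                report.n_unknown_term += 1
                continue
            term = mapped
            report.n_alt_mapped += 1
        if entity not in entities:
            report.n_unknown_entity += 1
            continue
        if (entity, term) in pairs:
            report.n_duplicates += 1
            continue
        pairs.add((entity, term))
    report.n_kept = len(pairs)
    report.log()
    return annotations_from_pairs(pairs, entities.ids, report=report)


def annotations_from_pairs(
    pairs: Iterable[tuple[str, str]],
    entity_ids: list[str] | None = None,
    report: LoadReport | None = None,
) -> AnnotationStore:
    """Build an unpropagated store from (entity, term) pairs."""
    pairs = list(pairs)
    if entity_ids is None:
        entity_ids = sorted({e for e, _ in pairs})
    term_ids = sorted({t for _, t in pairs})
    eindex = {e: i for i, e in enumerate(entity_ids)}
    tindex = {t: j for j, t in enumerate(term_ids)}
    rows = [eindex[e] for e, _ in pairs]
    cols = [tindex[t] for _, t in pairs]
    data = np.ones(len(pairs), dtype=np.int8)
    inc = sp.coo_matrix((data, (rows, cols)), shape=(len(entity_ids), len(term_ids)))
    return AnnotationStore(entity_ids, term_ids, inc.tocsr(), propagated=False, report=report)


def propagate(anno: AnnotationStore, dag: OntologyDAG) -> AnnotationStore:
    """Apply the true-path rule: copy every annotation to all ancestors.

    Returns a new store with ``propagated=True``.  Term columns that remain
    all-zero are dropped, so only the annotated ("valid") part of the
    ontology is kept.  The operation is idempotent and never clears a bit.
    """
    unknown = [t for t in anno.term_ids if t not in dag.graph]
    if unknown:
        raise AnnotationError(f"annotation store names terms absent from the ontology: {unknown[:5]}")

    all_terms = sorted(dag.graph.nodes)
    tindex = {t: j for j, t in enumerate(all_terms)}
    # closure matrix R[j, k] = 1 if term k is term j or an ancestor of term j
    n_t = len(all_terms)
    closure = sp.lil_matrix((n_t, n_t), dtype=np.int8)
    for t in all_terms:
        j = tindex[t]
        closure[j, j] = 1
        for a in dag.ancestors(t):
            closure[j, tindex[a]] = 1

    # embed the store's columns into the full term universe
    embed = sp.lil_matrix((len(anno.term_ids), n_t), dtype=np.int8)
    for i, t in enumerate(anno.term_ids):
        embed[i, tindex[t]] = 1
    full = (anno.incidence @ embed.tocsr() @ closure.tocsr()) > 0

    full = sp.csr_matrix(full, dtype=np.int8)
    keep = np.flatnonzero(np.asarray(full.sum(axis=0)).ravel() > 0)
    kept_terms = [all_terms[j] for j in keep]
    return AnnotationStore(
        anno.entity_ids, kept_terms, full[:, keep], propagated=True, report=anno.report
    )
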