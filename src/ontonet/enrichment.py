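"""Over-representation analysis of entity sets against an annotated ontology.

Given a background of N annotatable entities, K of which are annotated to a
term, and an input set of n entities of which x carry the term, the three
exact tests ask how surprising an overlap of at least x is:

* hypergeometric upper tail  P(X >= x), X ~ Hypergeom(N, K, n);
* binomial upper tail with success probability q = K/N;
* one-sided (greater) Fisher exact test on [[x, K-x], [n-x, N-K-n+x]] —
  identical to the hypergeometric tail by construction.

Because annotations obey the true-path rule, raw per-term tests are heavily
correlated along the DAG.  Two decorrelation algorithms are provided:

* ``elim`` — terms are tested leaves-first; when a term's p-value falls
  below a cutoff, its annotated entities are removed from all of its strict
  ancestors before those are tested, so a parent whose signal is fully
  explained by a significant child drops out.
* ``parent_child`` — each term is tested inside the annotation universe of
  its parents rather than the global background, measuring refinement over
  the parents; root terms keep p = 1.

All tests are one-sided for over-representation and include the observed
count.  Multiple-testing adjustment (BH / Bonferroni / Holm) is computed
across the set of actually tested terms for each run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ontology import AnnotationStore, OntologyDAG

logger = logging.getLogger("ontonet")

TESTS = ("hypergeometric", "binomial", "fisher")
ALGORITHMS = ("none", "elim", "parent_child")
ADJUST_METHODS = ("BH", "bonferroni", "holm", "none")


class EnrichmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------


def _check_counts(x: int, n: int, K: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N and 0 <= x <= min(n, K)):
        raise ValueError(f"invalid counts x={x}, n={n}, K={K}, N={N}")


def tail_hypergeometric(x: int, n: int, K: int, N: int) -> float:
    """P(X >= x) for X ~ Hypergeom(N, K, n): upper tail including x."""
    _check_counts(x, n, K, N)
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def tail_binomial(x: int, n: int, K: int, N: int) -> float:
    """P(X >= x) for X ~ Binomial(n, K/N): upper tail including x."""
    _check_counts(x, n, K, N)
    if N == 0 or x == 0:
        return 1.0
    return float(stats.binom.sf(x - 1, n, K / N))


def fisher_onesided(x: int, n: int, K: int, N: int) -> float:
    """One-sided (greater) Fisher exact p for the 2x2 overlap table."""
    _check_counts(x, n, K, N)
    if x <= max(0, n + K - N):
        return 1.0  # at or below the hypergeometric support minimum
    table = [[x, K - x], [n - x, N - K - n + x]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


_TEST_FUNCS = {
    "hypergeometric": tail_hypergeometric,
    "binomial": tail_binomial,
    "fisher": fisher_onesided,
}


# ---------------------------------------------------------------------------
# p-value adjustment
# ---------------------------------------------------------------------------


def adjust_pvalues(pvalues: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment: BH step-up, Bonferroni, Holm or none."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values outside [0, 1]")
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.clip(p * p.size, 0.0, 1.0)
    if method == "BH":
        return multipletests(p, method="fdr_bh")[1] if p.size else p.copy()
    if method == "holm":
        return multipletests(p, method="holm")[1] if p.size else p.copy()
    raise EnrichmentError(f"unknown adjustment method {method!r}; choose from {ADJUST_METHODS}")


# ---------------------------------------------------------------------------
# configuration and result containers
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentConfig:
    """Settings for one enrichment run.

    Defaults follow common ontology-tool practice: hypergeometric test, no
    DAG algorithm, BH adjustment, elim cutoff 0.01, minimum term size 2.
    """

    test: str = "hypergeometric"
    algorithm: str = "none"
    elim_cutoff: float = 0.01
    p_adjust: str = "BH"
    min_term_size: int = 2
    background: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.test not in TESTS:
            raise EnrichmentError(f"unknown test {self.test!r}; choose from {TESTS}")
        if self.algorithm not in ALGORITHMS:
            raise EnrichmentError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")
        if self.p_adjust not in ADJUST_METHODS:
            raise EnrichmentError(f"unknown p_adjust {self.p_adjust!r}; choose from {ADJUST_METHODS}")
        if not (0.0 < self.elim_cutoff < 1.0):
            raise EnrichmentError("elim_cutoff must lie in (0, 1)")
        if self.min_term_size < 1:
            raise EnrichmentError("min_term_size must be >= 1")
        if self.background is not None:
            self.background = frozenset(self.background)


@dataclass
class EnrichmentResult:
    """Per-term enrichment table plus run metadata.

    ``table`` has one row per tested term with columns term_id, term_name,
    K (background entities annotated), x (input entities annotated),
    expected (n*K/N), fold (x/expected), pvalue, adj_pvalue, members
    (sorted overlapping entity ids, comma-joined), sorted by adj_pvalue,
    then pvalue, then term_id.  For algorithm=elim, K/x/members reflect the
    counts actually tested (after eliminations).
    """

    table: pd.DataFrame
    n_background: int
    n_input: int
    config: EnrichmentConfig
    dropped_input: tuple[str, ...] = ()

    def top_terms(self, top_n: int) -> list[str]:
        return list(self.table["term_id"].iloc[:top_n])

    def members_of(self, term_id: str) -> set[str]:
        row = self.table.loc[self.table["term_id"] == term_id, "members"]
        if row.empty:
            raise KeyError(f"term {term_id!r} was not tested")
        cell = row.iloc[0]
        return set(cell.split(",")) if cell else set()


# ---------------------------------------------------------------------------
# the enrichment engine
# ---------------------------------------------------------------------------


def _per_term_sets(
    anno: AnnotationStore, background: set[str]
) -> dict[str, frozenset[str]]:
    """Annotated-entity set per term, restricted to the background."""
    out: dict[str, frozenset[str]] = {}
    inc = anno.incidence.tocsc()
    bg_idx = {i for i, e in enumerate(anno.entity_ids) if e in background}
    for j, t in enumerate(anno.term_ids):
        rows = inc.indices[inc.indptr[j]: inc.indptr[j + 1]]
        members = frozenset(anno.entity_ids[i] for i in rows if i in bg_idx)
        out[t] = members
    return out


def elim_pvalues(
    dag: OntologyDAG,
    term_sets: dict[str, frozenset[str]],
    input_set: frozenset[str],
    n: int,
    N: int,
    test: str,
    elim_cutoff: float,
) -> dict[str, tuple[float, frozenset[str], frozenset[str]]]:
    """Leaves-first elim pass over the tested terms.

    Returns per term ``(pvalue, K_set, x_set)`` where ``K_set`` / ``x_set``
    are the background / input annotation sets after removing entities
    eliminated by the term's significant descendants.
    """
    tf = _TEST_FUNCS[test]
    eliminated: dict[str, set[str]] = {t: set() for t in term_sets}
    out: dict[str, tuple[float, frozenset[str], frozenset[str]]] = {}
    order = [t for t in reversed(dag.topological_order()) if t in term_sets]
    for t in order:
        k_set = frozenset(term_sets[t] - eliminated[t])
        x_set = frozenset(k_set & input_set)
        p = tf(len(x_set), n, len(k_set), N)
        out[t] = (p, k_set, x_set)
        if p < elim_cutoff:
            for a in dag.ancestors(t):
                if a in eliminated:
                    eliminated[a] |= term_sets[t]
    return out


def parent_child_pvalues(
    dag: OntologyDAG,
    term_sets: dict[str, frozenset[str]],
    input_set: frozenset[str],
    background: frozenset[str],
    test: str,
) -> dict[str, float]:
    """Parent–child p-values: each term tested inside its parents' universe.

    The universe for term t is the union of its parents' annotated entities
    (within the background); root terms keep p = 1 by convention.
    """
    tf = _TEST_FUNCS[test]
    out: dict[str, float] = {}
    for t, members in term_sets.items():
        parents = [p for p in dag.terms[t].parent_ids if p in dag.graph]
        if not parents:
            out[t] = 1.0
            continue
        universe: set[str] = set()
        for p_id in parents:
            universe |= term_sets.get(p_id, frozenset())
        universe &= background
        K = len(members & universe)
        n_u = len(input_set & universe)
        x = len(members & input_set & universe)
        out[t] = tf(x, n_u, K, len(universe))
    return out


def enrich(
    input_ids: Sequence[str],
    anno: AnnotationStore,
    dag: OntologyDAG,
    cfg: EnrichmentConfig | None = None,
) -> EnrichmentResult:
    """Test an entity set for over-represented ontology terms.

    Requires a propagated annotation store.  The background defaults to all
    annotated entities; a user background is intersected with them.  Input
    entities outside the background are dropped and reported.  Terms with
    fewer than ``min_term_size`` background annotations are skipped.
    """
    cfg = cfg or EnrichmentConfig()
    if not anno.propagated:
        raise EnrichmentError("enrichment requires a propagated annotation store")

    annotated = anno.annotated_entities()
    background = frozenset(annotated if cfg.background is None else set(cfg.background) & annotated)
    if not background:
        raise EnrichmentError("empty background after restriction to annotated entities")

    input_all = list(dict.fromkeys(input_ids))
    input_set = frozenset(e for e in input_all if e in background)
    dropped = tuple(e for e in input_all if e not in background)
    if dropped:
        logger.info("enrich: dropped %d input entities outside the background", len(dropped))
    if not input_set:
        raise EnrichmentError("no input entities in background")

    N, n = len(background), len(input_set)
    all_sets = _per_term_sets(anno, set(background))
    term_sets = {t: s for t, s in all_sets.items() if len(s) >= cfg.min_term_size}
    tf = _TEST_FUNCS[cfg.test]

    rows = []
    if cfg.algorithm == "elim":
        res = elim_pvalues(dag, term_sets, input_set, n, N, cfg.test, cfg.elim_cutoff)
        for t, (p, k_set, x_set) in res.items():
            rows.append((t, len(k_set), len(x_set), p, x_set))
    elif cfg.algorithm == "parent_child":
        # parent universes need every term's background set, not only tested ones
        pc = parent_child_pvalues(dag, all_sets, input_set, background, cfg.test)
        for t, members in term_sets.items():
            x_set = frozenset(members & input_set)
            rows.append((t, len(members), len(x_set), pc[t], x_set))
    else:
        for t, members in term_sets.items():
            x_set = frozenset(members & input_set)
            rows.append((t, len(members), len(x_set), tf(len(x_set), n, len(members), N), x_set))

    table = pd.DataFrame(
        rows, columns=["term_id", "K", "x", "pvalue", "_members"]
    )
    table["term_name"] = [dag.terms[t].name for t in table["term_id"]]
    table["expected"] = n * table["K"] / N
    with np.errstate(divide="ignore", invalid="ignore"):
        table["fold"] = np.where(table["expected"] > 0, table["x"] / table["expected"], 0.0)
    table["adj_pvalue"] = adjust_pvalues(table["pvalue"].to_numpy(), cfg.p_adjust)
    table["members"] = [",".join(sorted(m)) for m in table["_members"]]
    table = table.drop(columns="_members")
    table = table.sort_values(
        ["adj_pvalue", "pvalue", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
    table = table[
        ["term_id", "term_name", "K", "x", "expected", "fold", "pvalue", "adj_pvalue", "members"]
    ]
    return EnrichmentResult(table, N, n, cfg, dropped)


def top_terms_subgraph(
    result: EnrichmentResult, dag: OntologyDAG, top_n: int = 5
) -> tuple[OntologyDAG, dict[str, float]]:
    """Sub-DAG induced by the `top_n` best-ranked terms plus their ancestors.

    Ties at the selection boundary break lexicographically by term id (the
    result table is already sorted that way).  The second return value maps
    every retained term that was tested to its adjusted p-value; untested
    ancestors are absent from the map.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    selected = result.top_terms(top_n)
    sub = dag.induced_subgraph(selected)
    tested = dict(zip(result.table["term_id"], result.table["adj_pvalue"]))
    annot = {t: float(tested[t]) for t in sub.graph.nodes if t in tested}
    return sub, annot
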