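"""Random walk with restart (RWR) and group-contact significance.

RWR diffuses probability mass from a set of seed nodes over a weighted
network: at every step the walker either follows an edge (with probability
1 − r, choosing neighbours proportionally to edge weight) or teleports back
to the seed distribution (with probability r).  The stationary distribution
p solves

    p = (1 − r) · W · p + r · p0,

with W the column-normalised weighted adjacency matrix and p0 the
normalised seed weights.  Seeds may be weighted; each group's weights are
normalised to sum to one before walking.

Contact analysis runs RWR once per seed group and scores each pair of
groups by the inner product of their stationary distributions — large when
the two groups diffuse into the same part of the network.  Significance is
empirical: the same walks are repeated for ``n_perm`` random seed sets of
identical cardinality and weight multiset drawn uniformly from the network
nodes, yielding a permutation z-score and an empirical p-value
(1 + #{perm ≥ observed}) / (1 + n_perm) per pair, BH-adjusted across pairs.
Pairs below the adjusted-p cutoff form the significant-contact network,
with the z-score as edge weight.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import adjust_pvalues
from .similarity import SimilarityNetwork

logger = logging.getLogger("ontonet")

#: permutation chunk width; fixed so serial and parallel runs perform the
#: same floating-point operations
_PERM_CHUNK = 200


class RWRError(ValueError):
    pass


# ---------------------------------------------------------------------------
# the walk
# ---------------------------------------------------------------------------


def transition_matrix(net: SimilarityNetwork) -> tuple[list[str], np.ndarray]:
    """Column-stochastic transition matrix of a weighted network.

    Each node distributes its outgoing mass proportionally to edge weight;
    isolated nodes receive a self-loop to keep the matrix stochastic.
    """
    nodes = list(net.graph.nodes)
    A = nx.to_numpy_array(net.graph, nodelist=nodes, weight="weight")
    col = A.sum(axis=0)
    isolated = col == 0
    if isolated.any():
        idx = np.flatnonzero(isolated)
        A[idx, idx] = 1.0
        col = A.sum(axis=0)
    return nodes, A / col


def _rwr_batch(
    W: np.ndarray,
    P0: np.ndarray,
    restart: float,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Iterate p ← (1−r)·W·p + r·p0 for every column of P0 simultaneously."""
    if restart == 1.0:
        return P0.copy()
    P = P0.copy()
    for _ in range(max_iter):
        P_next = (1.0 - restart) * (W @ P) + restart * P0
        if np.abs(P_next - P).sum(axis=0).max() < tol:
            return P_next
        P = P_next
    logger.warning("RWR did not converge within %d iterations", max_iter)
    return P


def seed_vector(nodes: list[str], seeds: Mapping[str, float]) -> np.ndarray:
    """Normalised seed distribution over `nodes`; unknown seeds are ignored."""
    index = {v: i for i, v in enumerate(nodes)}
    p0 = np.zeros(len(nodes))
    for node, w in seeds.items():
        if w < 0:
            raise RWRError(f"negative seed weight for {node!r}")
        if node in index:
            p0[index[node]] += w
    total = p0.sum()
    if total == 0:
        raise RWRError("seed vector is all zero (no positive-weight seed in the network)")
    return p0 / total


def rwr(
    net: SimilarityNetwork,
    seeds: Mapping[str, float],
    restart: float = 0.75,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> pd.Series:
    """Stationary RWR distribution for one weighted seed set.

    Returns a probability vector over the network nodes (sums to 1 within
    the tolerance).  ``restart`` must lie in (0, 1]; r = 1 returns the seed
    distribution itself.  The walk stays inside the connected components
    that carry seeds.
    """
    if not (0.0 < restart <= 1.0):
        raise RWRError("restart probability must lie in (0, 1]; r = 0 is not supported")
    nodes, W = transition_matrix(net)
    p0 = seed_vector(nodes, seeds)
    p = _rwr_batch(W, p0[:, None], restart, tol, max_iter)[:, 0]
    return pd.Series(p, index=nodes)


# ---------------------------------------------------------------------------
# contact significance
# ---------------------------------------------------------------------------

SeedSpec = Mapping[str, Mapping[str, float]]  # group id -> {entity id: weight}


@dataclass
class ContactResult:
    """Group×group contact strengths with permutation significance.

    ``contact`` holds the observed inner products C(g, h); ``zscore`` the
    permutation z = (C − μ) / σ; ``pvalue`` the empirical
    (1 + #{perm ≥ C}) / (1 + n_perm); ``adj_pvalue`` the BH adjustment over
    the off-diagonal pairs.  All matrices are symmetric; the diagonal is
    not tested.
    """

    groups: list[str]
    contact: pd.DataFrame
    zscore: pd.DataFrame
    pvalue: pd.DataFrame
    adj_pvalue: pd.DataFrame
    params: dict = field(default_factory=dict)
    dropped_seeds: dict[str, list[str]] = field(default_factory=dict)

    def pairs(self) -> list[tuple[str, str]]:
        return [
            (g, h)
            for i, g in enumerate(self.groups)
            for h in self.groups[i + 1:]
        ]


class ContactNetwork:
    """Graph over seed groups; edges are significant contacts weighted by z."""

    def __init__(self, graph: nx.Graph, cutoff: float):
        for _, _, w in graph.edges(data="weight"):
            if w is None or not np.isfinite(w):
                raise RWRError("contact edges must carry finite z-scores")
        self.graph = graph
        self.cutoff = cutoff

    def to_networkx(self) -> nx.Graph:
        return self.graph.copy()

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ContactNetwork({self.graph.number_of_nodes()} groups, "
            f"{self.graph.number_of_edges()} significant contacts, cutoff={self.cutoff})"
        )


def _group_matrix(nodes: list[str], seeds: SeedSpec, groups: list[str]) -> np.ndarray:
    return np.column_stack([seed_vector(nodes, seeds[g]) for g in groups])


def _permuted_seed_matrix(
    n_nodes: int, weight_multisets: list[np.ndarray], n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Seed matrix for all permutations of all groups, column-blocked by perm.

    Each permutation redraws every group's seeds uniformly (without
    replacement) from the network nodes, reusing the group's weight
    multiset in drawn order.
    """
    G = len(weight_multisets)
    P0 = np.zeros((n_nodes, n_perm * G))
    for b in range(n_perm):
        for gi, weights in enumerate(weight_multisets):
            pos = rng.choice(n_nodes, size=len(weights), replace=False)
            col = np.zeros(n_nodes)
            col[pos] = weights
            P0[:, b * G + gi] = col / col.sum()
    return P0


def contact_pipeline(
    net: SimilarityNetwork,
    seeds: SeedSpec,
    restart: float = 0.75,
    n_perm: int = 1000,
    cutoff: float = 0.1,
    rng_seed: int = 0,
    min_seeds: int = 1,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    workers: int = 1,
) -> tuple[ContactResult, ContactNetwork]:
    """RWR contact strength and significance between weighted seed groups.

    Seeds absent from the network are dropped and reported; groups left
    with fewer than ``min_seeds`` usable seeds are discarded.  At least two
    groups must survive and ``n_perm`` must be at least 10.  With a fixed
    ``rng_seed`` the whole pipeline is reproducible, serial or parallel.
    """
    if n_perm < 10:
        raise RWRError("n_perm must be >= 10")
    if not (0.0 < cutoff <= 1.0):
        raise RWRError("cutoff must lie in (0, 1]")
    nodes, W = transition_matrix(net)
    node_set = set(nodes)

    usable: dict[str, dict[str, float]] = {}
    dropped: dict[str, list[str]] = {}
    for g in sorted(seeds):
        inside = {e: w for e, w in seeds[g].items() if e in node_set and w > 0}
        outside = sorted(set(seeds[g]) - set(inside))
        if outside:
            dropped[g] = outside
        if len(inside) >= min_seeds and sum(inside.values()) > 0:
            usable[g] = inside
        else:
            logger.info("contact: group %r dropped (%d usable seeds < %d)", g, len(inside), min_seeds)
    groups = sorted(usable)
    if len(groups) < 2:
        raise RWRError("need at least 2 seed groups with usable seeds")

    P0_obs = _group_matrix(nodes, usable, groups)
    P_obs = _rwr_batch(W, P0_obs, restart, tol, max_iter)
    C_obs = P_obs.T @ P_obs  # observed contact matrix, symmetric

    rng = np.random.default_rng(rng_seed)
    multisets = [np.array(sorted(usable[g].values(), reverse=True), dtype=float) for g in groups]
    P0_perm = _permuted_seed_matrix(len(nodes), multisets, n_perm, rng)

    # walk the permuted seeds in fixed-size chunks; the chunking (hence the
    # floating-point result) is identical for any worker count
    chunks = [
        P0_perm[:, i: i + _PERM_CHUNK] for i in range(0, P0_perm.shape[1], _PERM_CHUNK)
    ]
    if workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            walked = list(pool.map(lambda c: _rwr_batch(W, c, restart, tol, max_iter), chunks))
    else:
        walked = [_rwr_batch(W, c, restart, tol, max_iter) for c in chunks]
    P_perm = np.concatenate(walked, axis=1)

    G = len(groups)
    # per-permutation contact matrices: C_perm[b] = P_b^T P_b
    P_blocks = P_perm.reshape(len(nodes), n_perm, G).transpose(1, 0, 2)  # (n_perm, n, G)
    C_perm = np.einsum("bng,bnh->bgh", P_blocks, P_blocks)

    mu = C_perm.mean(axis=0)
    sd = C_perm.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = np.where(sd > 0, (C_obs - mu) / sd, 0.0)
    P_emp = (1.0 + (C_perm >= C_obs[None, :, :]).sum(axis=0)) / (1.0 + n_perm)

    # BH over the off-diagonal pairs only
    iu = np.triu_indices(G, k=1)
    adj_flat = adjust_pvalues(P_emp[iu], "BH")
    Padj = np.ones((G, G))
    Padj[iu] = adj_flat
    Padj = np.minimum(Padj, Padj.T)
    np.fill_diagonal(Padj, 1.0)

    def df(M: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(M, index=groups, columns=groups)

    params = {
        "restart": restart,
        "tolerance": tol,
        "max_iter": max_iter,
        "n_perm": n_perm,
        "cutoff": cutoff,
        "rng_seed": rng_seed,
        "min_seeds": min_seeds,
        "contact_statistic": "inner product of group stationary distributions",
        "null_model": "uniform seed resampling preserving group size and weight multiset",
    }
    result = ContactResult(groups, df(C_obs), df(Z), df(P_emp), df(Padj), params, dropped)
    return result, significant_contacts(result, cutoff)


def significant_contacts(result: ContactResult, cutoff: float = 0.1) -> ContactNetwork:
    """Threshold the contact result into a network: keep pairs with adj_p < cutoff."""
    if not (0.0 < cutoff <= 1.0):
        raise RWRError("cutoff must lie in (0, 1]")
    graph = nx.Graph()
    graph.add_nodes_from(result.groups)
    for g, h in result.pairs():
        # cutoff = 1 keeps every tested pair (adjusted p never exceeds 1)
        if result.adj_pvalue.loc[g, h] < cutoff or cutoff == 1.0:
            graph.add_edge(g, h, weight=float(result.zscore.loc[g, h]))
    return ContactNetwork(graph, cutoff)
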