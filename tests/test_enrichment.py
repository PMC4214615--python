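"""Exact tests, DAG-aware adjustment algorithms and the enrichment engine."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontonet import (
    EnrichmentConfig,
    EnrichmentError,
    OntologyDAG,
    Term,
    adjust_pvalues,
    enrich,
    fisher_onesided,
    tail_binomial,
    tail_hypergeometric,
    top_terms_subgraph,
)

from conftest import make_propagated


def hypergeom_tail_bruteforce(x, n, K, N):
    """Upper tail by exhaustive pmf summation."""
    return sum(
        comb(K, k) * comb(N - K, n - k) / comb(N, n)
        for k in range(x, min(n, K) + 1)
    )


def binom_tail_bruteforce(x, n, q):
    return sum(comb(n, k) * q**k * (1 - q) ** (n - k) for k in range(x, n + 1))


def count_tuples(n_max):
    return [
        (x, n, K, N)
        for N in range(n_max + 1)
        for K in range(N + 1)
        for n in range(N + 1)
        for x in range(min(n, K) + 1)
    ]


# ---------------------------------------------------------------------------
# exact tests vs enumeration oracles
# ---------------------------------------------------------------------------


class TestExactTests:
    def test_x_zero_is_one(self):
        assert tail_hypergeometric(0, 5, 3, 10) == 1.0
        assert tail_binomial(0, 5, 3, 10) == 1.0
        assert fisher_onesided(0, 5, 3, 10) == 1.0

    def test_hand_value(self):
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        assert tail_hypergeometric(4, 4, 5, 10) == pytest.approx(5 / 210, abs=1e-15)

    def test_binomial_saturated(self):
        assert tail_binomial(6, 6, 10, 10) == pytest.approx(1.0)

    def test_fisher_degenerate_K_equals_N(self):
        assert fisher_onesided(3, 3, 8, 8) == pytest.approx(1.0)

    def test_hypergeometric_matches_bruteforce_small_sweep(self):
        for x, n, K, N in count_tuples(9):
            assert tail_hypergeometric(x, n, K, N) == pytest.approx(
                hypergeom_tail_bruteforce(x, n, K, N), abs=1e-12
            )

    def test_binomial_matches_bruteforce(self):
        for N in (5, 8, 12):
            for K in range(N + 1):
                for n in range(1, N + 1):
                    for x in range(min(n, K) + 1):
                        assert tail_binomial(x, n, K, N) == pytest.approx(
                            binom_tail_bruteforce(x, n, K / N), abs=1e-12
                        )

    def test_fisher_equals_hypergeometric(self):
        for x, n, K, N in count_tuples(9):
            assert fisher_onesided(x, n, K, N) == pytest.approx(
                tail_hypergeometric(x, n, K, N), abs=1e-12
            )

    def test_domain_errors(self):
        for bad in [(5, 4, 5, 10), (1, 2, 11, 10), (-1, 2, 3, 10)]:
            with pytest.raises(ValueError):
                tail_hypergeometric(*bad)

    @given(st.integers(1, 30), st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_nonincreasing_in_x(self, N, K, n):
        K, n = min(K, N), min(n, N)
        for tail in (tail_hypergeometric, tail_binomial, fisher_onesided):
            ps = [tail(x, n, K, N) for x in range(min(n, K) + 1)]
            assert ps[0] == 1.0
            assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


# ---------------------------------------------------------------------------
# p-value adjustment
# ---------------------------------------------------------------------------


class TestAdjust:
    def test_single_p_unchanged_under_bh(self):
        assert adjust_pvalues([0.03], "BH")[0] == pytest.approx(0.03)

    def test_bh_stepup_arithmetic(self):
        # p_(i) * m / i then step-up: all become 0.04
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "BH")
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_bonferroni_clipped(self):
        assert adjust_pvalues([0.3], "bonferroni")[0] == pytest.approx(0.3)
        assert adjust_pvalues([0.3] * 5, "bonferroni")[0] == pytest.approx(1.0)

    def test_holm_vs_manual(self):
        p = [0.01, 0.04, 0.03]
        # sorted: 0.01*3=0.03, 0.03*2=0.06, 0.04*1=0.04 -> monotone: 0.03, 0.06, 0.06
        assert adjust_pvalues(p, "holm") == pytest.approx([0.03, 0.06, 0.06])

    def test_unknown_method(self):
        with pytest.raises(EnrichmentError):
            adjust_pvalues([0.1], "fdr_by")

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([1.5], "BH")


# ---------------------------------------------------------------------------
# enrichment engine
# ---------------------------------------------------------------------------


def planted_dag_store(n_bg=40, k_planted=8):
    """Root R covers all entities; term T annotates the first k_planted."""
    dag = OntologyDAG([Term("R"), Term("T")], [("T", "R")])
    ids = [f"d{i:02d}" for i in range(n_bg)]
    pairs = [(e, "T") for e in ids[:k_planted]] + [(e, "R") for e in ids[k_planted:]]
    return dag, make_propagated(pairs, ids, dag), ids


class TestEnrich:
    def test_requires_propagated_store(self, chain_dag):
        from conftest import make_store

        store = make_store([("d1", "C")], ["d1"])
        with pytest.raises(EnrichmentError, match="propagated"):
            enrich(["d1"], store, chain_dag)

    def test_root_only_input_nothing_significant(self, chain_dag):
        store = make_propagated(
            [("d1", "A"), ("d2", "C"), ("d3", "C")], ["d1", "d2", "d3"], chain_dag
        )
        res = enrich(["d1"], store, chain_dag, EnrichmentConfig(min_term_size=1))
        root = res.table.set_index("term_id").loc["A"]
        assert root["pvalue"] == pytest.approx(1.0)

    def test_planted_term_closed_form(self):
        dag, store, ids = planted_dag_store()
        res = enrich(ids[:8], store, dag)
        top = res.table.iloc[0]
        assert top["term_id"] == "T"
        # C(8,8) * C(32,0) / C(40,8)
        assert top["pvalue"] == pytest.approx(1 / comb(40, 8), rel=1e-12)
        assert top["x"] == 8 and top["K"] == 8
        assert res.n_background == 40 and res.n_input == 8

    def test_members_reproduce_x(self):
        dag, store, ids = planted_dag_store()
        res = enrich(ids[:8] + ids[20:25], store, dag)
        for _, row in res.table.iterrows():
            members = set(row["members"].split(",")) if row["members"] else set()
            assert len(members) == row["x"]

    def test_input_order_invariance(self):
        dag, store, ids = planted_dag_store()
        a = enrich(ids[:10], store, dag).table
        b = enrich(ids[:10][::-1], store, dag).table
        assert a.equals(b)

    def test_input_outside_background_dropped(self):
        dag, store, ids = planted_dag_store()
        res = enrich(ids[:8] + ["ghost"], store, dag)
        assert res.dropped_input == ("ghost",)
        with pytest.raises(EnrichmentError, match="no input entities"):
            enrich(["ghost"], store, dag)

    def test_user_background_restriction(self):
        dag, store, ids = planted_dag_store()
        cfg = EnrichmentConfig(background=frozenset(ids[:20]))
        res = enrich(ids[:8], store, dag, cfg)
        assert res.n_background == 20


class TestElim:
    def chain_setup(self):
        """C absorbs the signal; B annotates exactly C's entities."""
        dag = OntologyDAG(
            [Term("A"), Term("B"), Term("C")], [("B", "A"), ("C", "B")]
        )
        ids = [f"e{i:02d}" for i in range(20)]
        pairs = [(e, "C") for e in ids[:5]] + [(e, "A") for e in ids[5:]]
        return dag, make_propagated(pairs, ids, dag), ids

    def test_none_leaves_both_significant(self):
        dag, store, ids = self.chain_setup()
        res = enrich(ids[:5], store, dag, EnrichmentConfig(algorithm="none"))
        t = res.table.set_index("term_id")
        assert t.loc["C", "pvalue"] == pytest.approx(1 / comb(20, 5), rel=1e-12)
        assert t.loc["B", "pvalue"] == pytest.approx(1 / comb(20, 5), rel=1e-12)

    def test_elim_silences_redundant_parent(self):
        dag, store, ids = self.chain_setup()
        res = enrich(ids[:5], store, dag, EnrichmentConfig(algorithm="elim"))
        t = res.table.set_index("term_id")
        assert t.loc["C", "pvalue"] == pytest.approx(1 / comb(20, 5), rel=1e-12)
        assert t.loc["B", "x"] == 0
        assert t.loc["B", "pvalue"] == pytest.approx(1.0)

    def test_tiny_cutoff_degenerates_to_none(self):
        dag, store, ids = self.chain_setup()
        none = enrich(ids[:5], store, dag, EnrichmentConfig(algorithm="none"))
        elim = enrich(
            ids[:5], store, dag,
            EnrichmentConfig(algorithm="elim", elim_cutoff=1e-300),
        )
        assert np.allclose(
            none.table.sort_values("term_id")["pvalue"],
            elim.table.sort_values("term_id")["pvalue"],
        )

    def test_diamond_eliminations_union_before_root(self, diamond_dag):
        # B and C both significant; A then loses the union of their entities
        ids = [f"e{i:02d}" for i in range(20)]
        pairs = (
            [(e, "B") for e in ids[:5]]
            + [(e, "C") for e in ids[3:8]]
            + [(e, "A") for e in ids[8:]]
        )
        store = make_propagated(pairs, ids, diamond_dag)
        res = enrich(ids[:8], store, diamond_dag, EnrichmentConfig(algorithm="elim"))
        t = res.table.set_index("term_id")
        assert t.loc["A", "x"] == 0  # union of B's and C's entities removed
        assert t.loc["A", "K"] == 12
        assert t.loc["A", "pvalue"] == pytest.approx(1.0)


class TestParentChild:
    def test_child_equal_to_parent_is_unrefined(self):
        dag = OntologyDAG([Term("A"), Term("B")], [("B", "A")])
        ids = [f"e{i}" for i in range(8)]
        pairs = [(e, "B") for e in ids]  # B's set equals A's after propagation
        store = make_propagated(pairs, ids, dag)
        res = enrich(ids[:3], store, dag, EnrichmentConfig(algorithm="parent_child"))
        t = res.table.set_index("term_id")
        assert t.loc["B", "pvalue"] == pytest.approx(1.0)

    def test_refinement_formula_on_fixture(self):
        # A root (all 15), P annotates 10, t annotates 3 of P's 10.
        dag = OntologyDAG([Term("A"), Term("P"), Term("t")], [("P", "A"), ("t", "P")])
        ids = [f"e{i:02d}" for i in range(15)]
        pairs = (
            [(e, "t") for e in ids[:3]]
            + [(e, "P") for e in ids[3:10]]
            + [(e, "A") for e in ids[10:]]
        )
        store = make_propagated(pairs, ids, dag)
        # input: t's 3 entities, 2 more in P, 2 outside P
        input_ids = ids[:3] + ids[5:7] + ids[12:14]
        res = enrich(input_ids, store, dag, EnrichmentConfig(algorithm="parent_child"))
        t = res.table.set_index("term_id")
        assert t.loc["t", "pvalue"] == pytest.approx(
            tail_hypergeometric(3, 5, 3, 10), rel=1e-12
        )
        assert t.loc["t", "pvalue"] == pytest.approx(1 / 12, rel=1e-12)

    def test_root_is_one_by_convention(self):
        dag, store, ids = planted_dag_store()
        res = enrich(ids[:8], store, dag, EnrichmentConfig(algorithm="parent_child"))
        t = res.table.set_index("term_id")
        assert t.loc["R", "pvalue"] == pytest.approx(1.0)


class TestTopTermsSubgraph:
    def test_top_n_exceeding_tested_terms(self):
        dag, store, ids = planted_dag_store()
        res = enrich(ids[:8], store, dag)
        sub, pvals = top_terms_subgraph(res, dag, top_n=50)
        assert set(sub.terms) == {"R", "T"}
        assert set(pvals) == {"R", "T"}

    def test_top_one_pulls_ancestor_chain(self):
        dag, store, ids = planted_dag_store()
        res = enrich(ids[:8], store, dag)
        sub, pvals = top_terms_subgraph(res, dag, top_n=1)
        assert set(sub.terms) == {"T", "R"}  # planted term plus its ancestor
        assert pvals["T"] == pytest.approx(res.table.iloc[0]["adj_pvalue"])

    def test_ties_break_by_term_id(self, chain_dag):
        store = make_propagated(
            [("d1", "C"), ("d2", "C"), ("d3", "A"), ("d4", "A")],
            ["d1", "d2", "d3", "d4"], chain_dag,
        )
        res = enrich(["d1", "d2"], store, chain_dag)
        # B and C have identical annotation sets hence identical p-values
        tied = res.table[res.table["pvalue"] == res.table["pvalue"].min()]
        assert list(tied["term_id"]) == sorted(tied["term_id"])
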