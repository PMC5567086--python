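import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rvburden import (
    TermEnrichmentAnalysis,
    bh_adjust,
    cluster_terms,
    kappa_similarity,
    term_stats,
)
from rvburden.enrichment import TermEnrichment
from rvburden.io import GeneSetCollection, InputError


def genes(n, prefix="g"):
    return [f"{prefix}{i:04d}" for i in range(n)]


class TestTermStats:
    def test_proportional_representation_fold_one(self):
        bg = genes(1000)
        term = bg[:100]
        lst = bg[:5] + bg[100:145]  # 5 of 50 in term, term is 100 of 1000
        e = term_stats(lst, term, bg)
        assert e.fold == pytest.approx(1.0)

    def test_single_hit_guard_scores_one(self):
        bg = genes(100)
        e = term_stats(bg[:10], bg[:1] + bg[50:59], bg)
        assert e.k == 1
        assert e.p_ease == 1.0

    def test_fold_and_ease_against_enumeration(self):
        """k=8 hits of a 50-gene list against a 40-gene term in a
        1000-gene background: fold 4.0; EASE p equals the hypergeometric
        tail evaluated at k-1."""
        bg = genes(1000)
        term = bg[:40]
        lst = bg[:8] + bg[500:542]
        e = term_stats(lst, term, bg)
        assert (e.k, e.n, e.K, e.N) == (8, 50, 40, 1000)
        assert e.fold == pytest.approx(4.0)
        oracle = stats.hypergeom.sf(7 - 1, 1000, 40, 50)
        assert e.p_ease == pytest.approx(oracle, rel=1e-12)

    def test_plain_fisher_switch(self):
        bg = genes(200)
        lst, term = bg[:20], bg[:30]
        ease = term_stats(lst, term, bg).p_ease
        fisher = term_stats(lst, term, bg, method="fisher").p_ease
        assert fisher == pytest.approx(stats.hypergeom.sf(19, 200, 30, 20), rel=1e-12)
        assert ease >= fisher  # discounting a hit is conservative

    def test_out_of_background_genes_dropped_from_n(self):
        bg = genes(100)
        lst = bg[:10] + ["NOT_IN_BG"]
        e = term_stats(lst, bg[:20], bg)
        assert e.n == 10

    def test_empty_term_or_list_rejected(self):
        bg = genes(10)
        with pytest.raises(InputError):
            term_stats(bg[:3], ["absent"], bg)
        with pytest.raises(InputError):
            term_stats(["absent"], bg[:3], bg)


class TestBH:
    def test_hand_evaluated_examples(self):
        assert bh_adjust([0.5]) == [0.5]
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(1e-6, 1, size=40)
        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30))
    def test_q_dominates_p_and_is_clamped(self, p):
        q = bh_adjust(p)
        assert all(qi >= pi - 1e-15 for qi, pi in zip(q, p))
        assert max(q) <= 1.0


class TestKappa:
    def test_identical_nonconstant_vectors(self):
        v = [1, 0, 1, 0, 1]
        assert kappa_similarity(v, v) == 1.0

    def test_worked_2x2(self):
        # both=4, only-a=1, only-b=1, neither=4: Po=0.8, Pe=0.5
        a = [1] * 5 + [0] * 5
        b = [1] * 4 + [0, 1] + [0] * 4
        assert kappa_similarity(a, b) == pytest.approx(0.6)

    def test_disjoint_halves(self):
        a = [1] * 5 + [0] * 5
        b = [0] * 5 + [1] * 5
        assert kappa_similarity(a, b) == pytest.approx(-1.0)

    def test_constant_equal_vectors_defined_zero(self):
        assert kappa_similarity([1, 1, 1], [1, 1, 1]) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(2, 40), st.integers(0, 2**32 - 1))
    def test_symmetric_and_order_invariant(self, n, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random(n) < 0.4, rng.random(n) < 0.4
        k1 = kappa_similarity(a, b)
        assert k1 == kappa_similarity(b, a)
        perm = rng.permutation(n)
        assert kappa_similarity(a[perm], b[perm]) == pytest.approx(k1, abs=1e-12)


def make_enrichment(term_id, hit_genes, p):
    return TermEnrichment(
        term_id=term_id,
        term_name=term_id,
        k=len(hit_genes),
        n=10,
        K=len(hit_genes),
        N=100,
        fold=1.0,
        p_ease=p,
        hit_genes=frozenset(hit_genes),
    )


class TestClustering:
    def test_identical_terms_form_one_cluster_with_geomean_score(self):
        universe = genes(10)
        hits = universe[:4]
        terms = [make_enrichment(f"T{i}", hits, 0.1) for i in range(3)]
        clusters = cluster_terms(terms, universe)
        assert len(clusters) == 1
        assert clusters[0].member_terms == ("T0", "T1", "T2")
        assert clusters[0].enrichment_score == pytest.approx(1.0)

    def test_score_is_minus_log10_geometric_mean(self):
        universe = genes(10)
        hits = universe[:4]
        terms = [
            make_enrichment("T0", hits, 1e-2),
            make_enrichment("T1", hits, 1e-4),
            make_enrichment("T2", hits, 1e-3),
        ]
        (c,) = cluster_terms(terms, universe)
        assert c.enrichment_score == pytest.approx(3.0)

    def test_dissimilar_terms_yield_no_clusters(self):
        universe = genes(12)
        terms = [
            make_enrichment("T0", universe[0:4], 0.1),
            make_enrichment("T1", universe[4:8], 0.1),
            make_enrichment("T2", universe[8:12], 0.1),
        ]
        assert cluster_terms(terms, universe) == []

    def test_merge_reaches_fixpoint_and_is_deterministic(self):
        universe = genes(20)
        # two overlapping blocks of similar terms that must merge
        block1, block2 = universe[:8], universe[4:12]
        terms = (
            [make_enrichment(f"A{i}", block1, 0.05) for i in range(3)]
            + [make_enrichment(f"B{i}", block2, 0.05) for i in range(3)]
        )
        first = cluster_terms(terms, universe, kappa_threshold=0.3)
        second = cluster_terms(list(reversed(terms)), universe, kappa_threshold=0.3)
        assert [c.member_terms for c in first] == [c.member_terms for c in second]
        members = {t for c in first for t in c.member_terms}
        assert members == {f"A{i}" for i in range(3)} | {f"B{i}" for i in range(3)}


class TestAnalysisModel:
    def test_fit_sorts_by_p_and_fills_q(self):
        bg = genes(200)
        coll = GeneSetCollection(
            terms={
                "T1": ("enriched", frozenset(bg[:20])),
                "T2": ("flat", frozenset(bg[100:120])),
            },
            background=frozenset(bg),
        )
        res = TermEnrichmentAnalysis(bg[:15] + bg[150:160], coll).fit()
        assert res.terms[0].term_id == "T1"
        assert all(e.q is not None and e.q >= e.p_ease - 1e-15 for e in res.terms)
        assert "T1" in res.summary()

    def test_cluster_uses_listed_genes_universe(self):
        bg = genes(50)
        shared = frozenset(bg[:10])
        coll = GeneSetCollection(
            terms={f"T{i}": ("t", shared) for i in range(3)},
            background=frozenset(bg),
        )
        res = TermEnrichmentAnalysis(bg[:12], coll).fit()
        clusters = res.cluster()
        assert len(clusters) == 1
        assert math.isclose(
            clusters[0].enrichment_score,
            -math.log10(res.terms[0].p_ease),
            rel_tol=1e-12,
        )
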