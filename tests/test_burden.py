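import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rvburden import (
    AnnotatedVariant,
    CohortGenotypes,
    GeneBurden,
    VariantKey,
    collapse_carriers,
    exact_burden_p,
    run_gene_burden,
    summarize_variants,
)
from rvburden.burden import GeneCarrierTable
from rvburden.io import InputError


def cohort_from_matrix(matrix, n_cases):
    matrix = np.asarray(matrix, dtype=np.int8)
    n_samples, n_variants = matrix.shape
    samples = [f"S{i}" for i in range(n_samples)]
    phenotype = {
        s: ("case" if i < n_cases else "control") for i, s in enumerate(samples)
    }
    keys = [VariantKey("chr1", 10 * (j + 1), "G", "A") for j in range(n_variants)]
    return CohortGenotypes(samples, phenotype, keys, matrix), keys


def annotated(key, gene):
    return AnnotatedVariant(key=key, gene=gene, consequence="missense")


class TestExactP:
    def test_worked_example_three_case_carriers(self):
        """3 carriers of 13 cases vs 0 of 100 controls: the tail holds a
        single table, C(13,3)/C(113,3) = 286/234136, printed as 0.001."""
        p = exact_burden_p(3, 10, 0, 100)
        assert p == 286 / 234136
        assert f"{p:.3f}" == "0.001"

    def test_no_carriers_anywhere_gives_one(self):
        assert exact_burden_p(0, 13, 0, 100) == 1.0

    def test_small_table_matches_enumeration(self):
        # (2,3,1,9): margins n1=5, n2=10, k=3
        expected = sum(
            stats.hypergeom.pmf(x, 15, 3, 5) for x in (2, 3)
        )
        assert exact_burden_p(2, 3, 1, 9) == pytest.approx(expected, abs=1e-14)

    def test_agrees_with_scipy_fisher(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b == 0 or c + d == 0:
                continue
            ours = exact_burden_p(int(a), int(b), int(c), int(d))
            ref = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert ours == pytest.approx(ref, rel=1e-12)
            ours2 = exact_burden_p(int(a), int(b), int(c), int(d), "two-sided")
            ref2 = stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours2 == pytest.approx(ref2, rel=1e-9)

    def test_two_sided_equals_one_sided_for_worked_example(self):
        """No opposite-tail table is as extreme, so sidedness does not
        change the headline value."""
        assert exact_burden_p(3, 10, 0, 100) == exact_burden_p(
            3, 10, 0, 100, "two-sided"
        )

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        n1=st.integers(1, 20),
        n2=st.integers(1, 25),
        k=st.integers(0, 30),
    )
    def test_monotone_in_case_carriers(self, n1, n2, k):
        """At fixed margins the tail p is non-increasing in the number of
        case carriers."""
        k = min(k, n1 + n2)
        ps = []
        for a in range(max(0, k - n2), min(n1, k) + 1):
            c = k - a
            ps.append(exact_burden_p(a, n1 - a, c, n2 - c))
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_degenerate_margins_raise(self):
        with pytest.raises(InputError):
            exact_burden_p(0, 0, 1, 9)
        with pytest.raises(InputError):
            exact_burden_p(-1, 5, 0, 5)


class TestCollapse:
    def test_three_distinct_carriers_among_cases(self):
        # 13 cases, 100 controls; variants 0,1,2 carried by cases 0,1,2
        m = np.zeros((113, 3), dtype=np.int8)
        m[0, 0] = m[1, 1] = m[2, 2] = 1
        cohort, keys = cohort_from_matrix(m, 13)
        tables = collapse_carriers([annotated(k, "RYR3") for k in keys], cohort)
        assert tables == [GeneCarrierTable("RYR3", 3, 10, 0, 100)]

    def test_sample_with_two_variants_counted_once(self):
        m = np.zeros((5, 2), dtype=np.int8)
        m[0, 0] = m[0, 1] = 1
        cohort, keys = cohort_from_matrix(m, 2)
        tables = collapse_carriers([annotated(k, "G1") for k in keys], cohort)
        assert tables == [GeneCarrierTable("G1", 1, 1, 0, 3)]

    def test_missing_genotype_counts_as_non_carrier(self):
        m = np.array([[-1], [1], [0]], dtype=np.int8)
        cohort, keys = cohort_from_matrix(m, 2)
        tables = collapse_carriers([annotated(keys[0], "G1")], cohort)
        assert tables == [GeneCarrierTable("G1", 1, 1, 0, 1)]

    def test_allelic_coding_counts_alleles(self):
        m = np.array([[2], [1], [0], [0]], dtype=np.int8)
        cohort, keys = cohort_from_matrix(m, 2)
        (t,) = collapse_carriers([annotated(keys[0], "G1")], cohort, coding="allelic")
        assert (t.a, t.b, t.c, t.d) == (3, 1, 0, 4)

    def test_no_qualifying_variants_empty(self, small_cohort):
        _, (cohort, _, _, _) = small_cohort
        assert collapse_carriers([], cohort) == []

    def test_recounts_generator_truth(self, small_cohort):
        """Collapsing every simulated variant reproduces the generator's
        realized per-gene carrier counts exactly."""
        _, (cohort, ann, _, truth) = small_cohort
        tables = collapse_carriers(list(ann.values()), cohort)
        realized = {t.gene: (t.a, t.c) for t in tables}
        for gene, (a, c) in truth.realized_carriers.items():
            assert realized.get(gene, (0, 0)) == (a, c)


class TestRunBurden:
    def test_single_gene_q_equals_p(self):
        (res,) = run_gene_burden([GeneCarrierTable("RYR3", 3, 10, 0, 100)])
        assert res.p == res.q == pytest.approx(286 / 234136)

    def test_bh_over_two_genes(self):
        # engineered tables with p = 1/3 and ~1: BH doubles the smaller
        t1 = GeneCarrierTable("A", 1, 0, 0, 2)  # p = 1/3
        t2 = GeneCarrierTable("B", 0, 1, 1, 1)  # p = 1
        res = run_gene_burden([t1, t2])
        assert [r.gene for r in res] == ["A", "B"]
        assert res[0].p == pytest.approx(1 / 3)
        assert res[0].q == pytest.approx(2 / 3)
        assert res[1].q == 1.0

    def test_sorted_by_p_then_gene(self):
        tables = [
            GeneCarrierTable(g, 1, 12, 0, 100) for g in ("ZZZ", "AAA", "MMM")
        ]
        res = run_gene_burden(tables)
        assert [r.gene for r in res] == ["AAA", "MMM", "ZZZ"]

    def test_model_results_surface(self):
        model = GeneBurden([GeneCarrierTable("RYR3", 3, 10, 0, 100)])
        res = model.fit()
        df = res.frame
        assert df.loc[0, "GENE"] == "RYR3"
        assert df.loc[0, "P"] == pytest.approx(286 / 234136)
        text = res.summary()
        assert "RYR3" in text and "0.001" in text


class TestSummarize:
    def test_snv_indel_gene_counts(self):
        vs = [
            annotated(VariantKey("1", 1, "G", "A"), "A"),
            annotated(VariantKey("1", 2, "GA", "G"), "B"),
            annotated(VariantKey("1", 3, "C", "T"), "B"),
        ]
        assert summarize_variants(vs) == (2, 1, 2)
        assert summarize_variants(vs[:1]) == (1, 0, 1)
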