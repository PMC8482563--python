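"""Hypergeometric tail, multiple-testing correctors and the ORA model."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pathora as pa
from pathora.enrichment import Column, EnrichmentConfig
from pathora.errors import DomainError, EmptyQueryError

from conftest import hypergeom_tail_by_enumeration


class TestHypergeomPvalue:
    # expected values frozen from the enumeration oracle:
    # C(10,3)=120 draws; 40 contain >=2 of 4 marked; 1 contains all of 3 marked
    @pytest.mark.parametrize("k,m,n,N,expected", [
        (0, 4, 3, 10, 1.0),
        (2, 4, 3, 10, 40 / 120),
        (3, 3, 3, 10, 1 / 120),
        (5, 10, 5, 10, 1.0),   # pathway == universe forces full overlap
    ])
    def test_worked_examples(self, k, m, n, N, expected):
        p = pa.hypergeom_pvalue(k, m, n, N)
        assert p == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(hypergeom_tail_by_enumeration(k, m, n, N),
                                  rel=1e-12)

    @pytest.mark.parametrize("k,m,n,N", [
        (-1, 4, 3, 10), (4, 4, 3, 10),   # k out of [max(0,m+n-N), min(m,n)]
        (0, 11, 3, 10), (0, 3, 11, 10),  # m, n out of [0, N]
        (0, 9, 9, 10),                   # k below forced minimum m+n-N=8
    ])
    def test_bounds_violations_raise_domain_error(self, k, m, n, N):
        with pytest.raises(DomainError):
            pa.hypergeom_pvalue(k, m, n, N)

    def test_tail_non_increasing_in_k(self):
        m, n, N = 20, 15, 60
        values = [pa.hypergeom_pvalue(k, m, n, N) for k in range(0, 16)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_pmf_recovered_from_tail_sums_to_one(self):
        m, n, N = 7, 5, 12
        lo, hi = max(0, m + n - N), min(m, n)
        tail = {k: pa.hypergeom_pvalue(k, m, n, N) for k in range(lo, hi + 1)}
        tail[hi + 1] = 0.0
        total = sum(tail[k] - tail[k + 1] for k in range(lo, hi + 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_extreme_tail_does_not_underflow_to_zero(self):
        # overlaps like Table-2 magnitudes must stay strictly positive
        p = pa.hypergeom_pvalue(150, 200, 180, 5000)
        assert 0.0 < p < 1e-150


class TestBonferroni:
    def test_published_worked_example(self):
        # 291 simultaneous tests recovered from the printed corrected column
        assert f"{pa.bonferroni_adjust(2.95e-36, 291):.2e}" == "8.58e-34"

    @pytest.mark.parametrize("p,n,expected", [
        (0.5, 3, 1.0),      # capped
        (0.01, 1, 0.01),    # single test unchanged
    ])
    def test_cap_and_identity(self, p, n, expected):
        assert pa.bonferroni_adjust(p, n) == expected

    def test_invalid_test_count(self):
        with pytest.raises(DomainError):
            pa.bonferroni_adjust(0.01, 0)


class TestFdr:
    def test_published_rank_one_value(self):
        # smallest of 291 p-values; no later rank can lower rank 1 here
        ps = [4.33e-152] + [0.5] * 290
        assert f"{pa.fdr_adjust(ps)[0]:.2e}" == "1.26e-149"

    def test_single_value_unchanged(self):
        assert pa.fdr_adjust([0.03]) == [0.03]

    def test_hand_computed_equal_q_series(self):
        # q_i = p_i * 4 / i = 0.04 for all i; cumulative min leaves 0.04
        assert pa.fdr_adjust([0.01, 0.02, 0.03, 0.04]) == \
            pytest.approx([0.04] * 4)

    def test_matches_statsmodels_step_up(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        ps = rng.uniform(size=57)
        ours = pa.fdr_adjust(ps.tolist())
        theirs = multipletests(ps, method="fdr_bh")[1]
        assert ours == pytest.approx(theirs.tolist(), rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30),
           st.randoms(use_true_random=False))
    def test_adjusted_value_travels_with_its_pvalue(self, ps, rnd):
        base = list(zip(ps, pa.fdr_adjust(ps)))
        shuffled = ps[:]
        rnd.shuffle(shuffled)
        assert sorted(zip(shuffled, pa.fdr_adjust(shuffled))) == sorted(base)

    @pytest.mark.parametrize("bad", [[], [1.5], [-0.1]])
    def test_invalid_inputs(self, bad):
        with pytest.raises(DomainError):
            pa.fdr_adjust(bad)


class TestEnrich:
    def test_planted_overlap_ranks_first_with_exact_pvalue(self, toy_db):
        res = pa.enrich(["A", "B", "C"], toy_db)
        assert res.universe_size == 10 and res.n == 3 and res.N_tests == 3
        first = res.records[0]
        assert first.pathway_id == "P1"
        assert first.k == 3 and first.m == 4
        # P(X>=3) with m=4,n=3,N=10: 4/120 draws contain 3 of the 4 marked
        assert first.p_raw == pytest.approx(
            hypergeom_tail_by_enumeration(3, 4, 3, 10), rel=1e-12)
        assert {r.pathway_id for r in res.records[1:]} == {"P2", "P3"}
        assert all(r.k == 0 and r.p_raw == 1.0 for r in res.records[1:])

    def test_no_overlap_anywhere_yields_no_significance(self, toy_db):
        # query inside the universe but spread across all pathways
        res = pa.enrich(["A", "E", "H"], toy_db)
        assert all(r.p_raw > 0.005 for r in res.records)
        assert res.significant() == []

    def test_corrected_columns_obey_ordering(self, toy_db):
        res = pa.enrich(["A", "B", "E"], toy_db)
        for r in res.records:
            assert r.p_fdr <= r.p_bonf <= 1.0
            assert r.p_bonf == pytest.approx(
                min(1.0, r.p_raw * res.N_tests))
            assert len(r.overlap_genes) == r.k

    def test_query_genes_outside_universe_dropped_and_counted(self, toy_db):
        res = pa.enrich(["A", "B", "NOTINDB"], toy_db)
        assert res.n == 2 and res.dropped_query_genes == 1

    def test_query_disjoint_from_universe_errors(self, toy_db):
        with pytest.raises(EmptyQueryError, match="disjoint"):
            pa.enrich(["NOPE1", "NOPE2"], toy_db)

    def test_significant_count_monotone_in_alpha(self, toy_db):
        res = pa.enrich(["A", "B", "C"], toy_db)
        counts = [len(res.significant(alpha=a))
                  for a in (1.0, 0.05, 0.005, 1e-6)]
        assert counts == sorted(counts, reverse=True)

    def test_threshold_column_switch(self, toy_db):
        res = pa.enrich(["A", "B", "C"], toy_db,
                        EnrichmentConfig(alpha=0.05, column=Column.BONFERRONI))
        for r in res.significant():
            assert r.p_bonf <= 0.05

    def test_repeat_runs_are_byte_identical(self, toy_db):
        a = pa.enrich(["A", "B", "C"], toy_db).to_tsv()
        b = pa.enrich(["A", "B", "C"], toy_db).to_tsv()
        assert a == b

    def test_tsv_round_trip_preserves_records(self, toy_db):
        res = pa.enrich(["A", "B", "C"], toy_db)
        back = pa.EnrichmentResults.from_tsv(io.StringIO(res.to_tsv()))
        assert [(r.pathway_id, r.m, r.k) for r in back.records] == \
               [(r.pathway_id, r.m, r.k) for r in res.records]
        for ours, theirs in zip(res.records, back.records):
            assert theirs.p_raw == pytest.approx(ours.p_raw, rel=1e-5)
            assert theirs.overlap_genes == ours.overlap_genes

    def test_records_sorted_by_p_then_id(self, toy_db):
        res = pa.enrich(["A", "E", "H"], toy_db)
        keys = [(r.p_raw, r.pathway_id) for r in res.records]
        assert keys == sorted(keys)


class TestConfig:
    @pytest.mark.parametrize("alpha", [0.0, -0.1, 1.5])
    def test_alpha_bounds(self, alpha):
        with pytest.raises(DomainError):
            EnrichmentConfig(alpha=alpha)
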