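import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tadresponse.enrichment import (
    ContingencyTable,
    PermutationResult,
    bh_adjust,
    chisq_with_residuals,
    fisher_2x2,
    mann_whitney_u,
    permutation_gene_tad_enrichment,
    significance_stars,
    timecourse_comparison,
)


def table2x2(a, b, c, d):
    return ContingencyTable(("r1", "r2"), ("c1", "c2"), ((a, b), (c, d)))


class TestFisher:
    def test_no_association(self):
        res = fisher_2x2(table2x2(10, 10, 10, 10))
        assert res["odds_ratio"] == 1.0 and res["p_value"] == pytest.approx(1.0)

    def test_cross_product_odds_ratio(self):
        assert fisher_2x2(table2x2(20, 5, 10, 40))["odds_ratio"] == 16.0

    def test_exact_p_from_enumeration(self):
        # a in {0,1,2} given margins (2,2)/(2,2): P(a=2) = 1/6, two-sided
        # p sums tables as extreme: 2/6 = 1/3
        assert fisher_2x2(table2x2(2, 0, 0, 2))["p_value"] == pytest.approx(1 / 3)

    def test_infinite_odds_ratio_with_haldane_fallback(self):
        res = fisher_2x2(table2x2(5, 0, 3, 7))
        assert res["odds_ratio"] == float("inf")
        assert res["odds_ratio_haldane"] == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    @given(st.tuples(*[st.integers(0, 30)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_transpose_invariance(self, cells):
        a, b, c, d = cells
        p1 = fisher_2x2(table2x2(a, b, c, d))["p_value"]
        p2 = fisher_2x2(table2x2(a, c, b, d))["p_value"]
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestChiSquared:
    def test_no_deviation(self):
        res = chisq_with_residuals(table2x2(10, 20, 10, 20))
        assert res.chi2 == pytest.approx(0.0)
        assert (res.residuals.to_numpy() == 0).all()

    def test_single_cell_residual_magnitude(self):
        # O = 20 against E = 10 gives (20-10)/sqrt(10) = 3.162
        res = chisq_with_residuals(table2x2(20, 10, 10, 20))
        e = res.expected.iloc[0, 0]
        assert e == pytest.approx(15.0)
        res2 = chisq_with_residuals(
            ContingencyTable(("r1", "r2"), ("c1", "c2"), ((20, 0), (0, 20)))
        )
        assert res2.residuals.iloc[0, 0] == pytest.approx(10 / np.sqrt(10))

    def test_symmetric_association(self):
        res = chisq_with_residuals(table2x2(30, 10, 10, 30))
        assert res.chi2 == pytest.approx(20.0)  # 4 cells x (10^2 / 20)
        assert res.df == 1
        flags = res.flags()
        assert flags.iloc[0, 0] == "enriched" and flags.iloc[0, 1] == "depleted"

    def test_identity_chi2_equals_sum_of_squared_residuals(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            counts = rng.integers(1, 80, size=(3, 4))
            tab = ContingencyTable(
                ("a", "b", "c"), ("w", "x", "y", "z"),
                tuple(tuple(int(v) for v in row) for row in counts),
            )
            res = chisq_with_residuals(tab)
            assert res.chi2 == pytest.approx(
                float((res.residuals.to_numpy() ** 2).sum()), abs=1e-9
            )

    def test_zero_margin_error(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_with_residuals(table2x2(0, 0, 5, 5))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            table2x2(-1, 2, 3, 4)


class TestPermutation:
    def _setup(self, n_tads=20, genes_per_tad=5, responsive_frac=0.5):
        gene_tad = {
            f"g{i}": f"t{i // genes_per_tad}" for i in range(n_tads * genes_per_tad)
        }
        responsive = {f"t{i}" for i in range(int(n_tads * responsive_frac))}
        return gene_tad, responsive

    def test_floor_when_observed_is_maximal(self):
        gene_tad, responsive = self._setup()
        query = [g for g, t in gene_tad.items() if t in responsive][:30]
        res = permutation_gene_tad_enrichment(
            query, gene_tad.keys(), gene_tad, responsive, n_perm=999, seed=0
        )
        assert res.observed == 30
        assert res.p_value >= 1 / 1000  # never below the estimator floor

    def test_all_tads_responsive_gives_p_one(self):
        gene_tad, _ = self._setup()
        res = permutation_gene_tad_enrichment(
            list(gene_tad)[:10], gene_tad.keys(), gene_tad,
            set(gene_tad.values()), n_perm=999, seed=0,
        )
        assert res.observed == 10 and res.p_value == 1.0

    def test_seed_determinism_and_result_invariants(self):
        gene_tad, responsive = self._setup()
        query = list(gene_tad)[:25]
        a = permutation_gene_tad_enrichment(query, gene_tad.keys(), gene_tad, responsive, 999, seed=5)
        b = permutation_gene_tad_enrichment(query, gene_tad.keys(), gene_tad, responsive, 999, seed=5)
        assert a == b
        assert a.p_value == (a.exceedances + 1) / (a.n_perm + 1)

    def test_tad_shuffle_variant(self):
        gene_tad, responsive = self._setup()
        query = [g for g, t in gene_tad.items() if t in responsive][:40]
        res = permutation_gene_tad_enrichment(
            query, gene_tad.keys(), gene_tad, responsive, n_perm=999, seed=1,
            shuffle="tads",
        )
        assert res.observed == 40
        assert res.p_value <= 0.05  # all query genes responsive: strong signal

    def test_errors(self):
        gene_tad, responsive = self._setup()
        with pytest.raises(ValueError, match="empty query"):
            permutation_gene_tad_enrichment([], gene_tad.keys(), gene_tad, responsive)
        with pytest.raises(ValueError, match="outside the universe"):
            permutation_gene_tad_enrichment(
                ["nope"], gene_tad.keys(), gene_tad, responsive
            )
        with pytest.raises(ValueError):
            PermutationResult(5, 999, 3, 0.9, 0)  # inconsistent p


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_groups(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=20), rng.normal(1, 1, size=15)
        assert mann_whitney_u(x, y)[1] == pytest.approx(mann_whitney_u(y, x)[1])

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestBH:
    def test_min_over_tail(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_and_saturated(self):
        assert bh_adjust([0.3]) == [pytest.approx(0.3)]
        assert bh_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_alignment_to_input_order(self):
        adjusted = bh_adjust([0.04, 0.001, 0.5])
        assert adjusted[1] < adjusted[0] < adjusted[2]

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_adjusted_at_least_raw_and_capped(self, ps):
        adjusted = bh_adjust(ps)
        assert all(a >= p - 1e-12 for a, p in zip(adjusted, ps))
        assert all(a <= 1.0 for a in adjusted)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])


def test_significance_stars_encoding():
    assert [significance_stars(p) for p in (0.5, 0.04, 0.009, 0.0009)] == [
        "ns", "*", "**", "***",
    ]


class TestTimecourse:
    TPS = (0.5, 1, 2, 3, 4, 5, 6)

    def _traj(self, genes, offset=0.0, rng=None):
        data = {}
        for i in range(genes):
            noise = rng.normal(0, 0.1, len(self.TPS)) if rng is not None else 0.0
            data[f"g{i}_{offset}"] = dict(zip(self.TPS, np.full(len(self.TPS), offset) + noise))
        return data

    def test_identical_groups_all_ns(self):
        rng = np.random.default_rng(0)
        a = self._traj(20, 0.0, rng)
        out = timecourse_comparison(a, a, self.TPS)
        assert (out["p_adjusted"] == 1.0).all()
        assert (out["stars"] == "ns").all()

    def test_large_shift_fully_significant(self):
        rng = np.random.default_rng(1)
        out = timecourse_comparison(
            self._traj(50, 10.0, rng), self._traj(50, 0.0, rng), self.TPS
        )
        assert (out["p_adjusted"] < 0.001).all()
        assert (out["stars"] == "***").all()

    def test_bh_leaves_equal_pvalues_equal(self):
        ps = [0.2] * 7
        assert bh_adjust(ps) == pytest.approx([0.2] * 7)

    def test_missing_timepoint_error(self):
        a = self._traj(5, 1.0)
        b = {g: {0.5: 1.0} for g in "xyz"}
        with pytest.raises(ValueError):
            timecourse_comparison(a, b, self.TPS)
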