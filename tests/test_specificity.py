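import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from sescreen import (
    ExpressionMatrix,
    expression_variance,
    psi,
    screen,
    simulate_cohort,
    specificity,
    specificity_index,
    specificity_index_matrix,
    tsi,
)


def naive_si(values, labels, pseudocount=1.0):
    """Loop-based SI reference: mean descending rank of pairwise ratios."""
    tissues = list(dict.fromkeys(labels))
    means = np.column_stack(
        [
            values[:, [i for i, l in enumerate(labels) if l == t]].mean(axis=1)
            for t in tissues
        ]
    )
    n_genes = values.shape[0]
    si = np.zeros((n_genes, len(tissues)))
    for ti, t in enumerate(tissues):
        rank_sum = np.zeros(n_genes)
        for ui in range(len(tissues)):
            if ui == ti:
                continue
            ratios = (means[:, ti] + pseudocount) / (means[:, ui] + pseudocount)
            rank_sum += rankdata(-ratios, method="average")
        si[:, ti] = rank_sum / (len(tissues) - 1)
    return si, tissues


class TestSpecificityIndex:
    def test_exclusively_expressed_gene_has_si_one(self):
        values = pd.DataFrame(
            {
                "a": [100.0, 5, 5, 5],
                "b": [0.0, 5, 5, 5],
                "c": [0.0, 5, 5, 5],
            },
            index=["hit", "f1", "f2", "f3"],
        )
        expr = ExpressionMatrix(values, pd.Series({"a": "A", "b": "B", "c": "C"}))
        assert specificity_index(expr, "A")["hit"] == 1.0

    def test_three_by_three_toy_matches_hand_ranking(self, toy_expr):
        # t1-vs-t2 ratios (11/2, 6/6, 2/11) -> ranks (1, 2, 3); t1-vs-t3
        # ratios (11/2, 6/6, 2/2) -> ranks (1, 2.5, 2.5) with an average tie
        si = specificity_index(toy_expr, "t1")
        assert si["g1"] == 1.0
        assert si["g2"] == pytest.approx((2 + 2.5) / 2)
        assert si["g3"] == pytest.approx((3 + 2.5) / 2)

    def test_matches_naive_reference_on_random_matrices(self):
        rng = np.random.default_rng(11)
        values = rng.lognormal(3, 1, size=(40, 12))
        labels = [f"t{i % 4}" for i in range(12)]
        expr = ExpressionMatrix(
            pd.DataFrame(values, columns=[f"s{i}" for i in range(12)]),
            pd.Series(labels, index=[f"s{i}" for i in range(12)]),
        )
        expected, tissues = naive_si(values, labels)
        got = specificity_index_matrix(expr)
        np.testing.assert_allclose(got.values, expected)
        assert list(got.columns) == tissues

    def test_constant_matrix_gives_mid_rank_everywhere(self):
        g = 7
        values = pd.DataFrame(np.full((g, 3), 4.0), columns=list("abc"))
        expr = ExpressionMatrix(values, pd.Series({"a": "A", "b": "B", "c": "C"}))
        si = specificity_index_matrix(expr)
        np.testing.assert_allclose(si.values, (g + 1) / 2)

    def test_gene_order_invariance(self, toy_expr):
        shuffled = ExpressionMatrix(
            toy_expr.values.iloc[::-1], toy_expr.groups
        )
        a = specificity_index_matrix(toy_expr)
        b = specificity_index_matrix(shuffled)
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_scale_invariance_without_pseudocount(self, toy_expr):
        # ratio ranks are scale-free when the pseudocount does not interfere
        scaled = ExpressionMatrix(toy_expr.values * 37.0, toy_expr.groups)
        a = specificity_index_matrix(toy_expr, pseudocount=0.0)
        b = specificity_index_matrix(scaled, pseudocount=0.0)
        pd.testing.assert_frame_equal(a, b)

    def test_single_group_is_an_error(self):
        values = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["g"])
        expr = ExpressionMatrix(values, pd.Series({"a": "A", "b": "A"}))
        with pytest.raises(ValueError, match="2 groups"):
            specificity_index_matrix(expr)


def exhaustive_psi(values, labels, pseudocount=1.0):
    """Enumeration reference: every distinct label permutation, pooled null."""
    si_obs, tissues = naive_si(values, labels, pseudocount)
    perms = sorted(set(itertools.permutations(labels)))
    null = []
    for p in perms:
        si_p, order = naive_si(values, list(p), pseudocount)
        # align permuted columns to the observed tissue order before pooling
        null.append(si_p[:, [order.index(t) for t in tissues]])
    null = np.concatenate(null, axis=0)
    out = np.zeros_like(si_obs)
    for t in range(len(tissues)):
        for g in range(values.shape[0]):
            leq = int((null[:, t] <= si_obs[g, t]).sum())
            out[g, t] = (1 + leq) / (1 + null.shape[0])
    return out


class TestPsi:
    def make_expr(self, seed=0, n_genes=6):
        rng = np.random.default_rng(seed)
        values = rng.lognormal(3, 1, size=(n_genes, 3))
        values[0, 0] *= 20  # one clearly specific gene
        samples = ["s1", "s2", "s3"]
        return (
            ExpressionMatrix(
                pd.DataFrame(values, columns=samples),
                pd.Series(["t1", "t2", "t3"], index=samples),
            ),
            values,
        )

    def test_equals_exhaustive_enumeration_exactly(self):
        expr, values = self.make_expr()
        got = psi(expr, n_perm=100, seed=0)  # 3! = 6 <= 100 -> exhaustive
        expected = exhaustive_psi(values, ["t1", "t2", "t3"])
        np.testing.assert_array_equal(got.values, expected)

    def test_constant_matrix_gives_uniform_high_psi(self):
        values = pd.DataFrame(np.full((5, 3), 2.0), columns=list("abc"))
        expr = ExpressionMatrix(values, pd.Series({"a": "A", "b": "B", "c": "C"}))
        res = psi(expr, n_perm=10, seed=0)
        assert (res.values >= 0.5).all()
        assert np.unique(res.values).size == 1

    def test_same_seed_reproduces_sampled_null(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(
            rng.lognormal(3, 1, size=(20, 12)),
            columns=[f"s{i}" for i in range(12)],
        )
        groups = pd.Series(
            [f"t{i % 3}" for i in range(12)], index=values.columns
        )
        expr = ExpressionMatrix(values, groups)
        a = psi(expr, n_perm=25, seed=7)  # 12!/(4!^3) >> 25 -> sampled
        b = psi(expr, n_perm=25, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_psi_lies_in_unit_interval(self):
        expr, _ = self.make_expr(seed=3)
        res = psi(expr, n_perm=50, seed=0)
        assert (res.values > 0).all() and (res.values <= 1).all()

    def test_nonpositive_n_perm_is_an_error(self):
        expr, _ = self.make_expr()
        with pytest.raises(ValueError, match="n_perm"):
            specificity(expr, n_perm=0)


class TestTsi:
    def test_analytic_values(self):
        assert tsi(np.array([0.01, 0.005, 0.0001])) == pytest.approx(2.0)
        assert tsi(np.array([1.0, 1.0, 1.0])) == 0.0
        assert tsi(np.array([0.02, 0.5, 0.9])) == pytest.approx(-math.log10(0.9))

    def test_out_of_range_psi_is_an_error(self):
        with pytest.raises(ValueError):
            tsi(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            tsi(np.array([0.5, 1.5]))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        row=st.lists(
            st.floats(1e-12, 1.0, exclude_min=False), min_size=2, max_size=8
        ),
        idx=st.integers(0, 7),
        bump=st.floats(1e-6, 0.5),
    )
    def test_monotone_nonincreasing_in_every_entry(self, row, idx, bump):
        row = np.asarray(row)
        idx = idx % len(row)
        bumped = row.copy()
        bumped[idx] = min(1.0, bumped[idx] + bump)
        assert tsi(bumped) <= tsi(row) + 1e-12

    def test_masked_variant_ignores_nonspecific_tissues(self):
        frame = pd.DataFrame(
            {"t1": [1e-4, 0.5], "t2": [0.6, 0.7], "t3": [0.9, 0.8]},
            index=["specific", "flat"],
        )
        masked = tsi(frame, max_psi=0.01)
        assert masked["specific"] == pytest.approx(4.0)
        assert masked["flat"] == 0.0

    def test_dataframe_input_returns_series_per_gene(self):
        frame = pd.DataFrame({"t1": [0.01, 1.0], "t2": [0.001, 1.0]})
        out = tsi(frame)
        np.testing.assert_allclose(out.values, [2.0, 0.0])


class TestSpecificityRanking:
    def test_ties_break_by_best_si_then_gene_id(self):
        from sescreen import specificity_ranking

        tsi_values = pd.Series({"a": 2.0, "b": 3.0, "c": 3.0, "d": 3.0})
        si = pd.DataFrame(
            {"t1": [5.0, 1.0, 2.0, 9.0], "t2": [4.0, 8.0, 1.5, 1.5]},
            index=["a", "b", "c", "d"],
        )
        order = list(specificity_ranking(tsi_values, si))
        # b (SI 1.0) before c and d (SI 1.5, tie broken by id); a last (lower TSI)
        assert order == ["b", "c", "d", "a"]

    def test_mismatched_index_is_an_error(self):
        from sescreen import specificity_ranking

        tsi_values = pd.Series({"a": 1.0})
        si = pd.DataFrame({"t1": [1.0]}, index=["b"])
        with pytest.raises(ValueError):
            specificity_ranking(tsi_values, si)


class TestExpressionVariance:
    def test_constant_gene_has_zero_variance(self):
        values = pd.DataFrame([[7.0, 7.0, 7.0]], index=["g"], columns=list("abc"))
        assert expression_variance(ExpressionMatrix(values))["g"] == 0.0

    def test_hand_computed_log_scale_variance(self):
        # log2(x + 1) values {0, 0, 4, 4} -> sample variance 16/3
        values = pd.DataFrame([[0.0, 0.0, 15.0, 15.0]], index=["g"])
        got = expression_variance(ExpressionMatrix(values))["g"]
        assert got == pytest.approx(16 / 3)

    def test_single_sample_is_an_error(self):
        values = pd.DataFrame([[1.0]], index=["g"])
        with pytest.raises(ValueError, match="2 samples"):
            expression_variance(ExpressionMatrix(values))

    def test_bimodal_genes_exceed_housekeeping_variance(self):
        wins = 0
        for seed in range(50):
            cohort, manifest = simulate_cohort(
                n_genes=50, n_samples=30, n_bimodal=3, seed=seed
            )
            var = expression_variance(cohort)
            planted = [m["gene"] for m in manifest]
            if var[planted].min() > var.drop(planted).max():
                wins += 1
        assert wins >= 48


class TestScreen:
    def make_axes(self, seed=0, n=50):
        rng = np.random.default_rng(seed)
        idx = [f"g{i}" for i in range(n)]
        return (
            pd.Series(rng.random(n) * 4, index=idx),
            pd.Series(rng.random(n) * 2, index=idx),
        )

    def test_infinite_thresholds_select_nothing(self):
        t, v = self.make_axes()
        assert screen(t, v, tsi_min=np.inf, var_min=np.inf).candidates == []

    def test_zero_thresholds_select_everything(self):
        t, v = self.make_axes()
        assert len(screen(t, v, tsi_min=0.0, var_min=0.0).candidates) == len(t)

    def test_candidates_equal_brute_force_filter(self):
        t, v = self.make_axes(seed=3)
        res = screen(t, v, tsi_min=2.0, var_min=1.0)
        expected = {g for g in t.index if t[g] >= 2.0 and v[g] >= 1.0}
        assert set(res.candidates) == expected
        # sorted by descending tsi then variance
        keys = [(t[g], v[g]) for g in res.candidates]
        assert keys == sorted(keys, reverse=True)

    def test_percentile_defaults_pass_ten_percent_per_axis(self):
        t, v = self.make_axes(seed=4, n=200)
        res = screen(t, v)
        assert (t >= res.tsi_min).sum() == 20
        assert (v >= res.var_min).sum() == 20

    def test_mismatched_gene_sets_are_an_error(self):
        t, v = self.make_axes()
        with pytest.raises(ValueError, match="same genes"):
            screen(t, v.iloc[:-1])

    def test_planted_margin_thresholds_recover_planted_set(self):
        """End-to-end screen on synthetic data: thresholds at the planted
        margins return exactly the planted specific-and-variable genes."""
        from sescreen import simulate_tissue_expression

        expr, man = simulate_tissue_expression(n_genes=120, n_specific=4, seed=5)
        planted = sorted(m["gene"] for m in man)
        res = specificity(expr, n_perm=60, seed=5)
        tsi_values = tsi(res.psi, max_psi=0.01)
        cohort, _ = simulate_cohort(
            n_genes=120, n_bimodal=4, seed=6,
            gene_names=list(expr.genes), bimodal_genes=planted,
        )
        variance = expression_variance(cohort)
        out = screen(
            tsi_values,
            variance,
            tsi_min=float(tsi_values[planted].min()),
            var_min=float(variance[planted].min()),
        )
        assert sorted(out.candidates) == planted
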