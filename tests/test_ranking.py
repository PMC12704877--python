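"""Ranking-stage correctness: TOPSIS against a brute-force transcription
of its defining equations, tie conventions, the mRMR metric-selection
adaptation, McNemar's test against binomial enumeration, and Holm
step-down properties."""

import numpy as np
import pytest
from scipy.stats import binom

from ecgrank import (holm_adjust, mcnemar_pair, mrmr_rank,
                     mrmr_select_metrics, pairwise_comparison_suite,
                     rank_metric_table, topsis_closeness, topsis_rank)
from ecgrank.classifiers import PredictionSet
from ecgrank.evaluation import MetricRow, MetricTable


def brute_force_closeness(x):
    """Direct loop transcription of the closeness definition: vector
    normalization, ideal/worst solutions, Euclidean distances, then
    C = D-/(D+ + D-)."""
    m, n = x.shape
    r = np.zeros((m, n))
    for j in range(n):
        norm = np.sqrt(sum(x[i, j] ** 2 for i in range(m)))
        for i in range(m):
            r[i, j] = x[i, j] / norm if norm > 0 else 0.0
    a_plus = [max(r[i, j] for i in range(m)) for j in range(n)]
    a_minus = [min(r[i, j] for i in range(m)) for j in range(n)]
    c = np.zeros(m)
    for i in range(m):
        dp = np.sqrt(sum((r[i, j] - a_plus[j]) ** 2 for j in range(n)))
        dm = np.sqrt(sum((r[i, j] - a_minus[j]) ** 2 for j in range(n)))
        c[i] = dm / (dp + dm) if dp + dm > 0 else 0.5
    return c


def table_from(x, ids=None):
    ids = ids or [f"M{i}" for i in range(len(x))]
    return MetricTable([MetricRow(mid, *row) for mid, row in zip(ids, x)])


class TestTopsisCloseness:
    def test_matches_brute_force_on_many_random_matrices(self):
        rng = np.random.default_rng(99)
        for _ in range(250):
            m = int(rng.integers(1, 7))
            x = rng.uniform(0, 100, size=(m, 3))
            state = topsis_closeness(x)
            np.testing.assert_allclose(state.c, brute_force_closeness(x),
                                       atol=1e-12)

    def test_normalized_columns_have_unit_norm(self):
        x = np.random.default_rng(1).uniform(1, 100, size=(5, 3))
        state = topsis_closeness(x)
        np.testing.assert_allclose(np.linalg.norm(state.r, axis=0), 1.0)

    def test_ideal_row_has_closeness_one(self):
        x = np.array([[90.0, 95.0, 92.0],
                      [99.0, 99.0, 99.0],   # unique column-wise maximum
                      [80.0, 85.0, 82.0]])
        state = topsis_closeness(x)
        assert state.d_plus[1] == 0.0
        assert state.c[1] == 1.0
        assert state.c[1] == state.c.max()

    def test_identical_rows_identical_closeness(self):
        x = np.array([[90.0, 95.0, 92.0]] * 2 + [[70.0, 75.0, 72.0]])
        state = topsis_closeness(x)
        assert state.c[0] == state.c[1]

    def test_single_alternative_defined_as_half(self):
        state = topsis_closeness(np.array([[50.0, 60.0, 70.0]]))
        assert state.c[0] == 0.5

    def test_dominance(self):
        """Elementwise dominance implies strictly larger closeness and
        rank 1 for a fully dominant row (random matrices)."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            m = int(rng.integers(2, 7))
            x = rng.uniform(10, 90, size=(m, 3))
            x[0] = x.max(axis=0) + rng.uniform(0.5, 5, size=3)
            state = topsis_closeness(x)
            assert np.all(state.c[0] > state.c[1:])
            assert topsis_rank(x)["row0"] == 1

    def test_scale_invariance_of_one_criterion(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            x = rng.uniform(1, 100, size=(int(rng.integers(2, 7)), 3))
            scaled = x.copy()
            scaled[:, 1] *= 7.5
            np.testing.assert_allclose(topsis_closeness(x).c,
                                       topsis_closeness(scaled).c,
                                       atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 100, size=(6, 3))
        perm = rng.permutation(6)
        c = topsis_closeness(x).c
        np.testing.assert_allclose(topsis_closeness(x[perm]).c, c[perm],
                                   atol=1e-14)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            topsis_closeness(np.array([[1.0, -2.0, 3.0]]))

    def test_zero_column_warns(self):
        with pytest.warns(UserWarning):
            topsis_closeness(np.array([[1.0, 0.0], [2.0, 0.0]]))

    def test_explicit_weights_change_ordering(self):
        x = np.array([[100.0, 0.0], [0.0, 100.0]])
        heavy_first = topsis_closeness(x, weights=[0.9, 0.1])
        assert heavy_first.c[0] > heavy_first.c[1]


class TestTieConventions:
    def test_max_ties_for_topsis(self):
        x = np.array([[99.0, 99.0, 99.0]] * 2 + [[80.0, 85.0, 82.0]])
        rv = topsis_rank(x)
        assert rv["row0"] == rv["row1"] == 2.0
        assert rv["row2"] == 3.0

    def test_all_identical_rows_all_rank_m(self):
        x = np.array([[90.0, 95.0, 92.0]] * 4)
        rv = topsis_rank(x)
        assert all(r == 4.0 for r in rv.ranks.values())
        mv_c = topsis_closeness(x).c
        assert np.all(mv_c == 0.5)

    def test_average_ties_for_mrmr(self):
        rows = [[99.0, 99.0, 99.0], [95.0, 96.0, 95.0],
                [95.0, 96.0, 95.0], [80.0, 85.0, 82.0]]
        rv = mrmr_rank(table_from(np.array(rows)))
        assert rv["M1"] == rv["M2"] == 2.5
        assert rv["M0"] == 1.0 and rv["M3"] == 4.0

    def test_duplicate_rows_tie_under_every_metric_subset(self):
        """Identical metric rows stay tied for every non-empty subset of
        the three criteria (so the mRMR rank of a tied pair is invariant
        to whatever subset selection returns)."""
        from itertools import combinations
        from ecgrank.ranking import _tied_ranks
        x = np.array([[99.0, 98.0, 99.1], [95.0, 96.0, 95.0],
                      [95.0, 96.0, 95.0], [80.0, 85.0, 82.0]])
        names = ["Auc", "f1-score", "Accuracy"]
        t = table_from(x)
        for k in (1, 2, 3):
            for subset in combinations(names, k):
                state = topsis_closeness(t, columns=list(subset))
                ranks = _tied_ranks(state.c, "average")
                assert ranks[1] == ranks[2]

    def test_distinct_rows_integer_ranks(self):
        x = np.array([[99.0, 98.0, 97.0], [90.0, 91.0, 92.0],
                      [80.0, 81.0, 82.0]])
        rv = mrmr_rank(table_from(x))
        assert sorted(rv.ranks.values()) == [1.0, 2.0, 3.0]


class TestMrmrSelection:
    def test_duplicate_metric_keeps_at_most_one(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(60, 99, size=6)
        x = np.column_stack([a, a, rng.uniform(60, 99, size=6)])
        sel = mrmr_select_metrics(table_from(x))
        assert len([m for m in sel.selected_metrics
                    if m in ("Auc", "f1-score")]) <= 1

    def test_uncorrelated_equal_relevance_all_selected(self):
        # three mutually orthogonal (zero sample correlation) columns
        base = np.array([
            [1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
            [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]])
        x = 50.0 + 10.0 * base
        sel = mrmr_select_metrics(table_from(x))
        assert set(sel.selected_metrics) == {"Auc", "f1-score", "Accuracy"}
        for red in sel.redundancy.values():
            assert red == pytest.approx(0.0, abs=1e-12)

    def test_deterministic(self):
        x = np.random.default_rng(5).uniform(60, 99, size=(8, 3))
        t = table_from(x)
        s1, s2 = mrmr_select_metrics(t), mrmr_select_metrics(t)
        assert s1.selected_metrics == s2.selected_metrics

    def test_constant_column_warns(self):
        x = np.column_stack([np.full(4, 50.0),
                             [60, 70, 80, 90], [61, 72, 79, 93.0]])
        with pytest.warns(UserWarning, match="constant"):
            mrmr_select_metrics(table_from(x))

    def test_needs_three_models(self):
        with pytest.raises(ValueError):
            mrmr_select_metrics(table_from(np.array([[1.0, 2, 3],
                                                     [4, 5, 6.0]])))


class TestMcnemar:
    def test_identical_predictions_p_one(self):
        y = np.array([0, 1, 1, 0, 1])
        p = np.array([0, 1, 0, 0, 1])
        res = mcnemar_pair(p, p, y)
        assert (res.b, res.c, res.p_raw) == (0, 0, 1.0)

    def test_symmetric_center_p_one(self):
        # b = c = 5: A right where B wrong on 5 rows and vice versa
        y = np.zeros(10, int)
        a = np.r_[np.zeros(5, int), np.ones(5, int)]
        b = np.r_[np.ones(5, int), np.zeros(5, int)]
        res = mcnemar_pair(a, b, y)
        assert (res.b, res.c) == (5, 5)
        assert res.p_raw == pytest.approx(1.0)

    def test_b8_c1_matches_binomial_enumeration(self):
        y = np.zeros(9, int)
        a = np.r_[np.zeros(8, int), [1]]
        b = np.r_[np.ones(8, int), [0]]
        res = mcnemar_pair(a, b, y)
        assert (res.b, res.c) == (8, 1)
        expected = sum(binom.pmf(k, 9, 0.5) for k in (0, 1, 8, 9))
        assert res.p_raw == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("b,c", [(0, 3), (2, 5), (1, 11), (6, 6),
                                     (0, 12), (4, 7)])
    def test_exact_branch_against_tail_enumeration(self, b, c):
        """For b + c <= 12 the p-value equals the two-sided min-tail
        doubling of Binomial(b+c, 1/2), capped at 1."""
        n = b + c
        y = np.zeros(n, int)
        a = np.r_[np.zeros(b, int), np.ones(c, int)]
        bb = np.r_[np.ones(b, int), np.zeros(c, int)]
        res = mcnemar_pair(a, bb, y)
        pmf = binom.pmf(np.arange(n + 1), n, 0.5)
        obs = pmf[b]
        expected = min(1.0, float(pmf[pmf <= obs + 1e-12].sum()))
        assert res.p_raw == pytest.approx(expected, abs=1e-10)
        swapped = mcnemar_pair(bb, a, y)
        assert swapped.p_raw == pytest.approx(res.p_raw, abs=1e-14)
        assert (swapped.b, swapped.c) == (res.c, res.b)

    def test_large_discordance_chi_square_branch(self):
        from scipy.stats import chi2
        y = np.zeros(100, int)
        a = np.r_[np.zeros(70, int), np.ones(30, int)]
        b = np.r_[np.ones(70, int), np.zeros(30, int)]
        res = mcnemar_pair(a, b, y)
        assert (res.b, res.c) == (70, 30)
        stat = (abs(70 - 30) - 1) ** 2 / 100
        assert res.p_raw == pytest.approx(float(chi2.sf(stat, 1)))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mcnemar_pair([0, 1], [0], [0, 1])


class TestHolm:
    def test_single_p_identity(self):
        np.testing.assert_allclose(holm_adjust([0.037]), [0.037])

    def test_hand_worked_step_down(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(holm_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_properties_on_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 10)))
            adj = holm_adjust(p)
            assert np.all(adj >= p - 1e-15)
            assert np.all(adj <= 1.0)
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-15)
            # never exceeds plain Bonferroni
            assert np.all(adj <= np.minimum(1.0, p * p.size) + 1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(2)
        p = rng.uniform(size=8)
        _, adj, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(holm_adjust(p), adj, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])


class TestPairwiseSuite:
    def make_preds(self, rng, n=60, k=4):
        truth = rng.integers(0, 2, n)
        sets = []
        for i in range(k):
            labels = truth.copy()
            flip = rng.random(n) < 0.1 * (i + 1)
            labels[flip] = 1 - labels[flip]
            sets.append(PredictionSet(f"M{i}", labels,
                                      rng.normal(size=n)))
        return sets, truth

    def test_four_distinct_models_six_pairs(self, rng):
        sets, truth = self.make_preds(rng)
        results, sig, groups = pairwise_comparison_suite(sets, truth)
        assert len(results) == 6
        assert all(r.p_holm >= r.p_raw - 1e-15 for r in results)
        assert all(r.significant == (r.p_holm < 0.05) for r in results)

    def test_identical_models_collapse(self, rng):
        sets, truth = self.make_preds(rng, k=2)
        clone = PredictionSet("M0clone", sets[0].labels.copy(),
                              sets[0].scores.copy())
        results, sig, groups = pairwise_comparison_suite(
            [sets[0], clone], truth)
        assert results == []
        assert groups == [["M0", "M0clone"]]

    def test_significance_matrix_symmetric_empty_diagonal(self, rng):
        sets, truth = self.make_preds(rng)
        _, sig, _ = pairwise_comparison_suite(sets, truth)
        assert (sig.values == sig.values.T).all()
        assert all(sig.iloc[i, i] == "" for i in range(len(sig)))

    def test_alpha_one_all_significant_unless_p_is_one(self, rng):
        sets, truth = self.make_preds(rng)
        results, _, _ = pairwise_comparison_suite(sets, truth, alpha=1.0)
        for r in results:
            assert r.significant == (r.p_holm < 1.0)


class TestRankTable:
    def test_frame_layout_and_best_row(self):
        x = np.array([[97.0, 99.0, 98.0], [90.0, 95.0, 92.0],
                      [80.0, 85.0, 82.0], [70.0, 75.0, 72.0]])
        frame = rank_metric_table(table_from(x))
        assert list(frame.columns) == ["Method", "Auc", "f1-score",
                                       "Accuracy", "Rank_mRMR",
                                       "Rank_TOPSIS", "Closeness"]
        assert frame.loc[0, "Rank_TOPSIS"] == 1.0
        assert frame.loc[0, "Closeness"] == 1.0

    def test_single_row_table_rank_one(self):
        frame = rank_metric_table(table_from(np.array([[9.0, 9.0, 9.0]])))
        assert frame.loc[0, "Rank_TOPSIS"] == 1.0
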