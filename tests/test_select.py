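"""Chi-square scoring and minimal subset search."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.feature_selection import chi2 as sklearn_chi2

from mzwin import (Cohort, build_grid, chi2_contingency, chi2_frequency,
                   construct_features, default_config, generate_cohort,
                   make_splits, minimal_subset_search, presence_counts,
                   rank_features, truth_table)
from mzwin.construct import FeatureMatrix, WindowGrid
from mzwin.models import SplitSpec
from mzwin.select import ContingencyCounts

from conftest import make_sample


def matrix_from(values, step=1.0):
    """Wrap a dense array as a FeatureMatrix (missing = zero cells)."""
    values = np.asarray(values, dtype=float)
    grid = WindowGrid(0.0, values.shape[1] * step, step, values.shape[1])
    return FeatureMatrix(peak_type="height", values=values,
                         missing_mask=values == 0, grid=grid,
                         sample_ids=[f"s{i}" for i in range(values.shape[0])])


class TestChi2Contingency:
    def test_independence_is_zero(self):
        assert chi2_contingency(ContingencyCounts(5, 5, 5, 5)) == 0.0

    def test_perfect_association(self):
        # (10*10 - 0)^2 / (10 * 10 * 10 * 10)
        assert chi2_contingency(ContingencyCounts(10, 0, 0, 10)) == 1.0

    def test_zero_marginal_returns_zero(self):
        assert chi2_contingency(ContingencyCounts(3, 2, 0, 0)) == 0.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyCounts(-1, 0, 0, 0)

    def test_times_n_equals_pearson_on_random_tables(self):
        """The printed form times N is the classical Pearson statistic."""
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 1000:
            a, b, c, d = rng.integers(0, 40, size=4)
            if min(a + c, b + d, a + b, c + d) == 0:
                continue
            ours = chi2_contingency(ContingencyCounts(a, b, c, d)) * (a + b + c + d)
            pearson = scipy.stats.chi2_contingency(
                [[a, b], [c, d]], correction=False)[0]
            assert ours == pytest.approx(pearson, abs=1e-10)
            checked += 1

    def test_classical_flag(self):
        counts = ContingencyCounts(8, 3, 2, 9)
        assert chi2_contingency(counts, classical=True) == pytest.approx(
            chi2_contingency(counts) * 22)


class TestPresenceCounts:
    def test_count_by_case(self):
        c = presence_counts([1.2, 0, 3.4, 0], [1, 1, 0, 0])
        assert (c.a, c.c, c.b, c.d) == (1, 1, 1, 1)

    def test_all_present(self):
        c = presence_counts([1, 2, 3, 4], [1, 1, 0, 0])
        assert c.c == 0 and c.d == 0

    def test_planted_marker_ground_truth(self):
        cohort = generate_cohort(default_config(
            n_pos=15, n_neg=12, background_peaks=0, mz_range=(100.0, 300.0),
            anchor_range=False, seed=0))
        m = construct_features(cohort, build_grid(100, 300, 1.0), "height")
        w = truth_table(default_config(n_pos=15, n_neg=12, background_peaks=0,
                                       mz_range=(100.0, 300.0), seed=0),
                        m.grid)[113.02]
        c = presence_counts(m.values[:, w], cohort.y, m.missing_mask[:, w])
        assert (c.a, c.b, c.c, c.d) == (15, 0, 0, 12)

    def test_respects_explicit_mask(self):
        col = np.array([0.0, 5.0])
        mask = np.array([False, False])  # a true zero measurement, not missing
        c = presence_counts(col, [1, 0], mask)
        assert (c.a, c.b) == (1, 1)


class TestChi2Frequency:
    def test_balanced_identical_classes(self):
        assert chi2_frequency([3, 3, 3, 3], [1, 1, 0, 0]) == 0.0

    def test_hand_evaluated(self):
        # O = (4, 0), E = (2, 2): (4-2)^2/2 + (0-2)^2/2 = 4
        assert chi2_frequency([2, 2, 0, 0], [1, 1, 0, 0]) == 4.0

    def test_constant_zero_feature(self):
        assert chi2_frequency([0, 0, 0, 0], [1, 1, 0, 0]) == 0.0

    def test_matches_two_term_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            col = rng.uniform(0, 10, size=n)
            y = rng.integers(0, 2, size=n)
            if len(set(y.tolist())) < 2:
                continue
            # independent oracle: explicit two-term (O-E)^2/E
            total = col.sum()
            expected = 0.0
            for cls in (0, 1):
                e = (y == cls).mean() * total
                o = col[y == cls].sum()
                expected += (o - e) ** 2 / e
            assert chi2_frequency(col, y) == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn_scorer(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 5, size=(30, 8))
        y = rng.integers(0, 2, size=30)
        ours = np.array([chi2_frequency(X[:, j], y) for j in range(8)])
        theirs = sklearn_chi2(X, y)[0]
        np.testing.assert_allclose(ours, theirs, atol=1e-10)


class TestRankFeatures:
    def test_planted_marker_ranked_first(self):
        cfg = default_config(n_pos=20, n_neg=20, background_peaks=50,
                             mz_range=(100.0, 150.0), seed=0)
        cohort = generate_cohort(cfg)
        grid = build_grid(100, 150, 1.0)
        m = construct_features(cohort, grid, "height")
        truth = truth_table(cfg, grid)[113.02]
        assert rank_features(m, cohort.y)[0].feature_index == truth

    def test_tie_broken_by_lower_index(self):
        col = [5.0, 5.0, 1.0, 1.0]
        m = matrix_from(np.column_stack([col, col, [9, 1, 9, 1]]))
        ranked = rank_features(m, [1, 1, 0, 0])
        first_two = [s.feature_index for s in ranked[:2]]
        assert first_two == [0, 1]

    def test_matches_columnwise_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 4, size=(12, 5))
        y = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        m = matrix_from(values)
        ranked = rank_features(m, y)
        oracle = sorted(
            [(j, chi2_frequency(values[:, j], y)) for j in range(5)],
            key=lambda t: (-t[1], t[0]))
        assert [s.feature_index for s in ranked] == [j for j, _ in oracle]
        for s, (_, stat) in zip(ranked, oracle):
            assert s.chi2 == pytest.approx(stat)

    def test_contingency_method(self):
        values = np.array([[4.0, 1.0], [3.0, 0.0], [0.0, 2.0], [0.0, 5.0]])
        m = matrix_from(values)
        ranked = rank_features(m, [1, 1, 0, 0], method="contingency")
        assert ranked[0].feature_index == 0  # perfect presence split
        assert ranked[0].chi2 == 1.0

    def test_single_class_rejected(self, toy_cohort):
        m = construct_features(toy_cohort, build_grid(10, 20, 1.0), "height")
        with pytest.raises(ValueError):
            rank_features(m, np.ones(len(toy_cohort), dtype=int))

    def test_scale_invariance_of_ranking(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 3, size=(16, 6))
        y = rng.permutation([1] * 8 + [0] * 8)
        base = [s.feature_index for s in rank_features(matrix_from(values), y)]
        scaled = [s.feature_index
                  for s in rank_features(matrix_from(values * 137.5), y)]
        assert base == scaled

    def test_noise_feature_does_not_displace_marker(self):
        """Appending a pure-noise column leaves the planted marker at rank 1."""
        rng = np.random.default_rng(5)
        n = 30
        y = np.array([1] * 15 + [0] * 15)
        marker = np.where(y == 1, rng.lognormal(8, 0.5, n), rng.lognormal(5, 0.5, n))
        noise = rng.lognormal(5, 0.5, n)
        m = matrix_from(np.column_stack([noise, marker]))
        assert rank_features(m, y)[0].feature_index == 1
        m2 = matrix_from(np.column_stack([noise, marker, rng.lognormal(5, 0.5, n)]))
        assert rank_features(m2, y)[0].feature_index == 1


class TestMinimalSubsetSearch:
    def _separable_matrix(self):
        rng = np.random.default_rng(6)
        n = 24
        y = np.array([1] * 12 + [0] * 12)
        sep = np.where(y == 1, 10.0, 1.0) + rng.uniform(0, 0.1, n)
        noise = rng.uniform(0, 5, size=(n, 4))
        return matrix_from(np.column_stack([sep, noise])), y

    def test_single_separating_feature_gives_k1(self):
        m, y = self._separable_matrix()
        cohort_idx = np.arange(len(y))
        train, val, test = cohort_idx[::3], cohort_idx[1::3], cohort_idx[2::3]
        res = minimal_subset_search(m, y, train, val, test, k_max=4)
        assert res.k == 1
        assert res.validation.accuracy == 1.0
        assert res.feature_indices == [0]

    def test_k_never_exceeds_k_max_or_windows(self):
        m, y = self._separable_matrix()
        idx = np.arange(len(y))
        res = minimal_subset_search(m, y, idx[::3], idx[1::3], idx[2::3],
                                    k_max=50)
        assert res.k <= m.n_windows

    def test_invalid_k_max(self):
        m, y = self._separable_matrix()
        idx = np.arange(len(y))
        with pytest.raises(ValueError):
            minimal_subset_search(m, y, idx, idx, idx, k_max=0)

    def test_sweep_records_every_model_and_k(self):
        m, y = self._separable_matrix()
        idx = np.arange(len(y))
        res = minimal_subset_search(m, y, idx[::3], idx[1::3], idx[2::3], k_max=2)
        assert len(res.sweep) == 2 * 10
        best_per_k = {}
        for row in res.sweep:
            best_per_k[row["k"]] = max(best_per_k.get(row["k"], 0.0),
                                       row["val_accuracy"])
        assert best_per_k[res.k] == max(best_per_k.values())
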