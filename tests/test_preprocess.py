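import numpy as np
import pytest

from gdmcshm import preprocess as pp
from gdmcshm.synthetic_cohort import CohortConfig, default_feature_catalog, generate_cohort

from conftest import make_table


class TestFilterByMissingness:
    def test_feature_over_threshold_dropped(self):
        vals = np.column_stack([np.r_[[np.nan] * 6, np.zeros(4)], np.arange(10.0)])
        table = make_table(vals, ["continuous", "continuous"], [1] * 5 + [-1] * 5)
        out, report = pp.filter_by_missingness(table, 0.5, 0.5)
        assert out.feature_names == ["f1"]
        assert report.dropped_features == [("f0", 0.6)]

    def test_fully_observed_identity(self):
        table = make_table(np.arange(20.0).reshape(10, 2), ["continuous"] * 2, [1, -1] * 5)
        out, report = pp.filter_by_missingness(table)
        assert np.array_equal(out.values, table.values)
        assert report.dropped_features == [] and report.dropped_subjects == []

    def test_hand_counted_toy_grid(self):
        # 6 subjects x 3 features; by hand: f2 is 4/6 missing -> dropped;
        # then rows 0 (2/2 missing) and 4 (2/2) exceed 0.5 -> dropped.
        vals = np.array(
            [
                [np.nan, np.nan, 1.0],
                [1.0, 2.0, np.nan],
                [1.0, np.nan, np.nan],
                [2.0, 2.0, 1.0],
                [np.nan, np.nan, np.nan],
                [2.0, 1.0, np.nan],
            ]
        )
        table = make_table(vals, ["continuous"] * 3, [1, -1, 1, -1, 1, -1])
        out, report = pp.filter_by_missingness(table, 0.5, 0.5)
        assert out.n_features == 2 and out.n_subjects == 4
        assert [n for n, _ in report.dropped_features] == ["f2"]
        assert [i for i, _ in report.dropped_subjects] == [0, 4]

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(30, 4))
        vals[rng.random(vals.shape) < 0.4] = np.nan
        table = make_table(vals, ["continuous"] * 4, [1, -1] * 15)
        once, _ = pp.filter_by_missingness(table, 0.3, 0.3)
        twice, rep2 = pp.filter_by_missingness(once, 0.3, 0.3)
        assert np.array_equal(once.values, twice.values, equal_nan=True)
        assert rep2.dropped_features == [] and rep2.dropped_subjects == []

    def test_error_when_everything_dropped(self):
        vals = np.full((4, 2), np.nan)
        table = make_table(vals, ["continuous"] * 2, [1, -1, 1, -1])
        with pytest.raises(ValueError):
            pp.filter_by_missingness(table, 0.4, 0.4)


class TestMinMaxNormalize:
    def test_endpoints(self):
        table = make_table([[150.0], [160.0], [170.0]], ["continuous"], [1, -1, 1])
        out, record = pp.min_max_normalize(table)
        assert np.allclose(out.values[:, 0], [0.0, 0.5, 1.0])
        assert record["f0"] == (150.0, 170.0)

    def test_constant_column_warns_to_zero(self, caplog):
        table = make_table([[7.0], [7.0], [7.0]], ["continuous"], [1, -1, 1])
        with caplog.at_level("WARNING"):
            out, _ = pp.min_max_normalize(table)
        assert np.allclose(out.values[:, 0], 0.0)
        assert any("constant" in r.message for r in caplog.records)

    def test_order_preserved_and_range_exact(self):
        rng = np.random.default_rng(8)
        col = rng.exponential(size=50)
        table = make_table(col[:, None], ["continuous"], [1, -1] * 25)
        out, _ = pp.min_max_normalize(table)
        norm = out.values[:, 0]
        assert norm.min() == 0.0 and norm.max() == 1.0
        assert np.array_equal(np.argsort(norm), np.argsort(col))

    def test_ordinal_and_binary_untouched(self):
        table = make_table([[1.0, 0.0], [3.0, 1.0]], ["ordinal3", "binary"], [1, -1])
        out, record = pp.min_max_normalize(table)
        assert np.array_equal(out.values, table.values)
        assert record == {}

    def test_fit_on_train_never_peeks_at_test(self):
        rng = np.random.default_rng(1)
        train = make_table(rng.normal(size=(20, 1)), ["continuous"], [1, -1] * 10)
        _, record = pp.min_max_normalize(train)
        test = make_table(rng.normal(10, 5, size=(5, 1)), ["continuous"], [1, -1, 1, -1, 1])
        applied = pp.apply_min_max(test, record)
        lo, hi = record["f0"]
        assert np.allclose(applied.values[:, 0], (test.values[:, 0] - lo) / (hi - lo))
        # values outside [0,1] are expected on held-out data
        assert applied.values[:, 0].max() > 1.0


class TestDiscretize:
    def test_equal_frequency_forced(self):
        table = make_table(np.arange(1.0, 10.0)[:, None], ["continuous"], [1, -1] * 4 + [1])
        out, _ = pp.discretize_continuous(table, 3)
        assert np.array_equal(out.values[:, 0], [1, 1, 1, 2, 2, 2, 3, 3, 3])

    def test_ordinal_feature_unchanged(self):
        table = make_table([[1.0], [2.0], [3.0]], ["ordinal3"], [1, -1, 1])
        out, cuts = pp.discretize_continuous(table, 3)
        assert np.array_equal(out.values, table.values)
        assert cuts == {}

    def test_skewed_sample_balanced_bins(self):
        rng = np.random.default_rng(5)
        col = rng.exponential(size=99)
        table = make_table(col[:, None], ["continuous"], [1, -1] * 49 + [1])
        out, _ = pp.discretize_continuous(table, 3)
        counts = [int((out.values[:, 0] == k).sum()) for k in (1, 2, 3)]
        assert all(abs(c - 33) <= 1 for c in counts)

    def test_fewer_distinct_values_than_bins(self):
        table = make_table([[1.0], [1.0], [5.0], [5.0]], ["continuous"], [1, -1, 1, -1])
        out, _ = pp.discretize_continuous(table, 3)
        assert set(np.unique(out.values[:, 0])) == {1.0, 2.0}

    def test_cuts_reapply_to_held_out_rows(self):
        train = make_table(np.arange(1.0, 10.0)[:, None], ["continuous"], [1, -1] * 4 + [1])
        _, cuts = pp.discretize_continuous(train, 3)
        test = make_table([[0.0], [5.0], [99.0]], ["continuous"], [1, -1, 1])
        out = pp.apply_discretization(test, cuts)
        assert np.array_equal(out.values[:, 0], [1.0, 2.0, 3.0])


class TestImputePmm:
    def _holey_cohort(self, n=600, seed=2):
        rng = np.random.default_rng(seed)
        x1 = rng.normal(size=n)
        x2 = 0.8 * x1 + rng.normal(scale=0.5, size=n)
        x3 = rng.integers(1, 4, size=n).astype(float)
        labels = np.where(rng.random(n) < 0.3, 1, -1)
        table = make_table(
            np.column_stack([x1, x2, x3]), ["continuous", "continuous", "ordinal3"], labels
        )
        table.values[rng.random(n) < 0.1, 1] = np.nan
        table.values[rng.random(n) < 0.1, 2] = np.nan
        return table

    def test_no_missing_gives_identical_copies(self):
        table = make_table(np.arange(20.0).reshape(10, 2), ["continuous"] * 2, [1, -1] * 5)
        outs = pp.impute_pmm(table, k_donors=3, m=4, seed=0)
        assert len(outs) == 4
        for out in outs:
            assert np.array_equal(out.values, table.values)

    def test_single_observed_value_always_copied(self):
        col = np.array([2.0] * 8 + [np.nan, np.nan])
        other = np.arange(10.0)
        table = make_table(np.column_stack([other, col]), ["continuous"] * 2, [1, -1] * 5)
        outs = pp.impute_pmm(table, k_donors=5, m=3, seed=1)
        for out in outs:
            assert np.allclose(out.values[:, 1], 2.0)

    def test_support_property(self):
        table = self._holey_cohort()
        observed = {
            j: set(table.values[~np.isnan(table.values[:, j]), j]) for j in (1, 2)
        }
        for out in pp.impute_pmm(table, k_donors=5, m=5, seed=3):
            assert not np.isnan(out.values).any()
            for j in (1, 2):
                assert set(out.values[:, j]) <= observed[j] | set(
                    table.values[~np.isnan(table.values[:, j]), j]
                )

    def test_error_when_too_few_donors(self):
        col = np.array([1.0, 2.0, np.nan, np.nan, np.nan, np.nan])
        table = make_table(
            np.column_stack([np.arange(6.0), col]), ["continuous"] * 2, [1, -1] * 3
        )
        with pytest.raises(ValueError, match="f1"):
            pp.impute_pmm(table, k_donors=5, m=2, seed=0)


class TestPoolImputations:
    def test_identical_tables_identity(self):
        table = make_table(np.arange(8.0).reshape(4, 2), ["continuous"] * 2, [1, -1, 1, -1])
        pooled = pp.pool_imputations([table.copy() for _ in range(5)])
        assert np.array_equal(pooled.values, table.values)

    def test_ordinal_mode_tie_goes_low(self):
        tables = [
            make_table([[v]], ["ordinal3"], [1]) for v in (1.0, 2.0, 2.0, 3.0, 3.0)
        ]
        pooled = pp.pool_imputations(tables)
        assert pooled.values[0, 0] == 2.0

    def test_continuous_median(self):
        tables = [make_table([[v]], ["continuous"], [1]) for v in (1.0, 2.0, 10.0)]
        pooled = pp.pool_imputations(tables)
        assert pooled.values[0, 0] == 2.0

    def test_first_mode_and_empty_error(self):
        tables = [make_table([[v]], ["continuous"], [1]) for v in (5.0, 7.0)]
        assert pp.pool_imputations(tables, mode="first").values[0, 0] == 5.0
        with pytest.raises(ValueError):
            pp.pool_imputations([])


class TestSplitAndFolds:
    def test_reference_sizes_90_10(self):
        table = generate_cohort(
            CohortConfig(4378, default_feature_catalog(), 0.14, seed=0, with_missingness=False)
        )
        train, test = pp.split_train_test(table, pp.SplitSpec(0.9, True, 0))
        assert (train.n_subjects, test.n_subjects) == (3940, 438)

    def test_stratified_half_split_balance(self):
        n = 200
        labels = np.r_[np.ones(28), -np.ones(172)].astype(int)
        table = make_table(np.zeros((n, 1)), ["continuous"], labels)
        a, b = pp.split_train_test(table, pp.SplitSpec(0.5, True, 4))
        assert abs((a.labels == 1).sum() - (b.labels == 1).sum()) <= 1

    def test_split_deterministic_disjoint_exhaustive(self):
        table = make_table(np.arange(50.0)[:, None], ["continuous"], [1, -1] * 25)
        a1, b1 = pp.split_train_test(table, pp.SplitSpec(0.7, True, 9))
        a2, b2 = pp.split_train_test(table, pp.SplitSpec(0.7, True, 9))
        assert np.array_equal(a1.ids, a2.ids) and np.array_equal(b1.ids, b2.ids)
        assert set(a1.ids) | set(b1.ids) == set(range(50))
        assert set(a1.ids) & set(b1.ids) == set()

    def test_fold_sizes(self):
        table = make_table(np.zeros((103, 1)), ["continuous"], [1, -1] * 51 + [1])
        folds = pp.make_cv_folds(table, k=10, seed=0)
        sizes = sorted(len(va) for _, va in folds)
        assert sizes == [10] * 7 + [11] * 3

    def test_folds_partition(self):
        table = make_table(np.zeros((100, 1)), ["continuous"], [1, -1] * 50)
        folds = pp.make_cv_folds(table, k=10, seed=1)
        all_val = np.concatenate([va for _, va in folds])
        assert sorted(all_val) == list(range(100))
        for tr, va in folds:
            assert set(tr) | set(va) == set(range(100))
            assert set(tr) & set(va) == set()


class TestUndersample:
    def _table(self):
        labels = np.r_[np.ones(10), -np.ones(90)].astype(int)
        return make_table(np.arange(100.0)[:, None], ["continuous"], labels)

    @pytest.mark.parametrize("ratio,expected", [(1.0, 20), (2.0, 30)])
    def test_ratio_counts(self, ratio, expected):
        out = pp.undersample_majority(self._table(), ratio=ratio, seed=0)
        assert out.n_subjects == expected
        assert (out.labels == 1).sum() == 10

    def test_deterministic_and_ratio_too_large(self):
        a = pp.undersample_majority(self._table(), ratio=1.0, seed=7)
        b = pp.undersample_majority(self._table(), ratio=1.0, seed=7)
        assert np.array_equal(a.ids, b.ids)
        with pytest.raises(ValueError):
            pp.undersample_majority(self._table(), ratio=10.0, seed=0)
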