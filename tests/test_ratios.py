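"""Reference-frame log-ratio tests: cancellation, pairing, zero policy."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from refframes import (FeatureTable, LogRatioResult, absolute_from_relative,
                       compute_log_ratio, correlate_with_covariate,
                       paired_ttest, per_taxon_naive_tests,
                       simulate_count_experiment)


def _lr(values, samples, num=("n",), den=("d",), dropped=()):
    return LogRatioResult(tuple(samples), np.asarray(values, float),
                          tuple(dropped), tuple(num), tuple(den))


class TestComputeLogRatio:
    def test_single_taxon_sets(self):
        ft = FeatureTable(np.array([[8, 2]]), ("s1",), ("a", "b"))
        lr = compute_log_ratio(ft, ["a"], ["b"])
        assert lr.values[0] == pytest.approx(np.log(4))

    def test_zero_in_denominator_drops_sample(self):
        ft = FeatureTable(np.array([[8, 2], [5, 0], [3, 6]]),
                          ("s1", "s2", "s3"), ("a", "b"))
        lr = compute_log_ratio(ft, ["a"], ["b"])
        assert lr.dropped_sample_ids == ("s2",)
        assert lr.sample_ids == ("s1", "s3")
        assert set(lr.sample_ids) | set(lr.dropped_sample_ids) \
            == {"s1", "s2", "s3"}

    def test_load_scaling_cancels(self, rng):
        n, D = 15, 10
        counts = rng.integers(1, 200, size=(n, D))
        samples = tuple(f"s{i}" for i in range(n))
        taxa = tuple(f"t{i}" for i in range(D))
        ft = FeatureTable(counts, samples, taxa)
        loads = pd.Series(rng.uniform(1e3, 1e9, size=n), index=samples)
        absolute = absolute_from_relative(ft, loads)
        num, den = ["t1", "t4"], ["t7"]
        from_counts = compute_log_ratio(ft, num, den)
        from_absolute = compute_log_ratio(absolute, num, den)
        assert np.abs(from_counts.values - from_absolute.values).max() < 1e-10

    def test_multi_taxon_geometric_mean(self):
        ft = FeatureTable(np.array([[4, 16, 2]]), ("s1",), ("a", "b", "c"))
        lr = compute_log_ratio(ft, ["a", "b"], ["c"])
        gm = np.sqrt(4 * 16)
        assert lr.values[0] == pytest.approx(np.log(gm / 2))

    def test_overlap_and_unknown_errors(self, small_table):
        with pytest.raises(ValueError, match="overlap"):
            compute_log_ratio(small_table, ["taxA"], ["taxA", "taxB"])
        with pytest.raises(KeyError, match="taxZ"):
            compute_log_ratio(small_table, ["taxZ"], ["taxB"])

    def test_all_samples_dropped_errors(self):
        ft = FeatureTable(np.array([[1, 0], [2, 0]]), ("s1", "s2"), ("a", "b"))
        with pytest.raises(ValueError, match="zero.coverage"):
            compute_log_ratio(ft, ["a"], ["b"])


class TestPairedTTest:
    def test_textbook_differences(self):
        before = _lr([0, 0, 0], ["b1", "b2", "b3"])
        after = _lr([1, 2, 3], ["a1", "a2", "a3"])
        pairing = {"b1": "a1", "b2": "a2", "b3": "a3"}
        res = paired_ttest(before, after, pairing)
        # hand formula: mean 2, sd 1, t = 2 / (1/sqrt(3)); p from t CDF
        t_hand = 2 / (1 / np.sqrt(3))
        p_hand = 2 * stats.t.sf(t_hand, df=2)
        assert res.t_statistic == pytest.approx(t_hand, abs=1e-10)
        assert res.p_value == pytest.approx(p_hand, abs=1e-10)
        assert res.n_pairs == 3

    def test_symmetric_differences_give_zero_t(self):
        before = _lr([0, 0], ["b1", "b2"])
        after = _lr([-1, 1], ["a1", "a2"])
        res = paired_ttest(before, after, {"b1": "a1", "b2": "a2"})
        assert res.t_statistic == 0
        assert res.p_value == pytest.approx(1.0)

    def test_pairs_with_dropped_side_excluded(self):
        before = _lr([0.5, 0.7], ["b1", "b3"], dropped=("b2",))
        after = _lr([1.0, 1.1, 0.2], ["a1", "a2", "a3"])
        with pytest.raises(ValueError, match="2 complete pairs"):
            paired_ttest(before, _lr([1.0], ["a1"]),
                         {"b1": "a1", "b2": "a2", "b3": "a3"})

    def test_zero_variance_flagged_degenerate(self):
        before = _lr([0, 0, 0], ["b1", "b2", "b3"])
        after = _lr([1, 1, 1], ["a1", "a2", "a3"])
        with pytest.raises(ValueError, match="degenerate"):
            paired_ttest(before, after, {"b1": "a1", "b2": "a2", "b3": "a3"})

    def test_relative_equals_absolute(self, rng):
        # the module's defining contract: per-sample load cancels exactly
        exp = simulate_count_experiment(10, 6, depth=3000, seed=13,
                                        log_load_ratio=1.5)
        ft = exp.table
        absolute = absolute_from_relative(ft, exp.loads)
        pairing = {f"A{i}": f"B{i}" for i in range(10)}
        num, den = [ft.taxon_ids[0]], [ft.taxon_ids[3]]
        t_rel = paired_ttest(compute_log_ratio(ft, num, den),
                             compute_log_ratio(ft, num, den), pairing)
        t_abs = paired_ttest(compute_log_ratio(absolute, num, den),
                             compute_log_ratio(absolute, num, den), pairing)
        assert t_rel.t_statistic == pytest.approx(t_abs.t_statistic, abs=1e-10)
        assert t_rel.p_value == pytest.approx(t_abs.p_value, abs=1e-10)


class TestCorrelateWithCovariate:
    def test_perfect_linear_pearson(self):
        lr = _lr([1.0, 2.0, 3.0, 4.0], ["s1", "s2", "s3", "s4"])
        cov = {"s1": 10, "s2": 20, "s3": 30, "s4": 40}
        r, p = correlate_with_covariate(lr, cov, "pearson")
        assert r == pytest.approx(1.0)

    def test_constant_covariate_errors(self):
        lr = _lr([1.0, 2.0, 3.0], ["s1", "s2", "s3"])
        with pytest.raises(ValueError, match="constant"):
            correlate_with_covariate(lr, {"s1": 5, "s2": 5, "s3": 5})

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_matches_scipy_on_retained_samples(self, rng, method):
        samples = [f"s{i}" for i in range(12)]
        vals = rng.normal(size=10)
        lr = _lr(vals, samples[:10], dropped=tuple(samples[10:]))
        cov = pd.Series(rng.normal(size=12), index=samples)
        r, p = correlate_with_covariate(lr, cov, method)
        f = stats.pearsonr if method == "pearson" else stats.spearmanr
        expected = f(vals, cov[samples[:10]].to_numpy())
        assert r == pytest.approx(float(expected[0]), abs=1e-10)
        assert p == pytest.approx(float(expected[1]), abs=1e-10)


class TestAbsoluteFromRelative:
    def test_load_times_proportions(self):
        ft = FeatureTable(np.array([[20, 80]]), ("s1",), ("a", "b"))
        prof = absolute_from_relative(ft, np.array([1000.0]))
        assert np.allclose(prof.values, [[200.0, 800.0]])

    def test_copy_number_correction(self):
        ft = FeatureTable(np.array([[4, 4]]), ("s1",), ("a", "b"))
        prof = absolute_from_relative(ft, np.array([300.0]),
                                      copy_numbers=np.array([2.0, 1.0]))
        assert np.allclose(prof.values, [[100.0, 200.0]])

    def test_row_sums_equal_load(self, rng, small_table):
        loads = rng.uniform(100, 1e6, size=small_table.n_samples)
        prof = absolute_from_relative(small_table, loads)
        assert np.abs(prof.values.sum(axis=1) - loads).max() < 1e-6

    def test_log_ratio_unchanged_by_load(self, rng, small_table):
        loads = rng.uniform(10, 1e5, size=small_table.n_samples)
        prof = absolute_from_relative(small_table, loads)
        a = compute_log_ratio(small_table, ["taxA"], ["taxD"])
        b = compute_log_ratio(prof, ["taxA"], ["taxD"])
        assert np.abs(a.values - b.values).max() < 1e-12

    def test_nonpositive_load_errors(self, small_table):
        with pytest.raises(ValueError, match="positive"):
            absolute_from_relative(small_table, np.array([1.0, 2.0, 0.0, 4.0]))


class TestPerTaxonNaiveTests:
    @staticmethod
    def _pair(n):
        return {f"A{i}": f"B{i}" for i in range(n)}

    def test_identical_tables_give_zero_t(self):
        counts = np.array([[5, 5, 5], [6, 4, 2]])
        before = FeatureTable(counts, ("A0", "A1"), ("x", "y", "z"))
        after = FeatureTable(counts, ("B0", "B1"), ("x", "y", "z"))
        # align pairing so each sample is compared to its clone
        after = FeatureTable(counts, ("B0", "B1"), ("x", "y", "z"))
        df = per_taxon_naive_tests(before, after, {"A0": "B0", "A1": "B1"})
        assert (df["t_statistic"] == 0).all()
        assert (df["reference_frame"] == "none (biased by total load)").all()

    def test_constant_taxon_looks_changed_on_relative_data(self):
        # community declines 4-fold while taxon "stable" is constant:
        # its proportion rises, the naive relative test calls it positive,
        # the absolute test does not
        rng = np.random.default_rng(0)
        n, D = 60, 5
        base = np.array([1000, 800, 600, 400, 500], dtype=float)
        before_abs = rng.poisson(base, size=(n, D)).astype(float) + 1
        after_abs = rng.poisson(base * [0.25, 0.25, 0.25, 0.25, 1.0],
                                size=(n, D)).astype(float) + 1
        samples_b = tuple(f"A{i}" for i in range(n))
        samples_a = tuple(f"B{i}" for i in range(n))
        taxa = ("t1", "t2", "t3", "t4", "stable")
        ft_b = FeatureTable(before_abs.astype(int), samples_b, taxa)
        ft_a = FeatureTable(after_abs.astype(int), samples_a, taxa)
        rel = per_taxon_naive_tests(ft_b, ft_a, self._pair(n))
        loads_b = pd.Series(before_abs.sum(axis=1), index=samples_b)
        loads_a = pd.Series(after_abs.sum(axis=1), index=samples_a)
        abs_b = absolute_from_relative(ft_b, loads_b)
        abs_a = absolute_from_relative(ft_a, loads_a)
        absolute = per_taxon_naive_tests(abs_b, abs_a, self._pair(n))
        t_rel = rel.set_index("taxon_id")["t_statistic"]["stable"]
        t_abs = absolute.set_index("taxon_id")["t_statistic"]["stable"]
        assert t_rel > 2.0       # naive relative test: spurious increase
        assert abs(t_abs) < 2.0  # absolute data: no real change

    def test_matches_independent_per_taxon_oracle(self, rng):
        n, D = 12, 6
        cb = rng.integers(1, 50, size=(n, D))
        ca = rng.integers(1, 50, size=(n, D))
        taxa = tuple(f"t{i}" for i in range(D))
        ft_b = FeatureTable(cb, tuple(f"A{i}" for i in range(n)), taxa)
        ft_a = FeatureTable(ca, tuple(f"B{i}" for i in range(n)), taxa)
        df = per_taxon_naive_tests(ft_b, ft_a, self._pair(n)).set_index("taxon_id")
        pb = cb / cb.sum(axis=1, keepdims=True)
        pa = ca / ca.sum(axis=1, keepdims=True)
        for j, t in enumerate(taxa):
            expect = stats.ttest_rel(pa[:, j], pb[:, j])
            assert df.loc[t, "t_statistic"] == pytest.approx(
                float(expect.statistic), abs=1e-10)
            assert df.loc[t, "p_value"] == pytest.approx(
                float(expect.pvalue), abs=1e-10)

    def test_fdr_column_present_when_requested(self, rng):
        n, D = 8, 4
        ft_b = FeatureTable(rng.integers(1, 30, size=(n, D)),
                            tuple(f"A{i}" for i in range(n)),
                            tuple(f"t{i}" for i in range(D)))
        ft_a = FeatureTable(rng.integers(1, 30, size=(n, D)),
                            tuple(f"B{i}" for i in range(n)),
                            tuple(f"t{i}" for i in range(D)))
        df = per_taxon_naive_tests(ft_b, ft_a, self._pair(n), fdr=True)
        assert "q_value" in df.columns
        assert (df["q_value"].dropna() >= df["p_value"].dropna() - 1e-12).all()


def test_scale_invariance_of_log_ratio_statistics(rng):
    """Multiplying each sample by an arbitrary constant changes nothing."""
    exp = simulate_count_experiment(8, 6, depth=2000, seed=21)
    ft = exp.table
    scales = rng.uniform(0.5, 2000, size=ft.n_samples)
    scaled = absolute_from_relative(ft, ft.counts.sum(axis=1) * scales)
    num, den = [ft.taxon_ids[1]], [ft.taxon_ids[5]]
    a = compute_log_ratio(ft, num, den)
    b = compute_log_ratio(scaled, num, den)
    assert a.sample_ids == b.sample_ids
    assert np.abs(a.values - b.values).max() < 1e-10
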