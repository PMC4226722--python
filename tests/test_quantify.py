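import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isomirpipe.quantify import (
    filter_isomirs, one_sample_ttest, quantile_normalize, summarize_arms,
)

IDX = ["arm_id", "off5", "off3"]


def naive_quantile_normalize(X: np.ndarray) -> np.ndarray:
    """Independent oracle: literal rank-mean procedure with tie averaging,
    written without vectorized tricks."""
    n, m = X.shape
    rank_means = np.mean(np.sort(X, axis=0), axis=1)
    out = np.zeros_like(X, dtype=float)
    for j in range(m):
        col = list(X[:, j])
        order = sorted(range(n), key=lambda i: col[i])
        assigned = [0.0] * n
        for rank, i in enumerate(order):
            assigned[i] = rank_means[rank]
        # tie averaging: all rows sharing a value get the mean of their means
        for v in set(col):
            idx = [i for i in range(n) if col[i] == v]
            mean_v = sum(assigned[i] for i in idx) / len(idx)
            for i in idx:
                assigned[i] = mean_v
        out[:, j] = assigned
    return out


def _df(X):
    X = np.asarray(X)
    idx = pd.MultiIndex.from_tuples(
        [(f"arm{i // 3}", i % 3, 0) for i in range(X.shape[0])], names=IDX)
    return pd.DataFrame(X, index=idx,
                        columns=[f"s{j}" for j in range(X.shape[1])])


class TestQuantileNormalize:
    def test_matches_independent_oracle_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(2, 30))
            m = int(rng.integers(2, 8))
            X = rng.integers(0, 50, size=(n, m)).astype(float)
            got = quantile_normalize(_df(X)).to_numpy()
            exp = naive_quantile_normalize(X)
            np.testing.assert_allclose(got, exp, atol=1e-9)

    def test_columns_share_value_multiset(self):
        # tie-free input: the sorted columns must be bitwise-identical; with
        # ties the multisets differ by tie-averaging but column sums agree
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 100, size=(40, 5))
        out = quantile_normalize(_df(X)).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-9)
        Xt = rng.poisson(20, size=(40, 5)).astype(float)
        out_t = quantile_normalize(_df(Xt)).to_numpy()
        np.testing.assert_allclose(out_t.sum(axis=0),
                                   out_t.sum(axis=0)[0], atol=1e-9)

    def test_fixed_point_when_columns_share_multiset(self):
        base = np.array([1.0, 4.0, 9.0, 16.0])
        X = np.column_stack([base, base[::-1], np.roll(base, 1)])
        out = quantile_normalize(_df(X)).to_numpy()
        np.testing.assert_allclose(out, X)

    def test_constant_matrix_unchanged(self):
        X = np.full((5, 3), 7.0)
        np.testing.assert_allclose(quantile_normalize(_df(X)).to_numpy(), X)

    def test_single_sample_identity_with_warning(self):
        df = _df(np.array([[1.0], [2.0]]))
        with pytest.warns(UserWarning, match="single sample"):
            out = quantile_normalize(df)
        np.testing.assert_allclose(out.to_numpy(), df.to_numpy())

    def test_preserves_within_column_ranks_and_total_mass(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 100, size=(30, 4))
        df = _df(X)
        out = quantile_normalize(df).to_numpy()
        for j in range(4):
            assert (np.argsort(X[:, j]) == np.argsort(out[:, j])).all()
        assert abs(out.sum() - X.sum()) < 1e-9 * X.sum()


def arm_df(shares, scale=1000.0, arm="armX", n_samples=4):
    idx = pd.MultiIndex.from_tuples(
        [(arm, 0, k) for k in range(len(shares))], names=IDX)
    vals = np.outer(np.asarray(shares) * scale, np.ones(n_samples))
    return pd.DataFrame(vals, index=idx,
                        columns=[f"s{j}" for j in range(n_samples)])


def brute_force_filter(shares, cum_share=0.95):
    """Oracle: enumerate prefixes of the descending-share list, iterated to a
    fixed point, and return how many isomiRs survive."""
    vals = sorted(shares, reverse=True)
    k = len(vals)
    while True:
        total = sum(vals[:k])
        k_new = None
        for j in range(1, k + 1):
            if sum(vals[:j]) >= cum_share * total - 1e-12:
                k_new = j
                break
        if k_new == k:
            return k
        k = k_new


class TestFilterIsomirs:
    def test_arm_below_min_top_mean_dropped(self):
        df = arm_df([1.0], scale=24.9)
        assert filter_isomirs(df).empty
        df = arm_df([1.0], scale=25.0)
        assert len(filter_isomirs(df)) == 1

    def test_single_isomir_arm_kept_with_full_share(self):
        out = filter_isomirs(arm_df([1.0], scale=100))
        assert len(out) == 1

    def test_spec_example_prefix(self):
        out = filter_isomirs(arm_df([0.70, 0.20, 0.06, 0.04], scale=1000))
        assert len(out) == 3  # 0.96 >= 0.95

    def test_matches_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            k = int(rng.integers(1, 9))
            shares = rng.dirichlet(np.full(k, rng.uniform(0.3, 5.0)))
            out = filter_isomirs(arm_df(shares, scale=10_000))
            assert len(out) == brute_force_filter(list(shares))

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            k = int(rng.integers(1, 9))
            shares = rng.dirichlet(np.full(k, rng.uniform(0.3, 5.0)))
            once = filter_isomirs(arm_df(shares, scale=10_000))
            twice = filter_isomirs(once)
            pd.testing.assert_frame_equal(once, twice)

    def test_ties_broken_by_offsets(self):
        idx = pd.MultiIndex.from_tuples(
            [("a", 0, 2), ("a", 0, 1), ("a", 0, 0)], names=IDX)
        df = pd.DataFrame(np.full((3, 2), 100.0), index=idx, columns=["s0", "s1"])
        out = filter_isomirs(df, cum_share=0.95)
        # equal means: deterministic (off5, off3) lexicographic order decides
        assert list(out.index) == [("a", 0, 0), ("a", 0, 1), ("a", 0, 2)]

    def test_empty_matrix(self):
        assert filter_isomirs(arm_df([1.0]).iloc[0:0]).empty


class TestOneSampleTTest:
    def test_closed_form_example(self):
        # t = mean / (sd / sqrt(n)) = 2 / (1 / sqrt(3))
        t, p, degenerate = one_sample_ttest([1, 2, 3], 0.0, transform="identity")
        assert not degenerate
        assert t == pytest.approx(2.0 * math.sqrt(3), rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(2 * math.sqrt(3), 2), rel=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(1.0, 2.0, size=12)
        t, p, _ = one_sample_ttest(x, 0.5, transform="identity")
        ref = stats.ttest_1samp(x, 0.5)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_degenerate_cases(self):
        assert one_sample_ttest([3, 3, 3], 3.0, transform="identity") == (0.0, 1.0, True)
        t, p, degenerate = one_sample_ttest([3, 3, 3], 0.0, transform="identity")
        assert degenerate and p == 0.0 and t == math.inf

    def test_p_decreases_with_n_at_fixed_mean_and_sd(self):
        x = np.array([1.0, 2.0, 3.0])
        _, p1, _ = one_sample_ttest(x, 0.0, transform="identity")
        _, p2, _ = one_sample_ttest(np.tile(x, 2), 0.0, transform="identity")
        assert p2 < p1

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            one_sample_ttest([1.0])

    def test_default_transform_is_log2_plus_one(self):
        t1, p1, _ = one_sample_ttest([1, 3, 7], 0.0)
        t2, p2, _ = one_sample_ttest(np.log2(np.array([1, 3, 7]) + 1.0), 0.0,
                                     transform="identity")
        assert (t1, p1) == pytest.approx((t2, p2))


def _summary_matrix(rows):
    """rows: list of (arm, off5, off3, mean)."""
    idx = pd.MultiIndex.from_tuples([r[:3] for r in rows], names=IDX)
    vals = np.outer([r[3] for r in rows], np.ones(3))
    return pd.DataFrame(vals, index=idx, columns=["s0", "s1", "s2"])


class TestSummarizeArms:
    @pytest.mark.parametrize("o5,o3,category", [
        (0, 0, "none"), (0, 1, "3p_only"), (0, -2, "3p_only"),
        (1, 0, "5p_only"), (-1, 0, "5p_only"), (-1, 2, "both"), (1, -1, "both"),
    ])
    def test_disagreement_truth_table(self, o5, o3, category):
        rows = [("a", o5, o3, 1000.0)]
        if (o5, o3) != (0, 0):
            rows.append(("a", 0, 0, 100.0))
        df = _summary_matrix(rows)
        per_arm, _ = summarize_arms(df, df)
        assert per_arm.loc["a", "category"] == category
        assert per_arm.loc["a", "top_matches_reference"] == ((o5, o3) == (0, 0))

    def test_top_is_reference_never_conservative(self):
        df = _summary_matrix([("a", 0, 0, 1000.0), ("a", 0, 1, 500.0)])
        per_arm, _ = summarize_arms(df, df)
        assert not per_arm.loc["a", "conservative_flag"]

    def test_ratio_exactly_1_5_is_conservative(self):
        # top+1 = 150, ref+1 = 100 -> log2 ratio exactly log2(1.5)
        df = _summary_matrix([("a", 0, 1, 149.0), ("a", 0, 0, 99.0)])
        per_arm, _ = summarize_arms(df, df)
        assert per_arm.loc["a", "conservative_flag"]
        df = _summary_matrix([("a", 0, 1, 148.0), ("a", 0, 0, 99.0)])
        per_arm, _ = summarize_arms(df, df)
        assert not per_arm.loc["a", "conservative_flag"]

    def test_reference_filtered_out_detected(self):
        filtered = _summary_matrix([("a", 0, 1, 1000.0)])
        full = _summary_matrix([("a", 0, 1, 1000.0), ("a", 0, 0, 10.0)])
        per_arm, agg = summarize_arms(filtered, full)
        assert not per_arm.loc["a", "reference_in_95th"]
        # the reference mean still comes from the unfiltered layer
        assert per_arm.loc["a", "reference_mean"] == pytest.approx(10.0)
        row = agg.set_index("statistic").loc["reference_not_in_95th"]
        assert row["count"] == 1

    def test_aggregate_counts(self):
        df = _summary_matrix([
            ("a", 0, 0, 1000.0), ("a", 0, 1, 100.0),
            ("b", 0, 1, 1000.0), ("b", 0, 0, 100.0),
            ("c", -1, 2, 1000.0), ("c", 0, 0, 100.0),
        ])
        per_arm, agg = summarize_arms(df, df)
        agg = agg.set_index("statistic")
        assert agg.loc["arms_considered", "count"] == 3
        assert agg.loc["top_disagrees", "count"] == 2
        assert agg.loc["disagrees_3p", "count"] == 2
        assert agg.loc["disagrees_3p_only", "count"] == 1
        assert agg.loc["disagrees_both", "count"] == 1
        assert agg.loc["disagrees_5p_only", "count"] == 0
        assert agg.loc["top_disagrees", "percentage"] == 67
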