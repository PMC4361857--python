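"""KNN randomisation test, Bonferroni family, and source pooling."""

import itertools
import math

import numpy as np
import pytest

from isodiet import (IsotopeVector, Region, SourceSample,
                     knn_randomization_test, merge_sources,
                     pairwise_source_tests)


def knn_stat_oracle(x, labels, k):
    """Independent brute-force statistic: same-label fraction among k NN."""
    n = len(x)
    total = 0.0
    for i in range(n):
        d = [(np.sum((x[i] - x[j]) ** 2), j) for j in range(n) if j != i]
        d.sort()
        nn = [j for _, j in d[:k]]
        total += np.mean([labels[j] == labels[i] for j in nn])
    return total / n


def exact_p_oracle(x, n_a, k):
    """Enumerate all C(n, n_a) labelings; p = fraction with stat >= observed."""
    n = len(x)
    obs_labels = np.array([0] * n_a + [1] * (n - n_a))
    obs = knn_stat_oracle(x, obs_labels, k)
    count, total = 0, 0
    for combo in itertools.combinations(range(n), n_a):
        lab = np.ones(n, int)
        lab[list(combo)] = 0
        if knn_stat_oracle(x, lab, k) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


class TestKnnTest:
    def test_complete_separation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, (10, 2))
        b = rng.normal(100, 1, (10, 2))
        res = knn_randomization_test(a, b, k=3, n_perm=999, seed=1)
        assert res.observed_stat == 1.0
        assert res.p_value == pytest.approx(1 / 1000)

    def test_null_case_copy_rarely_significant(self):
        """b an exact interleaved copy of a: p > 0.05 in >= 95% of 200 seeds."""
        rng = np.random.default_rng(5)
        nonsig = 0
        for s in range(200):
            a = rng.normal(0, 1, (10, 2))
            res = knn_randomization_test(a, a.copy(), k=3, n_perm=999, seed=s)
            nonsig += res.p_value > 0.05
        assert nonsig >= 190

    def test_exact_mode_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            x = rng.normal(0, 1, (6, 2))
            res = knn_randomization_test(x[:3], x[3:], k=1, method="exact")
            assert res.p_value == pytest.approx(exact_p_oracle(x, 3, 1), abs=1e-12)
            assert res.n_permutations == math.comb(6, 3)

    def test_monte_carlo_converges_to_exact(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (8, 2))
        x[4:] += 1.5
        exact = knn_randomization_test(x[:4], x[4:], k=2, method="exact").p_value
        mc = knn_randomization_test(x[:4], x[4:], k=2, n_perm=49999, seed=9).p_value
        assert mc == pytest.approx(exact, abs=0.01)

    def test_p_never_zero_and_bounded_below(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, (5, 2))
        b = rng.normal(50, 1, (5, 2))
        res = knn_randomization_test(a, b, k=2, n_perm=99, seed=0)
        assert res.p_value >= 1 / 100

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, (8, 3)), rng.normal(1, 1, (8, 3))
        r1 = knn_randomization_test(a, b, k=3, n_perm=499, seed=42)
        r2 = knn_randomization_test(a, b, k=3, n_perm=499, seed=42)
        assert r1.p_value == r2.p_value and r1.observed_stat == r2.observed_stat

    def test_degenerate_identical_coordinates_flagged(self):
        x = np.zeros((6, 2))
        res = knn_randomization_test(x[:3], x[3:], k=2, n_perm=99, seed=0)
        assert res.degenerate

    def test_isotope_vectors_use_shared_channels(self):
        a = [IsotopeVector(d13C=-30 + 0.1 * i, d15N=1.0) for i in range(4)]
        b = [IsotopeVector(d13C=-12 + 0.1 * i) for i in range(4)]  # no d15N
        res = knn_randomization_test(a, b, k=2, n_perm=99, seed=0)
        assert res.observed_stat == 1.0  # separated on the only shared channel


def _samples(cat_means, n=5, sd=0.2, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for cat, (c, nn, s) in cat_means.items():
        for i in range(n):
            out.append(SourceSample(
                sample_id=f"{cat}{i}", category=cat, region=Region.EASTERN,
                isotopes=IsotopeVector(d13C=c + rng.normal(0, sd),
                                       d15N=nn + rng.normal(0, sd),
                                       d34S=s + rng.normal(0, sd)),
                pct_C=45.0, pct_N=5.0, pct_S=0.5))
    return out


class TestPairwiseAndPooling:
    def test_bonferroni_five_categories_gives_0_005(self):
        means = {f"c{i}": (-30.0 + 5 * i, 2.0 * i, 3.0 * i) for i in range(5)}
        with pytest.warns(UserWarning, match="n_perm"):
            tests = pairwise_source_tests(_samples(means), k=3, n_perm=99, seed=0)
        assert tests.n_tests == 10
        assert tests.alpha_adjusted == pytest.approx(0.005)

    def test_bonferroni_two_categories_single_comparison(self):
        means = {"a": (-30.0, 0.0, 0.0), "b": (-12.0, 10.0, 10.0)}
        tests = pairwise_source_tests(_samples(means), k=3, n_perm=99, seed=0)
        assert tests.n_tests == 1
        assert tests.alpha_adjusted == pytest.approx(0.05)

    def test_bonferroni_six_categories(self):
        means = {f"c{i}": (-30.0 + 4 * i, 2.0 * i, 3.0 * i) for i in range(6)}
        with pytest.warns(UserWarning, match="n_perm"):
            tests = pairwise_source_tests(_samples(means), k=3, n_perm=99, seed=0)
        assert tests.n_tests == 15
        assert tests.alpha_adjusted == pytest.approx(0.05 / 15)

    def test_small_category_skipped_with_warning(self):
        samples = _samples({"a": (-30.0, 0.0, 0.0), "b": (-12.0, 10.0, 10.0)})
        samples.append(SourceSample(
            sample_id="lone", category="tiny", region=Region.EASTERN,
            isotopes=IsotopeVector(d13C=-20.0), pct_C=45.0))
        with pytest.warns(UserWarning):
            tests = pairwise_source_tests(samples, k=3, n_perm=99, seed=0)
        assert "tiny" in tests.skipped

    def test_all_significant_partition_unchanged(self):
        means = {f"c{i}": (-30.0 + 6 * i, 3.0 * i, 4.0 * i) for i in range(4)}
        samples = _samples(means, n=8)
        tests = pairwise_source_tests(samples, k=3, n_perm=999, seed=1)
        partition, groups = merge_sources(tests, samples)
        assert len(groups) == 4
        assert all(v == k for k, v in partition.mapping.items())

    def test_indistinguishable_pair_pooled(self):
        means = {"herb": (-30.0, 1.0, 2.0), "fruit": (-30.0, 1.0, 2.0),
                 "fish": (-14.0, 15.0, 18.0)}
        samples = _samples(means, n=8, seed=2)
        tests = pairwise_source_tests(samples, k=3, n_perm=999, seed=2)
        partition, groups = merge_sources(tests, samples)
        assert partition.mapping["herb"] == partition.mapping["fruit"] == "fruit+herb"
        assert partition.mapping["fish"] == "fish"
        assert len(groups) == 2

    def test_transitive_closure_pools_chain(self):
        """A~B and B~C non-significant pools {A,B,C} even if A-C differs."""
        from isodiet.grouping import PairwiseSourceTests

        samples = _samples({"A": (-30.0, 0.0, 0.0), "B": (-28.0, 1.0, 1.0),
                            "C": (-26.0, 2.0, 2.0)}, n=4, seed=3)
        fake = PairwiseSourceTests(
            categories=["A", "B", "C"],
            p={("A", "B"): 0.5, ("B", "C"): 0.5, ("A", "C"): 0.001},
            alpha_adjusted=0.05 / 3, family_alpha=0.05, n_tests=3)
        partition, groups = merge_sources(fake, samples)
        assert len(groups) == 1 and groups[0].name == "A+B+C"
        assert ("A", "C") in partition.closure_merged_significant

    def test_pooled_mean_is_sample_weighted_mean(self):
        samples = _samples({"x": (-30.0, 0.0, 0.0)}, n=4, seed=4) + \
            _samples({"y": (-28.0, 1.0, 1.0)}, n=8, seed=5)
        from isodiet.grouping import PairwiseSourceTests
        fake = PairwiseSourceTests(["x", "y"], {("x", "y"): 0.9}, 0.05, 0.05, 1)
        _, groups = merge_sources(fake, samples)
        vals = [s.isotopes.d13C for s in samples]
        assert groups[0].mu["d13C"] == pytest.approx(np.mean(vals))
        assert groups[0].n == 12


class TestTypeIErrorCalibration:
    def test_null_rejection_rate_in_binomial_interval(self):
        """Under label exchange on one generating distribution, rejection at
        α=0.05 stays inside the 95% binomial CI over 500 datasets
        (n=30/group, k=5, 999 permutations; granularity chosen so the
        discrete statistic's tie conservatism is small)."""
        rng = np.random.default_rng(123)
        rejections = 0
        n_datasets = 500
        for _ in range(n_datasets):
            a = rng.normal(0, 1, (30, 2))
            b = rng.normal(0, 1, (30, 2))
            res = knn_randomization_test(a, b, k=5, n_perm=999,
                                         seed=int(rng.integers(2**31)))
            rejections += res.p_value <= 0.05
        rate = rejections / n_datasets
        half = 1.96 * math.sqrt(0.05 * 0.95 / n_datasets)
        assert 0.05 - half <= rate <= 0.05 + half
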