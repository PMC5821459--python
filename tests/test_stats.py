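import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from silacrnp.errors import DomainError, InsufficientDataError
from silacrnp.stats import (
    Dendrogram,
    DistanceMatrix,
    bh_adjust,
    cosine_distance,
    hierarchical_cluster,
    normal_upper_quantile,
    one_sample_t,
    welch_t,
)


class TestNormalUpperQuantile:
    def test_median_is_zero(self):
        assert normal_upper_quantile(0.5) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("alpha,expected", [(0.001, 3.090232), (0.025, 1.959964)])
    def test_against_erf_bisection(self, alpha, expected):
        assert normal_upper_quantile(alpha) == pytest.approx(expected, abs=1e-6)
        assert normal_upper_quantile(alpha) == pytest.approx(
            oracles.norm_upper_quantile(alpha), abs=1e-9
        )

    def test_composition_with_sf_is_identity(self):
        for alpha in np.linspace(0.0005, 0.9995, 41):
            z = normal_upper_quantile(alpha)
            assert oracles.norm_sf(z) == pytest.approx(alpha, abs=1e-6)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 2.0])
    def test_domain(self, alpha):
        with pytest.raises(DomainError):
            normal_upper_quantile(alpha)


class TestOneSampleT:
    def test_worked_example_against_integration_oracle(self):
        res = one_sample_t([0.55, 0.60, 0.65], 0.5)
        assert res.statistic == pytest.approx(3.4641016, abs=1e-6)
        assert res.df == 2
        assert res.p_value == pytest.approx(0.0741799, abs=1e-6)
        assert res.p_value == pytest.approx(
            oracles.two_sided_t_p(res.statistic, res.df), abs=1e-9
        )

    def test_mean_equal_mu0(self):
        res = one_sample_t([0.5, 0.5, 0.6, 0.4], 0.5)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_zero_variance_is_degenerate(self):
        res = one_sample_t([0.6, 0.6], 0.5)
        assert res.degenerate
        assert np.isnan(res.p_value)

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientDataError):
            one_sample_t([0.5], 0.5)


class TestWelchT:
    def test_worked_example_against_integration_oracle(self):
        res = welch_t([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1.2247449, abs=1e-6)
        assert res.df == pytest.approx(4.0, abs=1e-9)
        assert res.p_value == pytest.approx(0.2878641, abs=1e-6)
        assert res.p_value == pytest.approx(
            oracles.two_sided_t_p(res.statistic, res.df), abs=1e-9
        )

    def test_identical_samples(self):
        assert welch_t([1, 2, 3], [1, 2, 3]).p_value == pytest.approx(1.0)

    def test_large_separation(self):
        assert welch_t([0, 0, 0.001], [10, 10, 10.001]).p_value < 1e-6

    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=8),
        st.lists(st.floats(-10, 10), min_size=3, max_size=8),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetry_up_to_sign(self, a, b):
        if np.var(a) == 0 and np.var(b) == 0:
            return
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
        assert r1.statistic == pytest.approx(-r2.statistic, rel=1e-12)

    def test_pooled_variant_df(self):
        res = welch_t([1.0, 2.0, 3.0, 4.0], [2.0, 4.0], equal_var=True)
        assert res.df == 4.0


class TestBHAdjust:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([0.001, 1.0], [0.002, 1.0]),
        ],
    )
    def test_examples_match_brute_force(self, pvals, expected):
        np.testing.assert_allclose(bh_adjust(pvals), expected, atol=1e-12)
        np.testing.assert_allclose(
            bh_adjust(pvals), oracles.bh_brute_force(pvals), atol=1e-12
        )

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            p = rng.random(rng.integers(1, 25))
            np.testing.assert_allclose(
                bh_adjust(p), oracles.bh_brute_force(p), atol=1e-12
            )

    def test_q_at_least_p_and_order_preserving(self):
        rng = np.random.default_rng(7)
        p = rng.random(100)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_domain(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.5])


class TestCosineDistance:
    def test_proportional_vectors(self):
        assert cosine_distance([1, 2, 3], [2, 4, 6]) == 0.0

    def test_orthogonal(self):
        assert cosine_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert cosine_distance([1, 1], [1, 0]) == pytest.approx(
            1 - 1 / np.sqrt(2), abs=1e-12
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(DomainError):
            cosine_distance([0, 0], [1, 1])

    def test_nonnegative_vectors_bounded_by_one(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            u, v = rng.random(5) + 1e-6, rng.random(5) + 1e-6
            assert 0.0 <= cosine_distance(u, v) <= 1.0


def _random_distance_matrix(rng, n):
    pts = rng.random((n, 4))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix([f"P{i}" for i in range(n)], d)


class TestHierarchicalCluster:
    def test_two_points_merge_at_their_distance(self):
        d = DistanceMatrix(["A", "B"], np.array([[0.0, 0.7], [0.7, 0.0]]))
        dendro = hierarchical_cluster(d)
        assert dendro.merge_heights().tolist() == [pytest.approx(0.7)]

    def test_closest_pair_merges_first(self):
        vals = np.array([[0, 1, 10], [1, 0, 9.5], [10, 9.5, 0]], dtype=float)
        dendro = hierarchical_cluster(DistanceMatrix(["A", "B", "C"], vals))
        two = dendro.cut(2)
        assert two["A"] == two["B"] != two["C"]

    def test_average_linkage_matches_naive_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            d = _random_distance_matrix(rng, 6)
            dendro = hierarchical_cluster(d, linkage="average")
            expected = sorted(h for _, _, h in oracles.naive_average_linkage(d.values))
            np.testing.assert_allclose(
                np.sort(dendro.merge_heights()), expected, atol=1e-9
            )

    def test_cut_partitions_labels(self):
        rng = np.random.default_rng(5)
        d = _random_distance_matrix(rng, 12)
        dendro = hierarchical_cluster(d)
        for k in range(2, 6):
            labels = dendro.cut(k)
            assert sorted(labels.index) == sorted(d.labels)
            assert labels.nunique() == k

    def test_missing_pairs_rejected(self):
        d = _random_distance_matrix(np.random.default_rng(1), 4)
        d.mask = np.zeros((4, 4), dtype=bool)
        d.mask[0, 1] = d.mask[1, 0] = True
        with pytest.raises(DomainError, match="missing"):
            hierarchical_cluster(d)

    def test_newick_contains_all_leaves_once(self):
        d = _random_distance_matrix(np.random.default_rng(2), 7)
        nwk = hierarchical_cluster(d).to_newick()
        assert nwk.endswith(";")
        for label in d.labels:
            assert nwk.count(label) == 1

    def test_heights_monotone_for_average_linkage(self):
        d = _random_distance_matrix(np.random.default_rng(9), 15)
        heights = hierarchical_cluster(d).merge_heights()
        assert np.all(np.diff(heights) >= -1e-12)
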