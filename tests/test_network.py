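"""Correlation networks, Fisher Z, and the permutation edge test."""
import numpy as np
import pandas as pd
import pytest

from lesionet import (
    DegenerateDataError,
    InsufficientDataError,
    PermutationEdgeTest,
    classify_edges,
    fisher_z,
    group_correlation,
    permutation_edge_test,
)


def textbook_pearson(x):
    """Independent oracle: textbook sum formula, element by element."""
    n, k = x.shape
    r = np.eye(k)
    for i in range(k):
        for j in range(k):
            xi, xj = x[:, i], x[:, j]
            num = np.sum((xi - xi.mean()) * (xj - xj.mean()))
            den = np.sqrt(np.sum((xi - xi.mean()) ** 2) * np.sum((xj - xj.mean()) ** 2))
            r[i, j] = num / den
    return r


class TestGroupCorrelation:
    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0, 0.5, size=(5, 3))
        corr = group_correlation(pd.DataFrame(x, columns=list("abc")))
        assert np.allclose(corr.r, textbook_pearson(x), atol=1e-12)
        assert np.allclose(corr.r, corr.r.T)
        assert np.allclose(np.diag(corr.r), 1.0)

    def test_perfect_linear_relation(self):
        x = np.column_stack([np.arange(5.0), 2 * np.arange(5.0) + 1, [3, 1, 4, 1, 5]])
        corr = group_correlation(x)
        assert corr.r[0, 1] == pytest.approx(1.0)

    def test_independent_regions_have_small_correlations(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2000, 6))
        corr = group_correlation(x)
        off = corr.r[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.1  # 3 / sqrt(n) bound

    def test_zero_variance_region_is_hard_error(self):
        x = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(DegenerateDataError, match="region_0"):
            group_correlation(x)

    def test_too_few_subjects(self):
        with pytest.raises(InsufficientDataError):
            group_correlation(np.random.default_rng(2).normal(size=(2, 4)))


class TestFisherZ:
    @pytest.mark.parametrize(
        "r, expected",
        [(0.0, 0.0), (0.5, 0.5 * np.log(3.0)), (1.0, np.arctanh(1 - 1e-7))],
    )
    def test_closed_form_values(self, r, expected):
        z = fisher_z(np.array([[1.0, r], [r, 1.0]]))
        assert z[0, 1] == pytest.approx(expected, rel=1e-9)

    def test_sign_monotonicity_and_masked_diagonal(self):
        r = np.linspace(-0.9, 0.9, 7)
        m = np.eye(7)
        m[0, 1:] = m[1:, 0] = r[1:]
        z = fisher_z(m)
        assert np.isnan(z[0, 0])
        assert np.all(np.sign(z[0, 1:]) == np.sign(r[1:]))
        assert np.all(np.diff(z[0, 1:]) > 0)  # monotone in r


def two_group_data(seed, n=12, k=5, shift_edge=None, r=0.8):
    rng = np.random.default_rng(seed)
    cov = np.eye(k)
    xa = rng.multivariate_normal(np.zeros(k), cov, size=n)
    cov_b = cov.copy()
    if shift_edge is not None:
        i, j = shift_edge
        cov_b[i, j] = cov_b[j, i] = r
    xb = rng.multivariate_normal(np.zeros(k), cov_b, size=n)
    return xa, xb


class TestPermutationEdgeTest:
    def test_duplicated_data_gives_all_p_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 4))
        cmp_ = permutation_edge_test(x, x.copy(), n_permutations=200, seed=0)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(cmp_.delta_z[off], 0.0)
        assert np.allclose(cmp_.p[off], 1.0)

    def test_exact_mode_enumerates_all_splits(self):
        xa, xb = two_group_data(4, n=3, k=3)
        cmp_ = permutation_edge_test(xa, xb, mode="exact")
        assert cmp_.mode == "exact"
        assert cmp_.n_used == 19  # C(6,3) - identity

    def test_montecarlo_converges_to_exact(self):
        """Exhaustive enumeration over C(6,3)=20 splits is the oracle."""
        xa, xb = two_group_data(5, n=3, k=4, shift_edge=(0, 1), r=0.9)
        exact = permutation_edge_test(xa, xb, mode="exact")
        mc = permutation_edge_test(
            xa, xb, mode="montecarlo", n_permutations=100_000, seed=1
        )
        off = ~np.eye(4, dtype=bool)
        assert np.abs(exact.p[off] - mc.p[off]).max() < 0.02

    def test_label_swap_negates_dz_and_preserves_p(self):
        xa, xb = two_group_data(6, n=4, k=4, shift_edge=(1, 2), r=0.7)
        ab = permutation_edge_test(xa, xb, mode="exact")
        ba = permutation_edge_test(xb, xa, mode="exact")
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(ab.delta_z[off], -ba.delta_z[off])
        assert np.array_equal(ab.p[off], ba.p[off])

    def test_invariant_to_subject_order(self):
        xa, xb = two_group_data(7, n=8, k=4, shift_edge=(0, 2), r=0.6)
        c1 = permutation_edge_test(xa, xb, n_permutations=500, seed=2)
        c2 = permutation_edge_test(xa[::-1], xb[::-1], n_permutations=500, seed=2)
        assert np.array_equal(np.nan_to_num(c1.p), np.nan_to_num(c2.p))

    def test_fixed_seed_bit_identical(self):
        xa, xb = two_group_data(8, n=10, k=5)
        c1 = permutation_edge_test(xa, xb, n_permutations=300, seed=9)
        c2 = permutation_edge_test(xa, xb, n_permutations=300, seed=9)
        assert np.array_equal(np.nan_to_num(c1.p), np.nan_to_num(c2.p))
        assert np.array_equal(np.nan_to_num(c1.delta_z), np.nan_to_num(c2.delta_z))

    def test_add_one_lower_bound(self):
        xa, xb = two_group_data(9, n=20, k=3, shift_edge=(0, 1), r=0.95)
        cmp_ = permutation_edge_test(xa, xb, n_permutations=100, seed=3)
        off = ~np.eye(3, dtype=bool)
        assert (cmp_.p[off] >= 1 / 101).all()

    def test_monotone_power_in_planted_effect(self):
        """Rejection rate for the planted edge grows with the planted delta-r."""
        rates = []
        for r in (0.0, 0.3, 0.6, 0.9):
            hits = 0
            for seed in range(30):
                xa, xb = two_group_data(100 + seed, n=20, k=4, shift_edge=(0, 1), r=r)
                cmp_ = permutation_edge_test(xa, xb, n_permutations=300, seed=seed)
                hits += cmp_.p[0, 1] < 0.05
            rates.append(hits / 30)
        assert all(b >= a - 0.1 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > rates[0]

    def test_constant_region_inside_replicate_tolerated(self):
        # both groups vary in region 0, but most pooled rows share the value
        # 1.0 there, so many relabelings make it constant in one pseudo-group
        rng = np.random.default_rng(13)
        xa = rng.normal(size=(4, 3))
        xb = rng.normal(size=(4, 3))
        xa[:, 0] = [1.0, 1.0, 1.0, 2.0]
        xb[:, 0] = [1.0, 1.0, 1.0, 3.0]
        with pytest.warns(UserWarning, match="constant region"):
            cmp_ = permutation_edge_test(xa, xb, mode="exact")
        assert np.isfinite(cmp_.p[0, 1])

    def test_sklearn_estimator_surface(self):
        xa, xb = two_group_data(10, n=6, k=3)
        X = np.vstack([xa, xb])
        y = ["ich"] * 6 + ["sham"] * 6
        est = PermutationEdgeTest(n_permutations=200, random_state=0)
        assert est.get_params()["n_permutations"] == 200
        est.set_params(n_permutations=100).fit(X, y)
        assert est.groups_ == ("ich", "sham")
        assert est.p_values_.shape == (3, 3)
        assert est.direction_.shape == (3, 3)
        df = est.comparison_.edges()
        assert list(df.columns) == ["region_a", "region_b", "delta_z", "p", "direction"]
        assert len(df) == 3


class TestClassifyEdges:
    def test_partition_and_ordering(self):
        xa, xb = two_group_data(11, n=25, k=4, shift_edge=(0, 3), r=0.9)
        cmp_ = permutation_edge_test(xa, xb, n_permutations=1000, seed=4)
        increased, decreased = classify_edges(cmp_)
        # group A lacks the planted edge: it must come out decreased
        assert ("region_0", "region_3") in decreased
        for lst in (increased, decreased):
            assert lst == sorted(
                lst, key=lambda p: (cmp_.regions.index(p[0]), cmp_.regions.index(p[1]))
            )

    def test_no_significant_edges_yields_empty_lists(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(6, 3))
        cmp_ = permutation_edge_test(x, x.copy(), n_permutations=100, seed=5)
        assert classify_edges(cmp_) == ([], [])
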