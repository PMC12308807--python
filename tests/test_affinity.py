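"""Feature-space affinity construction against independent brute-force oracles."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptsne import (
    calibrate_bandwidths,
    conditional_affinities,
    joint_affinities,
    row_perplexity,
    squared_pairwise_distances,
    symmetrize,
)


def brute_force_d2(X):
    n, m = X.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = sum((X[i, k] - X[j, k]) ** 2 for k in range(m))
    return out


def brute_force_conditional(d2, sigma):
    """Direct evaluation of the Gaussian conditional formula, no shortcuts."""
    n = d2.shape[0]
    p = np.zeros((n, n))
    for i in range(n):
        denom = sum(
            math.exp(-d2[i, k] / (2 * sigma[i] ** 2)) for k in range(n) if k != i
        )
        for j in range(n):
            if j != i:
                p[i, j] = math.exp(-d2[i, j] / (2 * sigma[i] ** 2)) / denom
    return p


class TestSquaredDistances:
    def test_one_dimensional_hand_case(self):
        np.testing.assert_allclose(
            squared_pairwise_distances([[0.0], [3.0]]), [[0, 9], [9, 0]]
        )

    def test_identical_rows_have_zero_distance(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]])
        d2 = squared_pairwise_distances(X)
        assert d2[0, 1] == 0.0 and d2[1, 0] == 0.0

    def test_matches_brute_force(self, rng):
        X = rng.normal(size=(5, 3))
        np.testing.assert_allclose(
            squared_pairwise_distances(X), brute_force_d2(X), atol=1e-12
        )

    def test_symmetric_zero_diagonal(self, rng):
        d2 = squared_pairwise_distances(rng.normal(size=(7, 4)))
        assert np.array_equal(d2, d2.T)
        assert np.all(np.diag(d2) == 0)
        assert np.all(d2 >= 0)

    def test_rejects_nonfinite_with_row_diagnostic(self):
        X = np.ones((3, 2))
        X[1, 0] = np.nan
        with pytest.raises(ValueError, match="row 1"):
            squared_pairwise_distances(X)


class TestConditionalAffinities:
    def test_two_samples_single_neighbor(self):
        d2 = squared_pairwise_distances([[0.0], [5.0]])
        p = conditional_affinities(d2, [0.3, 7.0])
        np.testing.assert_allclose(p, [[0, 1], [1, 0]])

    def test_equidistant_triple_gives_half(self):
        # equilateral triangle: every neighbor equally likely
        X = np.array([[0, 0], [1, 0], [0.5, math.sqrt(3) / 2]])
        p = conditional_affinities(squared_pairwise_distances(X), [0.7, 0.7, 0.7])
        off = p[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.5, atol=1e-12)

    def test_matches_direct_formula_evaluation(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [3.0, 1.0]])
        sigma = np.ones(4)
        d2 = squared_pairwise_distances(X)
        np.testing.assert_allclose(
            conditional_affinities(d2, sigma),
            brute_force_conditional(d2, sigma),
            atol=1e-12,
        )

    def test_underflow_row_falls_back_to_uniform(self):
        # infinite distances: every off-diagonal exponential is zero
        d2 = np.full((3, 3), np.inf)
        np.fill_diagonal(d2, 0.0)
        with pytest.warns(RuntimeWarning, match="underflow"):
            p = conditional_affinities(d2, [1e-3, 1e-3, 1e-3])
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(p[0, 1:], 0.5)

    def test_rejects_nonpositive_sigma(self):
        d2 = squared_pairwise_distances([[0.0], [1.0]])
        with pytest.raises(ValueError, match="positive"):
            conditional_affinities(d2, [1.0, 0.0])


class TestRowPerplexity:
    def test_uniform_row_gives_neighbor_count(self):
        row = np.array([0.0, 0.25, 0.25, 0.25, 0.25])
        assert row_perplexity(row) == pytest.approx(4.0, abs=1e-12)

    def test_deterministic_row_gives_one(self):
        assert row_perplexity(np.array([0.0, 1.0, 0.0])) == pytest.approx(1.0)

    def test_direct_entropy_case(self):
        # H = 1.5 bits -> perplexity 2^1.5
        assert row_perplexity(np.array([0.5, 0.25, 0.25])) == pytest.approx(
            2**1.5, rel=1e-9
        )


class TestCalibration:
    def test_gaussian_data_hits_target(self, rng):
        d2 = squared_pairwise_distances(rng.normal(size=(10, 3)))
        sigma = calibrate_bandwidths(d2, 5.0, tol=1e-5)
        perp = row_perplexity(conditional_affinities(d2, sigma))
        np.testing.assert_allclose(perp, 5.0, atol=1e-5)

    def test_equidistant_rows_converge_immediately(self):
        X = np.array([[0, 0], [1, 0], [0.5, math.sqrt(3) / 2]])
        d2 = squared_pairwise_distances(X)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            sigma = calibrate_bandwidths(d2, 2.0)
        perp = row_perplexity(conditional_affinities(d2, sigma))
        np.testing.assert_allclose(perp, 2.0, atol=1e-9)

    def test_entropy_monotone_in_sigma(self, rng):
        d2 = squared_pairwise_distances(rng.normal(size=(8, 3)))
        for sgrid in [np.logspace(-2, 2, 40)]:
            perps = [
                row_perplexity(conditional_affinities(d2, np.full(8, s)), 0)
                for s in sgrid
            ]
            assert np.all(np.diff(perps) >= -1e-10)

    def test_rejects_perplexity_at_or_above_n(self, rng):
        d2 = squared_pairwise_distances(rng.normal(size=(6, 2)))
        with pytest.raises(ValueError, match="perplexity"):
            calibrate_bandwidths(d2, 6.0)

    def test_degenerate_unattainable_target_warns(self):
        X = np.array([[0, 0], [1, 0], [0.5, math.sqrt(3) / 2]])
        d2 = squared_pairwise_distances(X)
        with pytest.warns(RuntimeWarning, match="all-equal"):
            calibrate_bandwidths(d2, 1.5)


class TestSymmetrize:
    def test_two_samples_forced_half(self):
        p = symmetrize(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_allclose(p, [[0.0, 0.5], [0.5, 0.0]])

    def test_matches_direct_construction(self, rng):
        d2 = squared_pairwise_distances(rng.normal(size=(6, 3)))
        C = conditional_affinities(d2, np.full(6, 0.8))
        np.testing.assert_allclose(symmetrize(C), (C + C.T) / 12.0, atol=1e-15)

    def test_total_mass_one(self, rng):
        d2 = squared_pairwise_distances(rng.normal(size=(9, 2)))
        C = conditional_affinities(d2, calibrate_bandwidths(d2, 4.0))
        P = symmetrize(C)
        assert abs(P.sum() - 1.0) <= 1e-9
        assert np.abs(P - P.T).max() == 0.0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n=st.integers(min_value=3, max_value=8),
    m=st.integers(min_value=1, max_value=4),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_affinity_invariants_hold_on_random_data(n, m, seed):
    """Rows of the conditional matrix sum to 1; P is symmetric with mass 1."""
    X = np.random.default_rng(seed).normal(size=(n, m))
    P_cond = conditional_affinities(
        squared_pairwise_distances(X), np.full(n, 0.5)
    )
    np.testing.assert_allclose(P_cond.sum(axis=1), 1.0, atol=1e-9)
    assert np.all((P_cond >= 0) & (P_cond <= 1))
    assert np.all(np.diag(P_cond) == 0)
    P = symmetrize(P_cond)
    assert abs(P.sum() - 1.0) <= 1e-9


def test_full_pipeline_reproduces_target_perplexity(rng):
    X = rng.normal(size=(40, 5))
    P = joint_affinities(X, perplexity=12.0)
    assert abs(P.sum() - 1.0) <= 1e-9
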