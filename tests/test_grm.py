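"""Graded response model simulator: probabilities, DIF injection, sampling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from difnet.grm import (
    DIFSpec,
    ItemBank,
    apply_uniform_dif,
    grm_category_probs,
    grm_cumulative_prob,
    sample_item_bank,
    simulate_responses,
)

ordered_thresholds = (
    st.lists(st.floats(-3, 3), min_size=1, max_size=6, unique=True)
    .map(sorted)
    .map(np.asarray)
    # keep gaps large enough that adding a shift cannot tie them in float64
    .filter(lambda b: b.size == 1 or np.min(np.diff(b)) > 1e-6)
)


class TestItemBank:
    def test_sampled_bank_is_valid_grm(self):
        bank = sample_item_bank(5, 5, seed=7)
        assert bank.n_items == 5 and bank.n_categories == 5
        assert np.all((bank.discriminations > 1) & (bank.discriminations < 2))
        assert bank.thresholds.shape == (5, 4)
        assert np.all(np.diff(bank.thresholds, axis=1) > 0)

    def test_seed_determinism(self):
        b1 = sample_item_bank(4, 5, seed=42)
        b2 = sample_item_bank(4, 5, seed=42)
        np.testing.assert_array_equal(b1.discriminations, b2.discriminations)
        np.testing.assert_array_equal(b1.thresholds, b2.thresholds)

    def test_minimal_bank(self):
        bank = sample_item_bank(1, 2, seed=1)
        assert bank.thresholds.shape == (1, 1)

    @pytest.mark.parametrize("n_items,n_cat", [(0, 5), (3, 1), (-1, 5)])
    def test_invalid_sizes_rejected(self, n_items, n_cat):
        with pytest.raises(ValueError):
            sample_item_bank(n_items, n_cat, seed=0)

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ItemBank(np.array([1.0]), np.array([[0.5, -0.5]]))

    def test_nonpositive_discrimination_rejected(self):
        with pytest.raises(ValueError):
            ItemBank(np.array([0.0]), np.array([[-1.0, 1.0]]))


class TestUniformDIF:
    def test_threshold_shift_arithmetic(self):
        bank = ItemBank(np.array([1.2, 1.5]),
                        np.array([[-1.0, 0.0, 1.0, 2.0], [-0.5, 0.0, 0.5, 1.0]]))
        focal = apply_uniform_dif(bank, DIFSpec(1, 0.4))
        np.testing.assert_allclose(focal.thresholds[0], [-0.6, 0.4, 1.4, 2.4])
        # locality: other items untouched, input bank unmodified
        np.testing.assert_array_equal(focal.thresholds[1], bank.thresholds[1])
        np.testing.assert_allclose(bank.thresholds[0], [-1.0, 0.0, 1.0, 2.0])

    def test_zero_magnitude_is_identity(self):
        bank = sample_item_bank(3, 4, seed=3)
        focal = apply_uniform_dif(bank, DIFSpec(2, 0.0))
        np.testing.assert_array_equal(focal.thresholds, bank.thresholds)

    def test_out_of_range_item(self):
        bank = sample_item_bank(2, 3, seed=0)
        with pytest.raises(IndexError):
            apply_uniform_dif(bank, DIFSpec(3, 0.4))


class TestProbabilities:
    @pytest.mark.parametrize("a,theta,b,expected", [
        (1.0, 0.0, 0.0, 0.5),
        (2.0, 1.0, 0.0, 1 / (1 + np.exp(-2.0))),  # 0.880797...
        (1.5, 60.0, 0.0, 1.0),  # saturation limit
    ])
    def test_cumulative_prob_values(self, a, theta, b, expected):
        assert grm_cumulative_prob(a, theta, b) == pytest.approx(expected, abs=1e-9)

    def test_category_probs_frozen_example(self):
        probs = grm_category_probs(1.0, 0.0, np.array([-1.0, 0.0, 1.0, 2.0]))
        np.testing.assert_allclose(
            probs, [0.26894, 0.23106, 0.23106, 0.14974, 0.11920], atol=5e-6
        )

    @given(a=st.floats(0.5, 3), theta=st.floats(-4, 4), b=ordered_thresholds)
    def test_category_probs_form_a_simplex(self, a, theta, b):
        probs = grm_category_probs(a, theta, b)
        assert probs.shape == (len(b) + 1,)
        assert np.all(probs >= -1e-12)
        assert np.sum(probs) == pytest.approx(1.0, abs=1e-9)

    @given(a=st.floats(0.5, 3), theta=st.floats(-3, 3), delta=st.floats(-2, 2),
           b=ordered_thresholds)
    def test_threshold_shift_equals_trait_shift(self, a, theta, delta, b):
        lhs = grm_category_probs(a, theta, b + delta)
        rhs = grm_category_probs(a, theta - delta, b)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_extreme_trait_limit(self):
        probs = grm_category_probs(1.0, -60.0, np.array([-1.0, 0.0, 1.0]))
        np.testing.assert_allclose(probs, [1, 0, 0, 0], atol=1e-12)

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            grm_category_probs(1.0, 0.0, np.array([1.0, -1.0]))


class TestSimulateResponses:
    def test_shapes_groups_and_range(self):
        bank = sample_item_bank(5, 5, seed=1)
        ds = simulate_responses(bank, bank, 50, 50, seed=3)
        assert ds.responses.shape == (100, 5)
        assert set(np.unique(ds.responses)) <= set(range(1, 6))
        assert ds.n_ref == 50 and ds.n_focal == 50
        assert ds.theta_true.shape == (100,)

    def test_seed_determinism(self):
        bank = sample_item_bank(3, 5, seed=1)
        d1 = simulate_responses(bank, bank, 30, 20, seed=9)
        d2 = simulate_responses(bank, bank, 30, 20, seed=9)
        np.testing.assert_array_equal(d1.responses, d2.responses)
        np.testing.assert_array_equal(d1.group, d2.group)

    def test_mismatched_banks_rejected(self):
        b1 = sample_item_bank(3, 5, seed=0)
        b2 = sample_item_bank(4, 5, seed=0)
        with pytest.raises(ValueError):
            simulate_responses(b1, b2, 10, 10, seed=1)

    def test_saturated_thresholds_pin_the_category(self):
        # thresholds at +-50 make one category near-certain
        bank = ItemBank(np.array([1.0]), np.array([[-50.0, 50.0]]))
        ds = simulate_responses(bank, bank, 500, 500, seed=4)
        assert np.all(ds.responses == 2)

    def test_empirical_frequencies_match_marginal_probabilities(self):
        # one item, many persons: empirical category frequencies vs the
        # theta-integrated category probabilities (Gauss-Hermite quadrature)
        bank = ItemBank(np.array([1.4]), np.array([[-0.8, 0.1, 0.9, 1.7]]))
        n = 100_000
        ds = simulate_responses(bank, bank, n // 2, n // 2, seed=11)
        freqs = np.bincount(ds.responses[:, 0], minlength=6)[1:] / n
        nodes, weights = np.polynomial.hermite_e.hermegauss(61)
        probs = grm_category_probs(1.4, nodes, bank.thresholds[0])
        marginal = (weights[:, None] * probs).sum(axis=0) / np.sum(weights)
        se = np.sqrt(marginal * (1 - marginal) / n)
        assert np.all(np.abs(freqs - marginal) < 3 * se + 1e-4)

    def test_no_dif_means_identical_banks(self):
        bank = sample_item_bank(2, 4, seed=5)
        focal = apply_uniform_dif(bank, DIFSpec(1, 0.0))
        np.testing.assert_array_equal(bank.thresholds, focal.thresholds)
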