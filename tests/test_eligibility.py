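import numpy as np
import pytest

from lscat import (
    PartialResponse,
    ULCMParams,
    class_posterior,
    eligibility_probability,
    eligibility_probability_by_enumeration,
    remaining_sum_distribution,
)

from .conftest import random_state_and_cutoff, random_ulcm


class TestPartialResponse:
    def test_answered_and_remaining_partition_the_bank(self):
        st = PartialResponse.empty(5).answer(3, 2).answer(0, 1)
        assert st.remaining == (1, 2, 4)
        assert st.observed_sum == 3
        assert st.n_answered == 2

    def test_double_answer_rejected(self):
        with pytest.raises(ValueError):
            PartialResponse.empty(3).answer(1, 0).answer(1, 2)


class TestClassPosterior:
    def test_prior_when_nothing_answered(self, phq9_params):
        post = class_posterior(phq9_params, PartialResponse.empty(9))
        np.testing.assert_allclose(post, phq9_params.class_weights)

    def test_single_class_always_certain(self, tiny_binary_model):
        st = PartialResponse.empty(2).answer(0, 1)
        np.testing.assert_allclose(class_posterior(tiny_binary_model, st), [1.0])

    def test_hand_bayes_two_classes(self):
        params = ULCMParams(
            np.array([0.5, 0.5]),
            (np.array([[0.2, 0.8], [0.8, 0.2]]), np.array([[0.5, 0.5], [0.5, 0.5]])),
        )
        post = class_posterior(params, PartialResponse.empty(2).answer(0, 1))
        np.testing.assert_allclose(post, [0.8, 0.2], atol=1e-12)

    def test_zero_probability_cell_raises(self):
        params = ULCMParams(
            np.array([1.0]), (np.array([[1.0, 0.0]]), np.array([[0.5, 0.5]]))
        )
        with pytest.raises(ValueError, match="item 0"):
            class_posterior(params, PartialResponse.empty(2).answer(0, 1))


class TestRemainingSumDistribution:
    def test_empty_set_is_point_mass_at_zero(self, phq9_params):
        d = remaining_sum_distribution(phq9_params, (), 0)
        np.testing.assert_allclose(d.mass, [1.0])

    def test_two_fair_binary_items_hand_convolution(self, tiny_binary_model):
        d = remaining_sum_distribution(tiny_binary_model, (0, 1), 0)
        np.testing.assert_allclose(d.mass, [0.25, 0.5, 0.25], atol=1e-15)

    def test_matches_exhaustive_enumeration(self):
        import itertools

        rng = np.random.default_rng(3)
        params = random_ulcm(rng, n_classes=2, n_items=4, max_categories=3)
        for k in range(2):
            d = remaining_sum_distribution(params, (0, 1, 2, 3), k)
            exact = np.zeros(params.max_sum + 1)
            for combo in itertools.product(*[range(m) for m in params.categories]):
                p = np.prod([params.conditionals[j][k, x] for j, x in enumerate(combo)])
                exact[sum(combo)] += p
            np.testing.assert_allclose(d.mass, exact[: d.mass.size], atol=1e-12)


class TestEligibilityProbability:
    def test_observed_sum_at_cutoff_is_exactly_one(self, phq9_params):
        st = PartialResponse.empty(9).answer(0, 3).answer(1, 2)
        assert eligibility_probability(phq9_params, st, 5) == 1.0

    def test_unreachable_cutoff_is_exactly_zero(self, phq9_params):
        st = PartialResponse.empty(9)
        for j in range(8):
            st = st.answer(j, 0)
        # one item left, max score 3 < cutoff 5
        assert eligibility_probability(phq9_params, st, 5) == 0.0

    def test_two_fair_binary_items_hand_enumeration(self, tiny_binary_model):
        q = eligibility_probability(tiny_binary_model, PartialResponse.empty(2), 1)
        assert q == pytest.approx(0.75, abs=1e-12)

    def test_monotone_nonincreasing_in_cutoff(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            params = random_ulcm(rng)
            state, _ = random_state_and_cutoff(rng, params)
            qs = [
                eligibility_probability(params, state, t)
                for t in range(1, params.max_sum + 1)
            ]
            assert all(a >= b - 1e-12 for a, b in zip(qs, qs[1:]))


class TestEnumerationOracle:
    def test_equivalence_on_random_suite(self):
        """Convolution route == literal pattern-zeroing route, 100 random triples."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            params = random_ulcm(rng)
            state, cutoff = random_state_and_cutoff(rng, params)
            a = eligibility_probability(params, state, cutoff)
            b = eligibility_probability_by_enumeration(params, state, cutoff)
            assert a == pytest.approx(b, abs=1e-10)

    def test_cutoff_above_bank_maximum(self):
        params = ULCMParams(np.array([1.0]), (np.array([[0.5, 0.5]]),) * 2)
        st = PartialResponse.empty(2)
        assert eligibility_probability_by_enumeration(params, st, 3) == 0.0

    def test_fully_answered_state_is_indicator(self, phq9_params):
        st = PartialResponse.empty(9)
        for j in range(9):
            st = st.answer(j, 1)
        assert eligibility_probability_by_enumeration(phq9_params, st, 5) == 1.0
        assert eligibility_probability_by_enumeration(phq9_params, st, 10) == 0.0

    def test_oversized_bank_refused(self):
        params = ULCMParams(
            np.array([1.0]), tuple(np.array([[0.25] * 4]) for _ in range(12))
        )
        with pytest.raises(ValueError, match="enumeration limit"):
            eligibility_probability_by_enumeration(
                params, PartialResponse.empty(12), 5
            )


class TestMartingale:
    def test_expected_updated_probability_equals_current(self):
        """E over the next response of the updated eligibility probability
        equals the current one (law of total probability)."""
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 40:
            params = random_ulcm(rng)
            state, cutoff = random_state_and_cutoff(rng, params)
            if not state.remaining:
                continue
            q = eligibility_probability(params, state, cutoff)
            j = int(state.remaining[0])
            post = class_posterior(params, state)
            expect = 0.0
            for x in range(params.categories[j]):
                px = float(post @ params.conditionals[j][:, x])
                if px > 0:
                    expect += px * eligibility_probability(
                        params, state.answer(j, x), cutoff
                    )
            assert expect == pytest.approx(q, abs=1e-10)
            checked += 1
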