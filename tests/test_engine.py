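import numpy as np
import pytest

from lscat import (
    PartialResponse,
    ScreeningConfig,
    ULCMParams,
    administer,
    administer_all,
    eligibility_probability_by_enumeration,
    select_next_item,
)
from lscat.synthdata import GeneratorSpec, generate

from .conftest import random_ulcm


@pytest.fixture()
def toy_three_item_model() -> ULCMParams:
    """Two classes; item 0 is identical across classes, items 1-2 discriminate."""
    flat = np.array([[0.5, 0.5], [0.5, 0.5]])
    disc = np.array([[0.9, 0.1], [0.1, 0.9]])
    return ULCMParams(np.array([0.5, 0.5]), (flat, disc.copy(), disc.copy()))


@pytest.fixture()
def toy_dead_item_model() -> ULCMParams:
    """Item 0 is class-identical *and* always scores 0 (cannot move the sum)."""
    dead = np.array([[1.0, 0.0], [1.0, 0.0]])
    disc = np.array([[0.9, 0.1], [0.1, 0.9]])
    return ULCMParams(np.array([0.5, 0.5]), (dead, disc.copy(), disc.copy()))


class TestSelectNextItem:
    def test_forced_choice_with_one_remaining(self, phq9_params):
        st = PartialResponse.empty(9)
        for j in range(8):
            st = st.answer(j, 1)
        assert select_next_item(phq9_params, st, 10) == 8

    def test_uninformative_item_never_preferred(self, toy_dead_item_model):
        """An item with class-identical conditionals whose score cannot change
        the reach-cutoff outcome loses to items that can, at every state
        where the decision is still open."""
        m = toy_dead_item_model
        assert select_next_item(m, PartialResponse.empty(3), 2) in (1, 2)
        # after a positive answer on item 1 the decision hinges on item 2 alone
        st2 = PartialResponse.empty(3).answer(1, 1)
        assert select_next_item(m, st2, 2) == 2

    def test_tie_breaks_to_lowest_index(self):
        # two exchangeable items: identical conditionals -> exact tie
        rho = np.array([[0.7, 0.3], [0.2, 0.8]])
        m = ULCMParams(np.array([0.5, 0.5]), (rho.copy(), rho.copy()))
        assert select_next_item(m, PartialResponse.empty(2), 1) == 0

    def test_fixed_strategy_follows_order(self, phq9_params):
        st = PartialResponse.empty(9).answer(0, 1)
        assert select_next_item(phq9_params, st, 5, strategy="fixed") == 1
        assert (
            select_next_item(phq9_params, st, 5, strategy="fixed", order=[8, 0, 3])
            == 8
        )


class TestAdminister:
    def test_certainty_only_stopping_never_errs(self, phq9_params):
        data, _ = generate(GeneratorSpec(phq9_params, 300, seed=5))
        cfg = ScreeningConfig(5, 1.0)
        for i, row in enumerate(data.scores):
            rec = administer(phq9_params, row, cfg, respondent=i)
            assert rec.predicted_status == (row.sum() >= 5)
            assert rec.final_probability in (0.0, 1.0)

    def test_barely_above_half_stops_after_first_item(self, toy_three_item_model):
        cfg = ScreeningConfig(2, 0.5 + 1e-9)
        for row in np.ndindex(2, 2, 2):
            rec = administer(toy_three_item_model, np.array(row), cfg)
            assert rec.n_items == 1

    def test_first_item_curtailment(self, phq9_params):
        cfg = ScreeningConfig(3, 0.95)
        row = np.array([3, 3, 3, 0, 0, 0, 0, 0, 0])
        rec = administer(phq9_params, row, cfg)
        # whichever item is asked first, a score of 3 meets the cutoff
        if rec.responses[0] == 3:
            assert rec.n_items == 1 and rec.predicted_status

    def test_at_least_one_item_always_administered(self, phq9_params):
        # cutoff 1: prior P(sum >= 1) is far above .55, yet one item must be asked
        cfg = ScreeningConfig(1, 0.55)
        rec = administer(phq9_params, np.zeros(9, dtype=int), cfg)
        assert rec.n_items >= 1

    def test_early_stop_value_matches_enumeration_oracle(self):
        rng = np.random.default_rng(77)
        params = random_ulcm(rng, n_classes=3, n_items=5)
        cutoff = max(1, params.max_sum // 2)
        cfg = ScreeningConfig(cutoff, 0.9)
        for _ in range(20):
            row = np.array([rng.integers(0, m) for m in params.categories])
            rec = administer(params, row, cfg)
            if rec.stopped_early:
                st = PartialResponse(params.n_items,
                                     tuple(zip(rec.item_sequence, rec.responses)))
                oracle = eligibility_probability_by_enumeration(params, st, cutoff)
                assert rec.final_probability == pytest.approx(oracle, abs=1e-10)


class TestAdministerAll:
    def test_identical_respondents_have_zero_sd(self, phq9_params):
        rows = np.tile(np.array([1, 0, 1, 0, 1, 0, 1, 0, 1]), (20, 1))
        from lscat import ResponseMatrix

        data = ResponseMatrix(rows, (4,) * 9)
        records, eff = administer_all(phq9_params, data, ScreeningConfig(5, 0.95))
        assert eff.sd == 0.0
        assert len({r.n_items for r in records}) == 1

    def test_certainty_stopping_needs_two_items_when_one_cannot_decide(
        self, toy_three_item_model
    ):
        from lscat import ResponseMatrix

        rows = np.array(list(np.ndindex(2, 2, 2)))
        data = ResponseMatrix(rows, (2, 2, 2))
        # cutoff 2 of max 3: no single binary item can settle sum >= 2
        _, eff = administer_all(toy_three_item_model, data, ScreeningConfig(2, 1.0))
        assert eff.min >= 2

    def test_average_items_nondecreasing_in_criterion(self, phq9_params, phq9_data_small):
        effs = [
            administer_all(phq9_params, phq9_data_small, ScreeningConfig(5, c))[1].mean
            for c in (0.95, 0.99)
        ]
        assert effs[1] >= effs[0]

    def test_cached_and_uncached_administration_agree(self, phq9_params, phq9_data_small):
        cfg = ScreeningConfig(5, 0.95)
        cached, _ = administer_all(phq9_params, phq9_data_small.subset(np.arange(50)), cfg)
        for i, rec in enumerate(cached):
            direct = administer(phq9_params, phq9_data_small.scores[i], cfg, respondent=i)
            assert rec == direct
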