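"""Adaptive administration under the latent class engine (LSCAT).

Items are presented one at a time.  After each response the eligibility
probability q = P(final sum >= cutoff | responses) is updated; the test
halts once q >= c ('eligible') or q <= 1 - c ('not eligible'), where c is
the stopping criterion.  If all items are used without triggering, the
decision falls back to the observed sum versus the cutoff.

Item selection is dynamic.  The default rule picks the item minimizing
the expected posterior uncertainty of the eligibility indicator,
E[min(q', 1 - q')], the expectation taken over the candidate item's
predictive response distribution — i.e. the item expected to push q
closest to certainty.  A fixed-order rule (which reduces LSCAT to a
curtailment-like scheme) and a random rule are provided for ablation.

Administration is post-hoc: responses are looked up in a complete
observed response row, never elicited.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .eligibility import (
    PartialResponse,
    class_posterior,
    eligibility_probability,
)
from .io import ResponseMatrix, ScreeningConfig
from .ulcm import ULCMParams

__all__ = [
    "AdministrationRecord",
    "EfficiencySummary",
    "select_next_item",
    "administer",
    "administer_all",
    "LSCATAdministrator",
]

Strategy = Literal["uncertainty", "fixed", "random"]


@dataclass(frozen=True)
class AdministrationRecord:
    """Per-respondent trace of one adaptive administration."""

    respondent: int
    item_sequence: tuple[int, ...]
    responses: tuple[int, ...]
    final_probability: float
    predicted_status: bool
    stopped_early: bool

    @property
    def n_items(self) -> int:
        return len(set(self.item_sequence))


@dataclass(frozen=True)
class EfficiencySummary:
    """Mean, SD and range of the number of administered items."""

    mean: float
    sd: float
    min: int
    max: int

    @classmethod
    def from_records(cls, records: Sequence[AdministrationRecord]) -> "EfficiencySummary":
        n = np.array([r.n_items for r in records])
        sd = float(n.std(ddof=1)) if n.size > 1 else 0.0
        return cls(float(n.mean()), sd, int(n.min()), int(n.max()))


def _loo_tails(
    params: ULCMParams, remaining: tuple[int, ...], needed: int
) -> np.ndarray:
    """tails[k, idx, x] = P(sum over remaining minus item idx >= needed - x | k).

    Computed per class by prefix/suffix convolutions over the remaining
    items, so each leave-one-out sum distribution is exact.
    """
    K = params.n_classes
    r = len(remaining)
    m_max = max(params.categories[j] for j in remaining)
    tails = np.zeros((K, r, m_max))
    for k in range(K):
        masses = [params.conditionals[j][k] for j in remaining]
        prefix = [np.array([1.0])]
        for m in masses:
            prefix.append(np.convolve(prefix[-1], m))
        suffix = [np.array([1.0])]
        for m in reversed(masses):
            suffix.append(np.convolve(suffix[-1], m))
        suffix.reverse()
        for idx, j in enumerate(remaining):
            loo = np.convolve(prefix[idx], suffix[idx + 1])
            csum = np.concatenate([np.cumsum(loo[::-1])[::-1], [0.0]])
            for x in range(params.categories[j]):
                t = needed - x
                tails[k, idx, x] = 1.0 if t <= 0 else (
                    csum[t] if t < loo.size else 0.0
                )
    return tails


def select_next_item(
    params: ULCMParams,
    state: PartialResponse,
    cutoff: int,
    strategy: Strategy = "uncertainty",
    order: Sequence[int] | None = None,
    rng: np.random.Generator | None = None,
) -> int:
    """Choose the next item to administer from the remaining bank.

    ``uncertainty`` (default): minimize the expected posterior uncertainty
    of the eligibility indicator; ties break toward the lowest item index.
    ``fixed``: first remaining item of ``order`` (questionnaire order when
    omitted).  ``random``: uniform over remaining items.
    """
    if not state.remaining:
        raise ValueError("no items remain")
    if strategy == "fixed":
        seq = order if order is not None else range(state.n_items)
        rem = set(state.remaining)
        for j in seq:
            if j in rem:
                return int(j)
        raise ValueError("order does not cover the remaining items")
    if strategy == "random":
        rng = rng or np.random.default_rng()
        return int(rng.choice(state.remaining))
    if strategy != "uncertainty":
        raise ValueError(f"unknown strategy {strategy!r}")

    needed = int(cutoff) - state.observed_sum
    post = class_posterior(params, state)
    tails = _loo_tails(params, state.remaining, needed)
    best_j = -1
    best_crit = np.inf
    for idx, j in enumerate(state.remaining):
        m = params.categories[j]
        rho = params.conditionals[j][:, :m]  # K x m
        joint = post[:, None] * rho  # P(k, x | state)
        px = joint.sum(axis=0)
        num = (joint * tails[:, idx, :m]).sum(axis=0)  # P(x) * q(x)
        crit = 0.0
        for x in range(m):
            if px[x] > 0.0:
                q = num[x] / px[x]
                crit += px[x] * min(q, 1.0 - q)
        if crit < best_crit - 1e-12:
            best_crit = crit
            best_j = j
    return int(best_j)


def administer(
    params: ULCMParams,
    respondent_row: np.ndarray,
    config: ScreeningConfig,
    strategy: Strategy = "uncertainty",
    order: Sequence[int] | None = None,
    rng: np.random.Generator | None = None,
    respondent: int = 0,
) -> AdministrationRecord:
    """Run one post-hoc adaptive administration against a complete row.

    At least one item is always administered, even if the prior alone
    would already pass the criterion.  With c = 1.0 the comparison
    q >= c (q <= 1 - c) can only trigger on exact probabilities 1 (0),
    i.e. deterministic curtailment, so the prediction cannot err.
    """
    row = np.asarray(respondent_row, dtype=np.int64).ravel()
    if row.size != params.n_items:
        raise ValueError("respondent row length mismatch")
    c = config.stopping_criterion
    cutoff = config.cutoff
    state = PartialResponse.empty(params.n_items)
    q = np.nan
    while state.remaining:
        j = select_next_item(params, state, cutoff, strategy, order, rng)
        state = state.answer(j, int(row[j]))
        q = eligibility_probability(params, state, cutoff)
        if q >= c:
            return _record(respondent, state, q, True, not state.is_complete())
        if q <= 1.0 - c:
            return _record(respondent, state, q, False, not state.is_complete())
    # all items used: decide by the observed sum (q is exactly 0 or 1 here)
    return _record(respondent, state, q, state.observed_sum >= cutoff, False)


def _record(
    respondent: int, state: PartialResponse, q: float, status: bool, early: bool
) -> AdministrationRecord:
    items, scores = zip(*state.answered)
    return AdministrationRecord(respondent, items, scores, float(q), status, early)


class LSCATAdministrator:
    """Administers a whole sample, caching decisions shared across respondents.

    For deterministic strategies the next-item choice and the updated
    eligibility probability depend only on the set of (item, score) pairs
    observed so far, so respondents with a common prefix share all the
    work.  On survey-scale samples this collapses the cost to the number
    of distinct partial patterns actually visited.
    """

    def __init__(
        self,
        params: ULCMParams,
        config: ScreeningConfig,
        strategy: Strategy = "uncertainty",
        order: Sequence[int] | None = None,
    ):
        if strategy == "random":
            raise ValueError("caching administrator requires a deterministic strategy")
        self.params = params
        self.config = config
        self.strategy = strategy
        self.order = order
        self._select_cache: dict[tuple, int] = {}
        self._prob_cache: dict[tuple, float] = {}

    def _select(self, state: PartialResponse) -> int:
        key = tuple(sorted(state.answered))
        j = self._select_cache.get(key)
        if j is None:
            j = select_next_item(
                self.params, state, self.config.cutoff, self.strategy, self.order
            )
            self._select_cache[key] = j
        return j

    def _prob(self, state: PartialResponse) -> float:
        key = tuple(sorted(state.answered))
        q = self._prob_cache.get(key)
        if q is None:
            q = eligibility_probability(self.params, state, self.config.cutoff)
            self._prob_cache[key] = q
        return q

    def administer_one(self, row: np.ndarray, respondent: int = 0) -> AdministrationRecord:
        c = self.config.stopping_criterion
        cutoff = self.config.cutoff
        state = PartialResponse.empty(self.params.n_items)
        q = np.nan
        while state.remaining:
            j = self._select(state)
            state = state.answer(j, int(row[j]))
            q = self._prob(state)
            if q >= c:
                return _record(respondent, state, q, True, not state.is_complete())
            if q <= 1.0 - c:
                return _record(respondent, state, q, False, not state.is_complete())
        return _record(respondent, state, q, state.observed_sum >= cutoff, False)


def administer_all(
    params: ULCMParams,
    data: ResponseMatrix,
    config: ScreeningConfig,
    strategy: Strategy = "uncertainty",
    order: Sequence[int] | None = None,
) -> tuple[list[AdministrationRecord], EfficiencySummary]:
    """Post-hoc administration of every respondent; returns traces + efficiency."""
    params.check_data(data)
    config.validate_for(data)
    if strategy == "random":
        rng = np.random.default_rng(config.seed)
        records = [
            administer(params, row, config, strategy, order, rng, i)
            for i, row in enumerate(data.scores)
        ]
    else:
        admin = LSCATAdministrator(params, config, strategy, order)
        records = [admin.administer_one(row, i) for i, row in enumerate(data.scores)]
    return records, EfficiencySummary.from_records(records)
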