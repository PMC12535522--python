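"""Eligibility probability: P(complete-test sum score >= cutoff | responses so far).

Under the latent class engine this probability has a closed decomposition.
Conditional on class k the remaining items are independent categoricals,
so the distribution of their sum is an exact discrete convolution; the
class posterior given the answered items is elementary Bayes.  Hence

    P(S >= t | answered) = sum_k P(k | answered) * P(R_k >= t - s_obs)

where s_obs is the observed partial sum and R_k the remaining-items sum in
class k.  This is mathematically identical to enumerating all completions
of the observed pattern, zeroing the patterns that have become obsolete
and renormalizing — the enumeration route is kept here as an oracle
(`eligibility_probability_by_enumeration`) but scales exponentially in the
remaining bank, whereas the convolution route is linear.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .ulcm import ULCMParams

__all__ = [
    "PartialResponse",
    "SumScoreDistribution",
    "class_posterior",
    "remaining_sum_distribution",
    "eligibility_probability",
    "eligibility_probability_by_enumeration",
]

# interior eligibility probabilities are kept strictly inside (0, 1):
# exact 0/1 is reserved for deterministic (curtailment-certain) states
_INTERIOR_EPS = 1e-15

MAX_ENUMERATION = 10**6


@dataclass(frozen=True)
class PartialResponse:
    """A respondent's state mid-administration.

    ``answered`` is the ordered (item index, score) trace; ``remaining``
    and ``observed_sum`` are derived and cached.
    """

    n_items: int
    answered: tuple[tuple[int, int], ...] = ()
    remaining: tuple[int, ...] = field(init=False)
    observed_sum: int = field(init=False)

    def __post_init__(self) -> None:
        seen = [j for j, _ in self.answered]
        if len(set(seen)) != len(seen):
            raise ValueError("an item may be answered only once")
        if any(j < 0 or j >= self.n_items for j in seen):
            raise ValueError("item index out of range")
        object.__setattr__(
            self, "remaining", tuple(j for j in range(self.n_items) if j not in set(seen))
        )
        object.__setattr__(self, "observed_sum", int(sum(x for _, x in self.answered)))

    @classmethod
    def empty(cls, n_items: int) -> "PartialResponse":
        return cls(n_items)

    def answer(self, item: int, score: int) -> "PartialResponse":
        return PartialResponse(self.n_items, self.answered + ((int(item), int(score)),))

    @property
    def n_answered(self) -> int:
        return len(self.answered)

    def is_complete(self) -> bool:
        return not self.remaining


@dataclass(frozen=True)
class SumScoreDistribution:
    """Probability mass over integer sum scores 0..max achievable."""

    mass: np.ndarray

    def __post_init__(self) -> None:
        mass = np.asarray(self.mass, dtype=float)
        if mass.ndim != 1 or np.any(mass < -1e-12):
            raise ValueError("mass must be a non-negative vector")
        if abs(mass.sum() - 1.0) > 1e-12:
            raise ValueError(f"mass must sum to 1, got {mass.sum()}")
        object.__setattr__(self, "mass", mass)

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.mass.size)

    def tail(self, threshold: int) -> float:
        """P(S >= threshold)."""
        if threshold <= 0:
            return 1.0
        if threshold >= self.mass.size:
            return 0.0
        return float(self.mass[threshold:].sum())

    def mean(self) -> float:
        return float(np.dot(self.support, self.mass))


def _check_state(params: ULCMParams, state: PartialResponse) -> None:
    if state.n_items != params.n_items:
        raise ValueError(
            f"state covers {state.n_items} items, model has {params.n_items}"
        )
    for j, x in state.answered:
        if not (0 <= x < params.categories[j]):
            raise ValueError(f"score {x} out of range for item {j}")


def class_posterior(params: ULCMParams, state: PartialResponse) -> np.ndarray:
    """P(class | answered items), by Bayes under within-class independence.

    With nothing answered this is the prior pi.  Raises if the observed
    fragment has probability zero under every class (possible only via
    zero-probability cells in the model).
    """
    _check_state(params, state)
    post = params.class_weights.copy()
    for j, x in state.answered:
        post = post * params.conditionals[j][:, x]
        if post.sum() == 0.0:
            raise ValueError(
                f"observed score {x} on item {j} has probability 0 in every class"
            )
    return post / post.sum()


def remaining_sum_distribution(
    params: ULCMParams, remaining: tuple[int, ...] | list[int], k: int
) -> SumScoreDistribution:
    """Distribution of the sum over ``remaining`` items within class k.

    Exact sequential convolution of the per-item categorical score
    distributions (items are independent given the class).  Empty set ->
    point mass at 0.
    """
    mass = np.array([1.0])
    for j in remaining:
        mass = np.convolve(mass, params.conditionals[j][k])
    # convolution keeps non-negativity; tiny float drift renormalized
    return SumScoreDistribution(mass / mass.sum())


def _mixture_tail(params: ULCMParams, state: PartialResponse, needed: int) -> float:
    post = class_posterior(params, state)
    return float(
        sum(
            post[k] * remaining_sum_distribution(params, state.remaining, k).tail(needed)
            for k in range(params.n_classes)
            if post[k] > 0.0
        )
    )


def eligibility_probability(
    params: ULCMParams, state: PartialResponse, cutoff: int
) -> float:
    """P(final sum score >= cutoff | answered items) under the latent class engine.

    Returns exactly 1.0 when the observed partial sum already reaches the
    cutoff, and exactly 0.0 when even maximal remaining scores cannot reach
    it (deterministic curtailment).  Interior values are kept strictly
    inside (0, 1) so exact 0/1 certifies a deterministic state.
    """
    _check_state(params, state)
    cutoff = int(cutoff)
    if state.observed_sum >= cutoff:
        return 1.0
    max_remaining = sum(params.categories[j] - 1 for j in state.remaining)
    if state.observed_sum + max_remaining < cutoff:
        return 0.0
    p = _mixture_tail(params, state, cutoff - state.observed_sum)
    return float(np.clip(p, _INTERIOR_EPS, 1.0 - _INTERIOR_EPS))


def eligibility_probability_by_enumeration(
    params: ULCMParams, state: PartialResponse, cutoff: int
) -> float:
    """Eligibility probability by literal pattern enumeration (test oracle).

    Enumerates every completion of the observed fragment, i.e. keeps the
    full response patterns still feasible (all others have probability
    zero), renormalizes, and sums the probability of patterns whose total
    reaches the cutoff.  Refuses banks with more than 10^6 completions —
    the memory wall that motivates the convolution route.
    """
    _check_state(params, state)
    cutoff = int(cutoff)
    n_completions = int(np.prod([params.categories[j] for j in state.remaining]))
    if n_completions > MAX_ENUMERATION:
        raise ValueError(
            f"{n_completions} completions exceed the enumeration limit {MAX_ENUMERATION}"
        )
    answered = dict(state.answered)
    total = 0.0
    reach = 0.0
    for combo in itertools.product(
        *[range(params.categories[j]) for j in state.remaining]
    ):
        full = np.empty(params.n_items, dtype=np.int64)
        for j, x in answered.items():
            full[j] = x
        for j, x in zip(state.remaining, combo):
            full[j] = x
        p = float(np.exp(params.pattern_log_prob(full[None, :])[0]))
        total += p
        if full.sum() >= cutoff:
            reach += p
    if total == 0.0:
        raise ValueError("observed fragment has probability 0 under the model")
    return reach / total
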