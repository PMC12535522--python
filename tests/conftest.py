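import numpy as np
import pytest

from lscat import GeneratorSpec, ResponseMatrix, ULCMParams, generate
from lscat.synthdata import phq9_model, phq9_preset


def random_ulcm(
    rng: np.random.Generator,
    n_classes: int | None = None,
    n_items: int | None = None,
    max_categories: int = 4,
) -> ULCMParams:
    """A random small latent class model for oracle suites."""
    k = n_classes or int(rng.integers(1, 5))
    j = n_items or int(rng.integers(2, 7))
    pi = rng.dirichlet(np.ones(k) * 2)
    conds = tuple(
        rng.dirichlet(np.ones(int(rng.integers(2, max_categories + 1))), size=k)
        for _ in range(j)
    )
    return ULCMParams(pi, conds)


def random_state_and_cutoff(rng: np.random.Generator, params: ULCMParams):
    """A random partial response plus a cutoff in the achievable range."""
    from lscat import PartialResponse

    j = params.n_items
    n_answered = int(rng.integers(0, j + 1))
    items = rng.permutation(j)[:n_answered]
    state = PartialResponse.empty(j)
    for it in items:
        state = state.answer(int(it), int(rng.integers(0, params.categories[it])))
    cutoff = int(rng.integers(1, params.max_sum + 1))
    return state, cutoff


@pytest.fixture(scope="session")
def phq9_params() -> ULCMParams:
    return phq9_model()


@pytest.fixture(scope="session")
def phq9_data_small() -> ResponseMatrix:
    """2,000 synthetic PHQ-9-like respondents (shared across tests)."""
    data, _ = generate(phq9_preset(2000, seed=11))
    return data


@pytest.fixture(scope="session")
def phq9_data_medium() -> ResponseMatrix:
    """5,000 synthetic PHQ-9-like respondents."""
    data, _ = generate(phq9_preset(5000, seed=7))
    return data


@pytest.fixture()
def tiny_binary_model() -> ULCMParams:
    """K=1, two binary items with P(score 1) = 0.5 each."""
    return ULCMParams(
        np.array([1.0]),
        (np.array([[0.5, 0.5]]), np.array([[0.5, 0.5]])),
    )
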