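"""Shared fixtures: small random worlds and model-consistent data generators."""

import numpy as np
import pytest

from stag import (
    ObservedDataset,
    RateParameters,
    SamplingSchedule,
    assemble_matrix,
)


def random_rates(
    rng: np.random.Generator,
    k: int = 3,
    n_links: int = 3,
    link_mean: float = 0.03,
    growth_range: tuple = (-0.05, 0.09),
    beta_base: float = 0.03,
) -> RateParameters:
    """Random sparse rate parameters at the small-rate scale."""
    pairs = [(i, j) for i in range(k) for j in range(k) if i != j]
    chosen = rng.choice(len(pairs), size=n_links, replace=False)
    rates = rng.exponential(1.0, size=n_links)
    rates *= link_mean / rates.mean()
    gamma = np.zeros((k, k))
    for p, rate in zip(chosen, rates):
        i, j = pairs[p]
        gamma[i, j] = rate
    r = rng.uniform(*growth_range, size=k)
    beta = np.where(r + beta_base >= 0, beta_base, -r)
    return RateParameters(r + beta, beta, gamma)


def first_order_dataset(
    rng: np.random.Generator,
    A: np.ndarray,
    times=(7.0, 14.0, 21.0),
    etas=(0.8, 0.8, 0.8),
    n_barcodes: int = 200,
    noise: str | None = None,
) -> ObservedDataset:
    """Data generated exactly by the first-order propagation chain.

    ``noise=None`` gives the noiseless exact-recovery regime;
    ``noise="poisson"`` adds conditionally Poisson counts around the
    propagated mean (the model the estimator assumes).
    """
    k = A.shape[0]
    X1 = np.zeros((k, n_barcodes))
    states = rng.integers(0, k, n_barcodes)
    X1[states, np.arange(n_barcodes)] = rng.geometric(0.3, n_barcodes)
    Xs = [X1]
    for s in range(1, len(times)):
        c = (1 - etas[s - 1]) * etas[s] / etas[s - 1]
        dt = times[s] - times[s - 1]
        mean = np.clip(c * (Xs[-1] + dt * (A @ Xs[-1])), 0.0, None)
        Xs.append(rng.poisson(mean).astype(float) if noise == "poisson" else mean)
    return ObservedDataset(tuple(times), tuple(etas), np.stack(Xs))


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)


@pytest.fixture
def small_world(rng):
    """3-state sparse rates with its assembled matrix."""
    params = random_rates(rng)
    return params, assemble_matrix(params)


@pytest.fixture
def weekly_schedule():
    return SamplingSchedule((7.0, 14.0, 21.0), (0.8, 0.8, 0.8))
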