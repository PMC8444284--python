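"""Simulation benchmark of the estimator across model size and design.

Sweeps the number of states (2-10), the network connectivity (1 link up
to fully connected) and the sampling interval (1-10 days) with the number
of sampling times fixed at three and the harvest fraction at 80%. For
each grid cell, random rate parameters are drawn (transition rates
rescaled so their mean is 0.03/day; net growth drawn at the same scale by
default, so the mean rate over the whole matrix stays near 0.03/day), a
barcoded experiment is simulated, the matrix is refitted, and recovery is
scored by the Frobenius distance between true and estimated A.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import ObservedDataset, fit_stag
from .model import RateParameters, assemble_matrix
from .simulate import SamplingSchedule, simulate_experiment

__all__ = ["BenchmarkGrid", "BenchmarkResult", "random_network", "run_benchmark"]

#: Death-rate floor used when decomposing a drawn net growth into alpha/beta.
_BASE_DEATH = 0.03


@dataclass(frozen=True)
class BenchmarkGrid:
    """Sweep definition. Fixed by design: 3 sampling times, 80% harvest."""

    k_values: tuple[int, ...] = tuple(range(2, 11))
    connectivity: tuple[int, ...] | None = None  # None: 1..k(k-1) per k
    intervals: tuple[float, ...] = tuple(float(d) for d in range(1, 11))
    reps: int = 3
    n_barcodes: int = 1000
    init_cells_per_barcode: int = 1
    eta: float = 0.8
    n_times: int = 3
    growth_range: tuple[float, float] = (-0.05, 0.09)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(i < 1 for i in self.intervals):
            raise ValueError("sampling intervals must be >= 1 day")
        if self.connectivity is not None:
            kmax = max(self.k_values)
            if any(c > kmax * (kmax - 1) or c < 1 for c in self.connectivity):
                raise ValueError("connectivity must lie in [1, k(k-1)]")


@dataclass
class BenchmarkResult:
    """Tidy per-rep distances plus per-cell aggregates."""

    table: pd.DataFrame
    grid: BenchmarkGrid

    def aggregate(self) -> pd.DataFrame:
        ok = self.table[self.table["status"] == "ok"]
        agg = ok.groupby(["k", "n_links", "interval"]).agg(
            mean_frobenius=("frobenius", "mean"),
            sd_frobenius=("frobenius", "std"),
            mean_relative=("relative_frobenius", "mean"),
            n=("frobenius", "size"),
        ).reset_index()
        empty = (
            self.table.groupby(["k", "n_links", "interval"])["status"]
            .apply(lambda s: (s == "ok").sum() == 0)
            .rename("empty")
            .reset_index()
        )
        return agg.merge(empty, on=["k", "n_links", "interval"], how="outer")


def random_network(
    k: int,
    n_links: int,
    mean_rate: float = 0.03,
    seed: int | np.random.Generator | None = None,
    growth_range: tuple[float, float] = (-0.1, 0.3),
) -> RateParameters:
    """Random rate parameters with ``n_links`` transitions at a pinned mean rate.

    ``n_links`` ordered state pairs are chosen uniformly; their rates are
    exponential draws rescaled so the mean over drawn transitions equals
    ``mean_rate`` exactly. Net growth per state is uniform on
    ``growth_range`` and split into alpha/beta with a small death floor.
    """
    if not (1 <= n_links <= k * (k - 1)):
        raise ValueError(f"n_links must lie in [1, {k * (k - 1)}] for k={k}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pairs = [(i, j) for i in range(k) for j in range(k) if i != j]
    chosen = rng.choice(len(pairs), size=n_links, replace=False)
    rates = rng.exponential(1.0, size=n_links)
    rates *= mean_rate / rates.mean()
    gamma = np.zeros((k, k))
    for p, rate in zip(chosen, rates):
        i, j = pairs[p]
        gamma[i, j] = rate
    r = rng.uniform(growth_range[0], growth_range[1], size=k)
    beta = np.where(r + _BASE_DEATH >= 0, _BASE_DEATH, -r)
    alpha = r + beta
    return RateParameters(alpha=alpha, beta=beta, gamma=gamma)


def run_benchmark(grid: BenchmarkGrid) -> BenchmarkResult:
    """Simulate/refit every grid cell; failures are recorded, not fatal.

    The lasso budget is fixed at twice the true off-diagonal sum per rep,
    isolating identifiability from penalty tuning. Every cell is
    reproducible from (grid.seed, k, n_links, interval, rep).
    """
    rows = []
    for k in grid.k_values:
        links = grid.connectivity or tuple(range(1, k * (k - 1) + 1))
        links = tuple(c for c in links if c <= k * (k - 1))
        for n_links, interval, rep in itertools.product(
            links, grid.intervals, range(grid.reps)
        ):
            cell_seed = np.random.SeedSequence(
                [grid.seed, k, n_links, int(interval * 1000), rep]
            )
            rng = np.random.default_rng(cell_seed)
            params = random_network(
                k, n_links, seed=rng, growth_range=grid.growth_range
            )
            A_true = assemble_matrix(params).A
            times = tuple(interval * (s + 1) for s in range(grid.n_times))
            schedule = SamplingSchedule(times, (grid.eta,) * grid.n_times)
            lam = 2.0 * float(params.gamma.sum())
            try:
                series = simulate_experiment(
                    params, grid.n_barcodes, grid.init_cells_per_barcode,
                    schedule, seed=rng,
                )
                data = ObservedDataset.from_sampled_series(series)
                fit = fit_stag(data, lam=lam)
                frob = float(np.linalg.norm(fit.A_hat.A - A_true))
                rel = frob / float(np.linalg.norm(A_true))
                rows.append((k, n_links, interval, rep, frob, rel, "ok"))
            except (ValueError, RuntimeError) as exc:
                warnings.warn(
                    f"benchmark cell (k={k}, links={n_links}, dt={interval},"
                    f" rep={rep}) failed: {exc}"
                )
                rows.append((k, n_links, interval, rep, np.nan, np.nan, "failed"))
    table = pd.DataFrame(
        rows,
        columns=["k", "n_links", "interval", "rep",
                 "frobenius", "relative_frobenius", "status"],
    )
    return BenchmarkResult(table, grid)
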