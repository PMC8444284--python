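"""Exact stochastic simulation of the k-state birth/death/transition process.

Implements the direct Gillespie method for the event rules

* growth:      X_i -> X_i + 1            at propensity alpha_i * X_i
* death:       X_i -> X_i - 1            at propensity beta_i  * X_i
* transition:  (X_i, X_j) -> (X_i - 1, X_j + 1)  at propensity gamma[j, i] * X_i

together with the harvest/reseed experimental protocol: at each sampling
time a fraction ``eta`` of the culture is removed for sequencing and the
remainder is grown on. The k=1 special case is a classical single-type
(Galton-Watson) branching process with immigration-free clones.

Deterministic mean-field propagation ``x(t+dt) = expm(A dt) x(t)`` and its
first-order approximation are provided for validation and projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .model import RateParameters, StateSpace, TransitionGrowthMatrix

__all__ = [
    "PopulationState",
    "SamplingSchedule",
    "SampledSeries",
    "gillespie_simulate",
    "binomial_harvest",
    "simulate_experiment",
    "galton_watson_experiment",
    "ode_propagate",
]

#: Abort guard for runaway simulations (configurable per call).
DEFAULT_MAX_EVENTS = 50_000_000


@dataclass
class PopulationState:
    """Integer cell counts per state at a time point (days)."""

    counts: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            counts = np.asarray(counts, dtype=np.int64)
            if np.any(counts < 0):
                raise ValueError("cell counts must be non-negative integers")
        self.counts = counts.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class SamplingSchedule:
    """Sampling days t_1 < t_2 < ... with harvest fractions eta_s in (0, 1]."""

    times: tuple[float, ...]
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        fractions = tuple(float(e) for e in self.fractions)
        if len(times) != len(fractions):
            raise ValueError("times and fractions must have equal length")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("sampling times must be strictly increasing")
        if any(not (0.0 < e <= 1.0) for e in fractions):
            raise ValueError("harvest fractions must lie in (0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "fractions", fractions)

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def weekly(cls, n_weeks: int = 3, eta: float = 0.8) -> "SamplingSchedule":
        """The canonical in vitro design: harvest eta weekly (days 7, 14, ...)."""
        return cls(tuple(7.0 * (i + 1) for i in range(n_weeks)), (eta,) * n_weeks)


@dataclass
class SampledSeries:
    """Harvested counts per (time, barcode, state), plus provenance.

    ``harvested[s]`` is a k x B integer matrix of cells harvested at
    ``schedule.times[s]``; barcode columns are aligned across times
    (extinct barcodes are zero columns).
    """

    harvested: list[np.ndarray]
    schedule: SamplingSchedule
    states: StateSpace
    barcodes: tuple[str, ...]
    seed: int | None = None
    condition: str = "untreated"

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time_days, barcode, state, count, condition."""
        rows = []
        for t, X in zip(self.schedule.times, self.harvested):
            state_idx, bc_idx = np.nonzero(X)
            for i, b in zip(state_idx, bc_idx):
                rows.append(
                    (t, self.barcodes[b], self.states.labels[i], int(X[i, b]), self.condition)
                )
        return pd.DataFrame(
            rows, columns=["time_days", "barcode", "state", "count", "condition"]
        )

    def distinct_barcodes(self) -> list[int]:
        """Number of barcodes with at least one harvested cell, per time point."""
        return [int((X.sum(axis=0) > 0).sum()) for X in self.harvested]

    def clone_sizes(self) -> list[np.ndarray]:
        """Observed (nonzero) clone sizes per time point."""
        out = []
        for X in self.harvested:
            sizes = X.sum(axis=0)
            out.append(sizes[sizes > 0])
        return out


def gillespie_simulate(
    params: RateParameters,
    init: PopulationState | np.ndarray,
    t_end: float,
    seed: int | np.random.Generator | None = None,
    record: bool = False,
    max_events: int = DEFAULT_MAX_EVENTS,
) -> PopulationState | list[PopulationState]:
    """Exact stochastic simulation from ``init.time`` to ``t_end``.

    Returns the final :class:`PopulationState` (or the full trajectory of
    post-event states when ``record=True``). An all-zero total propensity
    (extinct or frozen population) simply returns the state carried to
    ``t_end``. Raises ``RuntimeError`` if ``max_events`` is exceeded.
    """
    if not isinstance(init, PopulationState):
        init = PopulationState(np.asarray(init), 0.0)
    if t_end < init.time:
        raise ValueError("t_end must be >= the initial time")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = params.k
    x = init.counts.astype(np.int64).copy()
    t = float(init.time)

    # Flattened event table: per-cell rates and state updates.
    # events: birth in i (k), death in i (k), transition i -> j (gamma[j, i]).
    rate_per_cell = np.concatenate([params.alpha, params.beta, params.gamma.T.reshape(-1)])
    src = np.concatenate(
        [np.arange(k), np.arange(k), np.repeat(np.arange(k), k)]
    )
    dst = np.concatenate([np.arange(k), np.arange(k), np.tile(np.arange(k), k)])
    kind = np.concatenate(
        [np.zeros(k, np.int8), np.ones(k, np.int8), np.full(k * k, 2, np.int8)]
    )
    active = rate_per_cell > 0
    rate_per_cell = rate_per_cell[active]
    src, dst, kind = src[active], dst[active], kind[active]

    traj: list[PopulationState] = [PopulationState(x.copy(), t)] if record else []
    n_events = 0
    while True:
        prop = rate_per_cell * x[src]
        total = prop.sum()
        if total <= 0.0:
            break
        dt = rng.exponential(1.0 / total)
        if t + dt > t_end:
            break
        t += dt
        e = rng.choice(prop.size, p=prop / total) if prop.size > 1 else 0
        if kind[e] == 0:
            x[src[e]] += 1
        elif kind[e] == 1:
            x[src[e]] -= 1
        else:
            x[src[e]] -= 1
            x[dst[e]] += 1
        n_events += 1
        if record:
            traj.append(PopulationState(x.copy(), t))
        if n_events > max_events:
            raise RuntimeError(f"event budget exceeded ({max_events} events)")
    final = PopulationState(x, t_end)
    if record:
        traj.append(final)
        return traj
    return final


def _gillespie_counts(
    alpha: np.ndarray,
    beta: np.ndarray,
    gamma_flat: np.ndarray,  # gamma.T.reshape(-1): rate of i -> j at [i*k+j]
    x: np.ndarray,
    t0: float,
    t_end: float,
    rng: np.random.Generator,
    max_events: int,
) -> np.ndarray:
    """Fast inner loop used by the experiment drivers (no recording)."""
    k = x.size
    t = t0
    rate = np.concatenate([alpha, beta, gamma_flat])
    nz = np.nonzero(rate)[0]
    rate = rate[nz]
    n_ev = rate.size
    # per-event source/destination lookup
    src = np.empty(n_ev, np.int64)
    dst = np.empty(n_ev, np.int64)
    kind = np.empty(n_ev, np.int8)
    for a, e in enumerate(nz):
        if e < k:
            src[a], dst[a], kind[a] = e, e, 0
        elif e < 2 * k:
            src[a], dst[a], kind[a] = e - k, e - k, 1
        else:
            f = e - 2 * k
            src[a], dst[a], kind[a] = f // k, f % k, 2
    n_events = 0
    prop = np.empty(n_ev)
    while True:
        np.multiply(rate, x[src], out=prop)
        total = prop.sum()
        if total <= 0.0:
            return x
        t += rng.exponential(1.0 / total)
        if t > t_end:
            return x
        u = rng.random() * total
        e = int(np.searchsorted(np.cumsum(prop), u))
        if e >= n_ev:
            e = n_ev - 1
        if kind[e] == 0:
            x[src[e]] += 1
        elif kind[e] == 1:
            x[src[e]] -= 1
        else:
            x[src[e]] -= 1
            x[dst[e]] += 1
        n_events += 1
        if n_events > max_events:
            raise RuntimeError(f"event budget exceeded ({max_events} events)")


def binomial_harvest(
    pop: PopulationState | np.ndarray,
    eta: float,
    seed: int | np.random.Generator | None = None,
    method: str = "binomial",
) -> tuple[np.ndarray, np.ndarray]:
    """Split a population into (harvested, remaining) at fraction ``eta``.

    ``method="binomial"`` (default) harvests each cell independently with
    probability eta — the mechanism the propagation algebra of the
    estimator assumes. ``method="hypergeometric"`` draws an exact count
    ``round(eta * total)`` without replacement across all entries.
    """
    counts = pop.counts if isinstance(pop, PopulationState) else np.asarray(pop, np.int64)
    if not (0.0 <= eta <= 1.0):
        raise ValueError("eta must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if method == "binomial":
        harvested = rng.binomial(counts, eta)
    elif method == "hypergeometric":
        flat = counts.reshape(-1)
        n_draw = int(round(eta * flat.sum()))
        harvested = rng.multivariate_hypergeometric(flat, n_draw).reshape(counts.shape)
    else:
        raise ValueError(f"unknown harvest method {method!r}")
    return harvested.astype(np.int64), (counts - harvested).astype(np.int64)


def _initial_states(
    n_barcodes: int,
    init_cells: int,
    k: int,
    rng: np.random.Generator,
    init_distribution: np.ndarray | None,
) -> np.ndarray:
    """k x B founding counts; each founding cell's state drawn iid."""
    if init_distribution is None:
        p = np.full(k, 1.0 / k)
    else:
        p = np.asarray(init_distribution, dtype=float)
        if p.size != k or np.any(p < 0) or p.sum() <= 0:
            raise ValueError("init_distribution must be a length-k non-negative vector")
        p = p / p.sum()
    X0 = np.zeros((k, n_barcodes), dtype=np.int64)
    for b in range(n_barcodes):
        states = rng.choice(k, size=init_cells, p=p)
        np.add.at(X0[:, b], states, 1)
    return X0


def simulate_experiment(
    params: RateParameters,
    n_barcodes: int,
    init_cells_per_barcode: int = 1,
    schedule: SamplingSchedule | None = None,
    seed: int | np.random.Generator | None = None,
    init_distribution: np.ndarray | None = None,
    condition: str = "untreated",
    harvest_method: str = "binomial",
    max_events: int = DEFAULT_MAX_EVENTS,
) -> SampledSeries:
    """Simulate the barcoded harvest/reseed time-series experiment.

    Per barcode: Gillespie-simulate the clone to the first sampling time,
    harvest fraction eta_1 (each cell independently), continue the
    remaining cells to the next time, and so on. Founding cells draw
    their state iid from ``init_distribution`` (default: uniform over
    states). Extinct barcodes simply vanish from later time points.
    """
    if n_barcodes < 1:
        raise ValueError("n_barcodes must be >= 1")
    if schedule is None:
        schedule = SamplingSchedule.weekly()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = params.k
    gamma_flat = params.gamma.T.reshape(-1).copy()
    X = _initial_states(n_barcodes, init_cells_per_barcode, k, rng, init_distribution)
    harvested_series = [
        np.zeros((k, n_barcodes), dtype=np.int64) for _ in schedule.times
    ]
    alive = np.nonzero(X.sum(axis=0) > 0)[0]
    t_prev = 0.0
    for s, (t_s, eta) in enumerate(zip(schedule.times, schedule.fractions)):
        still_alive = []
        for b in alive:
            x = _gillespie_counts(
                params.alpha, params.beta, gamma_flat, X[:, b].copy(),
                t_prev, t_s, rng, max_events,
            )
            if x.sum() > 0:
                h = rng.binomial(x, eta) if harvest_method == "binomial" else None
                if h is None:
                    h, _ = binomial_harvest(x, eta, rng, method=harvest_method)
                harvested_series[s][:, b] = h
                x -= h
            X[:, b] = x
            if x.sum() > 0:
                still_alive.append(b)
        alive = np.asarray(still_alive, dtype=np.int64)
        t_prev = t_s
    barcodes = tuple(f"BC{b:05d}" for b in range(n_barcodes))
    seed_val = seed if isinstance(seed, int) else None
    return SampledSeries(
        harvested_series, schedule, params.states, barcodes, seed_val, condition
    )


def galton_watson_experiment(
    alpha: float,
    beta: float,
    n_barcodes: int = 1217,
    schedule: SamplingSchedule | None = None,
    seed: int | np.random.Generator | None = None,
) -> SampledSeries:
    """Single-state (Galton-Watson) special case of the barcoded experiment.

    Defaults mirror the canonical in vitro configuration: 1,217 founding
    barcoded cells, 80% of cells harvested weekly over 21 days. Use
    :meth:`SampledSeries.clone_sizes` and
    :meth:`SampledSeries.distinct_barcodes` for the clone-size statistics.
    """
    params = RateParameters(
        alpha=np.array([alpha]), beta=np.array([beta]), gamma=np.zeros((1, 1))
    )
    if schedule is None:
        schedule = SamplingSchedule.weekly(3, 0.8)
    return simulate_experiment(params, n_barcodes, 1, schedule, seed)


def ode_propagate(
    A: TransitionGrowthMatrix | np.ndarray,
    x0: np.ndarray,
    dt: float,
    mode: str = "exact",
) -> np.ndarray:
    """Deterministic mean propagation over ``dt`` days.

    ``mode="exact"`` returns ``expm(A*dt) @ x0`` — the exact mean of the
    branching process. ``mode="first_order"`` returns ``(I + A*dt) @ x0``,
    the linearization the convex estimator is built on.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    M = A.A if isinstance(A, TransitionGrowthMatrix) else np.asarray(A, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if mode == "exact":
        return expm(M * dt) @ x0
    if mode == "first_order":
        return x0 + dt * (M @ x0)
    raise ValueError(f"unknown mode {mode!r}")
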