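"""Core vocabulary of the state transition and growth (STAG) model.

A population of cells occupies one of ``k`` transcriptional states. Each
state ``i`` has a proliferation rate ``alpha[i]`` and a death rate
``beta[i]`` (events/cell/day), and cells switch from state ``j`` to state
``i`` at rate ``gamma[i, j]``. All of the dynamics are summarized by the
k x k matrix ``A``:

* off-diagonal ``A[i, j]`` (i != j) is the transition rate j -> i,
* diagonal ``A[j, j] = alpha[j] - beta[j] - sum_i gamma[i, j]``,
* column sum of column ``j`` is the net growth rate ``r[j] = alpha[j] - beta[j]``.

The orientation convention — **column = source state, row = destination
state** — is used everywhere in this package, including all file formats.

``A`` is a Metzler matrix (non-negative off-diagonals), so its leading
eigenvalue is real (the Perron root); this underpins the stability and
steady-state analyses in :mod:`stag.spectral`.

Rates are events per day throughout; times are days. No unit conversion
layer exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StateSpace",
    "RateParameters",
    "TransitionGrowthMatrix",
    "TransitionNetwork",
    "assemble_matrix",
    "decompose_matrix",
    "threshold_network",
    "DEFAULT_NETWORK_THRESHOLD",
]

#: Default display threshold for transition networks, 0.01/day — the lower
#: end of the transition-rate range typically resolved by the fit. May be
#: lowered (down to 0) to reveal rare transitions.
DEFAULT_NETWORK_THRESHOLD = 0.01


def _default_labels(k: int) -> list[str]:
    return [f"S{i + 1}" for i in range(k)]


@dataclass(frozen=True)
class StateSpace:
    """Ordered set of ``k`` transcriptional states.

    All matrices and vectors in the package are indexed consistently by
    this ordering.
    """

    k: int
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        labels = tuple(self.labels) if self.labels else tuple(_default_labels(self.k))
        if len(labels) != self.k:
            raise ValueError(f"expected {self.k} labels, got {len(labels)}")
        if len(set(labels)) != self.k:
            raise ValueError("state labels must be unique")
        object.__setattr__(self, "labels", labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class RateParameters:
    """Generative ground-truth rates of the k-state birth/death/switch process.

    Parameters
    ----------
    alpha, beta
        Per-state proliferation and death rates (events/cell/day, >= 0).
    gamma
        k x k transition-rate table, ``gamma[i, j]`` = rate of switching
        FROM state j TO state i. Diagonal must be zero.

    Note that only the net growth ``r = alpha - beta`` is identifiable
    from count data; alpha and beta are kept separate for simulation.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    states: StateSpace | None = None

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float).reshape(-1)
        beta = np.asarray(self.beta, dtype=float).reshape(-1)
        gamma = np.asarray(self.gamma, dtype=float)
        k = alpha.size
        if beta.size != k:
            raise ValueError(f"alpha has {k} entries but beta has {beta.size}")
        if gamma.shape != (k, k):
            raise ValueError(f"gamma must be {k}x{k}, got {gamma.shape}")
        for name, arr in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative rates")
        if np.any(np.diagonal(gamma) != 0):
            raise ValueError("gamma diagonal must be zero (no self-transitions)")
        states = self.states if self.states is not None else StateSpace(k)
        if states.k != k:
            raise ValueError(f"state space has k={states.k} but rates have k={k}")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "states", states)

    @property
    def k(self) -> int:
        return self.alpha.size

    @property
    def net_growth(self) -> np.ndarray:
        """r = alpha - beta, per state (1/day)."""
        return self.alpha - self.beta


@dataclass(frozen=True)
class TransitionGrowthMatrix:
    """The k x k matrix ``A`` (units 1/day) summarizing the dynamics.

    Off-diagonals are transition rates (hence >= 0: Metzler); column sums
    are net growth rates.
    """

    A: np.ndarray
    states: StateSpace | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"A must be square, got shape {A.shape}")
        if not np.all(np.isfinite(A)):
            raise ValueError("A contains non-finite entries")
        off = A[~np.eye(A.shape[0], dtype=bool)]
        if off.size and off.min() < 0:
            raise ValueError(
                "negative off-diagonal entry: not a valid transition-growth matrix"
            )
        states = self.states if self.states is not None else StateSpace(A.shape[0])
        if states.k != A.shape[0]:
            raise ValueError("state space dimension does not match A")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "states", states)

    @property
    def k(self) -> int:
        return self.A.shape[0]

    @property
    def net_growth(self) -> np.ndarray:
        """Column sums of A: the per-state net growth rates r (1/day)."""
        return self.A.sum(axis=0)

    @property
    def offdiagonal_sum(self) -> float:
        """Total transition rate, sum of off-diagonal entries (the l1 budget)."""
        return float(self.A.sum() - np.trace(self.A))


@dataclass(frozen=True)
class TransitionNetwork:
    """Directed transition edges of an A matrix above a rate threshold."""

    edges: tuple[tuple[str, str, float], ...]  # (source, target, rate/day)
    min_rate: float
    states: StateSpace = field(default_factory=lambda: StateSpace(1))

    def __len__(self) -> int:
        return len(self.edges)


def assemble_matrix(params: RateParameters) -> TransitionGrowthMatrix:
    """Build A from per-state rates.

    ``A[i, j] = gamma[i, j]`` for i != j, and the diagonal absorbs growth,
    death and total outflow: ``A[j, j] = alpha[j] - beta[j] - sum_i gamma[i, j]``,
    so that each column sums to the net growth ``alpha[j] - beta[j]``.
    """
    A = params.gamma.copy()
    outflow = params.gamma.sum(axis=0)
    np.fill_diagonal(A, params.alpha - params.beta - outflow)
    return TransitionGrowthMatrix(A, states=params.states)


def decompose_matrix(A: TransitionGrowthMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split A into (net_growth, gamma).

    Returns the column sums ``r = alpha - beta`` and the off-diagonal
    transition table. The individual alpha and beta are *not* recoverable
    from A — only their difference.
    """
    if not isinstance(A, TransitionGrowthMatrix):
        A = TransitionGrowthMatrix(np.asarray(A, dtype=float))
    gamma = A.A.copy()
    np.fill_diagonal(gamma, 0.0)
    return A.net_growth, gamma


def threshold_network(
    A: TransitionGrowthMatrix | np.ndarray,
    min_rate: float = DEFAULT_NETWORK_THRESHOLD,
) -> TransitionNetwork:
    """Extract directed edges with rate >= ``min_rate`` from A's off-diagonals.

    Lowering ``min_rate`` can only add edges; at 0 every strictly positive
    off-diagonal becomes an edge. Edge direction follows the package
    convention: entry (i, j) is an edge from state j to state i.
    """
    if min_rate < 0:
        raise ValueError("min_rate must be >= 0")
    if not isinstance(A, TransitionGrowthMatrix):
        A = TransitionGrowthMatrix(np.asarray(A, dtype=float))
    labels = A.states.labels
    edges = []
    M = A.A
    for i in range(A.k):
        for j in range(A.k):
            if i != j and M[i, j] >= min_rate and M[i, j] > 0:
                edges.append((labels[j], labels[i], float(M[i, j])))
    return TransitionNetwork(tuple(edges), float(min_rate), A.states)
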