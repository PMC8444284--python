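"""Eigenstructure of the transition-and-growth matrix A.

Because A is Metzler, its leading eigenvalue (the Perron root) is real and
governs the long-run fate of the population: all eigenvalue real parts
negative means the expected cell number shrinks to zero (Hurwitz-stable,
extinction); a positive Perron root means exponential growth. Even for a
growing population the *relative* state proportions can reach a steady
state: the normalized real non-negative eigenvector v of the Perron root,
``f_i = v_i / sum(v)``.

The minimal intervention asks for the smallest-l1 perturbation dA such
that A + dA is stable. For Metzler matrices, Hurwitz stability is exactly
equivalent to the existence of a positive vector d with
``(A + dA)^T d <= -eps d``; with d fixed this certificate is linear in
dA, so the search alternates linear programs over dA with eigenvector
updates of d. The certificate is exact (necessary and sufficient) for
this matrix class, so no conservatism is introduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import linprog

from .model import TransitionGrowthMatrix

__all__ = [
    "EigenSummary",
    "SteadyState",
    "Intervention",
    "eigen_summary",
    "steady_state",
    "long_term_projection",
    "minimal_intervention",
    "DEFAULT_STABILITY_MARGIN",
]

#: Default stability margin eps (1/day) required of A + dA.
DEFAULT_STABILITY_MARGIN = 1e-3


def _as_matrix(A) -> np.ndarray:
    return A.A if isinstance(A, TransitionGrowthMatrix) else np.asarray(A, dtype=float)


@dataclass(frozen=True)
class EigenSummary:
    eigenvalues: np.ndarray
    leading_real_part: float
    stable: bool


@dataclass(frozen=True)
class SteadyState:
    proportions: np.ndarray
    exists: bool
    unique: bool
    eigenvector: np.ndarray
    eigenvalue: float


@dataclass
class Intervention:
    deltaA: np.ndarray
    l1_norm: float
    epsilon: float
    mode: str
    feasible: bool
    modified: list[tuple[int, int]] = field(default_factory=list)
    certificate: np.ndarray | None = None


def eigen_summary(A: TransitionGrowthMatrix | np.ndarray) -> EigenSummary:
    """Eigenvalues of A; stable iff every real part is negative."""
    M = _as_matrix(A)
    w = np.linalg.eigvals(M)
    lead = float(np.max(w.real))
    return EigenSummary(w, lead, bool(lead < 0.0))


def steady_state(A: TransitionGrowthMatrix | np.ndarray, tol: float = 1e-9) -> SteadyState:
    """Limiting state proportions from the Perron eigenvector of A.

    Returns ``exists=False`` when no real non-negative eigenvector can be
    associated with the leading eigenvalue, and ``unique=False`` for
    degenerate spectra (e.g. a repeated Perron root: for the identity
    matrix any composition is a proportional steady state).
    """
    M = _as_matrix(A)
    k = M.shape[0]
    if k == 1:
        return SteadyState(np.array([1.0]), True, True, np.array([1.0]), float(M[0, 0]))
    w, V = np.linalg.eig(M)
    lead = np.max(w.real)
    scale = max(1.0, np.abs(w).max())
    leading_idx = np.nonzero(w.real >= lead - tol * scale)[0]
    unique = len(leading_idx) == 1
    # pick the leading eigenvector with the most consistent sign
    best_v, best_neg = None, np.inf
    for idx in leading_idx:
        v = V[:, idx]
        if np.abs(v.imag).max() > tol * max(1.0, np.abs(v.real).max()):
            continue
        v = v.real
        s = np.sum(v)
        if s < 0:
            v = -v
        neg = float(-np.minimum(v, 0.0).sum())
        if neg < best_neg:
            best_v, best_neg = v, neg
    if best_v is None or best_neg > tol * max(1.0, np.abs(best_v).max()):
        return SteadyState(np.full(k, np.nan), False, unique,
                           np.full(k, np.nan), float(lead))
    v = np.maximum(best_v, 0.0)
    if v.sum() == 0:
        return SteadyState(np.full(k, np.nan), False, unique,
                           np.full(k, np.nan), float(lead))
    f = v / v.sum()
    if not unique:
        warnings.warn(
            "degenerate leading eigenvalue: steady-state proportions are not unique;"
            " returning one valid eigenvector"
        )
    return SteadyState(f, True, unique, v, float(lead))


def long_term_projection(
    A: TransitionGrowthMatrix | np.ndarray,
    x0: np.ndarray,
    horizon: float,
    step: float = 1.0,
) -> "pd.DataFrame":
    """Deterministic projection of total size and composition over time.

    Repeated exact-exponential propagation on a fixed step grid; the
    composition converges to the steady-state proportions when the Perron
    eigenvalue is simple and dominant.
    """
    import pandas as pd

    if horizon <= 0 or step <= 0:
        raise ValueError("horizon and step must be > 0")
    M = _as_matrix(A)
    P = expm(M * step)
    x = np.asarray(x0, dtype=float).copy()
    t = 0.0
    rows = [(t, x.sum(), *(x / x.sum() if x.sum() > 0 else np.full(x.size, np.nan)))]
    while t < horizon - 1e-12:
        x = P @ x
        t += step
        tot = x.sum()
        comp = x / tot if tot > 0 else np.full(x.size, np.nan)
        rows.append((t, tot, *comp))
    k = M.shape[0]
    cols = ["time_days", "total"] + [f"f{i + 1}" for i in range(k)]
    return pd.DataFrame(rows, columns=cols)


def _positive_certificate(M: np.ndarray, eps: float) -> np.ndarray | None:
    """A positive d with M^T d <= -eps d, if M is stable with margin eps.

    Uses the left Perron eigenvector, regularized toward strict positivity
    for reducible matrices.
    """
    w, V = np.linalg.eig(M.T)
    idx = int(np.argmax(w.real))
    if w[idx].real > -eps * (1 - 1e-9):
        return None
    v = V[:, idx]
    if np.abs(v.imag).max() > 1e-9 * max(1.0, np.abs(v.real).max()):
        v = np.abs(v)
    else:
        v = v.real
        if v.sum() < 0:
            v = -v
    v = np.maximum(v, 0.0)
    if v.max() == 0:
        return None
    v = v / v.max()
    # nudge zeros (reducible case) without breaking the inequality much
    d = v + 1e-6
    if np.all(M.T @ d <= -eps * d + 1e-12):
        return d
    return None


def _intervention_lp(
    A: np.ndarray, d: np.ndarray, eps: float, mode: str
) -> np.ndarray | None:
    """min ||dA||_1 s.t. (A+dA)^T d <= -eps d, off-diag(A+dA) >= 0, for fixed d > 0."""
    k = A.shape[0]
    if mode == "free":
        # variables: u_ij - w_ij (positive/negative parts), both >= 0
        n = k * k
        c = np.ones(2 * n)
        # stability rows: for each column j, sum_i (A+dA)_ij d_i <= -eps d_j
        A_ub = np.zeros((k, 2 * n))
        b_ub = np.zeros(k)
        for j in range(k):
            for i in range(k):
                p = i * k + j
                A_ub[j, p] = d[i]
                A_ub[j, n + p] = -d[i]
            b_ub[j] = -eps * d[j] - float(A[:, j] @ d)
        # off-diagonal lower bounds: -(u - w)_ij <= A_ij  (i != j)
        rows = []
        rhs = []
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                row = np.zeros(2 * n)
                p = i * k + j
                row[p] = -1.0
                row[n + p] = 1.0
                rows.append(row)
                rhs.append(A[i, j])
        A_ub = np.vstack([A_ub] + rows)
        b_ub = np.concatenate([b_ub, rhs])
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=(0, None), method="highs")
        if not res.success:
            return None
        u = res.x[:n].reshape(k, k)
        w = res.x[n:].reshape(k, k)
        return u - w
    if mode == "transitions_only":
        # variables: reductions delta_ij >= 0 of off-diagonal (i, j), each
        # compensated by +delta on a_jj (blocked cells remain in state j,
        # so column sums are preserved)
        pairs = [(i, j) for i in range(k) for j in range(k) if i != j]
        n = len(pairs)
        c = np.ones(n)  # minimizing sum of reductions (||dA||_1 = 2 sum)
        A_ub = np.zeros((k, n))
        b_ub = np.zeros(k)
        for col in range(k):
            # stability row col: sum_i (A+dA)_{i,col} d_i <= -eps d_col
            for p, (i, j) in enumerate(pairs):
                if j == col:
                    A_ub[col, p] += -d[i]  # off-diagonal reduced
                    A_ub[col, p] += d[j]   # diagonal compensated
            b_ub[col] = -eps * d[col] - float(A[:, col] @ d)
        ub = np.array([A[i, j] for (i, j) in pairs])
        res = linprog(c, A_ub=A_ub, b_ub=b_ub,
                      bounds=list(zip(np.zeros(n), ub)), method="highs")
        if not res.success:
            return None
        dA = np.zeros((k, k))
        for p, (i, j) in enumerate(pairs):
            dA[i, j] -= res.x[p]
            dA[j, j] += res.x[p]
        return dA
    raise ValueError(f"unknown mode {mode!r}")


def minimal_intervention(
    A: TransitionGrowthMatrix | np.ndarray,
    epsilon: float = DEFAULT_STABILITY_MARGIN,
    mode: str = "free",
    max_rounds: int = 30,
) -> Intervention:
    """Smallest-l1 perturbation dA rendering A + dA Hurwitz-stable.

    Alternates a linear program over dA (with the positive-vector
    stability certificate fixed) and an eigenvector update of the
    certificate, starting from d = 1. ``mode="transitions_only"``
    restricts dA to reductions of transition rates with compensating
    diagonal increases (column sums preserved); ``mode="free"`` may
    perturb any entry. On success the result is verified stable by direct
    eigendecomposition; infeasibility is reported explicitly.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    M = _as_matrix(A)
    k = M.shape[0]
    if eigen_summary(M).leading_real_part <= -epsilon:
        return Intervention(np.zeros((k, k)), 0.0, epsilon, mode, True, [],
                            _positive_certificate(M, epsilon))

    best: np.ndarray | None = None
    best_norm = np.inf
    best_d = None
    d = np.ones(k)
    for _ in range(max_rounds):
        dA = _intervention_lp(M, d, epsilon, mode)
        if dA is not None:
            Mnew = M + dA
            if eigen_summary(Mnew).leading_real_part < 0.0:
                norm = float(np.abs(dA).sum())
                if norm < best_norm - 1e-12:
                    best, best_norm, best_d = dA, norm, d.copy()
                else:
                    break
            d_new = _positive_certificate(Mnew, epsilon * 0.5)
        else:
            d_new = None
        if d_new is None:
            # perturb the certificate and retry
            d = d * (1.0 + 0.1 * np.arange(1, k + 1) / k)
            continue
        if np.allclose(d_new / d_new.max(), d / d.max(), atol=1e-10):
            break
        d = d_new
    if best is None:
        return Intervention(np.zeros((k, k)), np.inf, epsilon, mode, False, [])
    modified = [
        (i, j) for i in range(k) for j in range(k)
        if abs(best[i, j]) > 1e-9 * max(1.0, np.abs(best).max())
    ]
    # certificate soundness: the returned matrix must be verifiably stable
    assert eigen_summary(M + best).stable
    return Intervention(best, best_norm, epsilon, mode, True, modified, best_d)
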