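"""Estimation of the transition-and-growth matrix A from barcode count series.

The observable is the harvested count matrix ``X(t_s)`` (states x barcodes)
at sampling times ``t_1 < ... < t_S`` with harvest fractions ``eta_s``.
Between samplings the expected counts propagate as ``expm(A dt)`` and are
thinned by the harvest/reseed protocol, so that

    E[X(t_s)] = expm(A (t_s - t_{s-1})) X(t_{s-1}) * c_s,
    c_s = (1 - eta_{s-1}) * eta_s / eta_{s-1},

where ``c_s`` is the ratio of observed counts attributable to sampling
alone. With the first-order propagator ``I + A dt`` the sum-of-squares
error over all barcodes,

    E(X, A) = sum_{s>=2} || X(t_s) - (I + A dt_s) X(t_{s-1}) c_s ||_F^2,

is quadratic in A, and the estimator is the convex program

    min_A E(X, A)   s.t.   sum_{i != j} a_ij <= lambda,   a_ij >= 0 (i != j),

an l1 (lasso) budget on the total transition rate with free diagonal.
Treatments are fitted jointly as perturbations ``A + dA_t`` of a shared
network under per-condition budgets (and optionally a Frobenius ball
around a prior matrix).

The quadratic programs are solved with an exact separable path (per-row
bounded least squares) whenever the global budget is slack, falling back
to SLSQP when it binds; every returned solution is checked post hoc
against all constraints, independently of the solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .model import StateSpace, TransitionGrowthMatrix

__all__ = [
    "ObservedDataset",
    "FitConfig",
    "FitResult",
    "BootstrapResult",
    "propagation_scaling",
    "stag_error",
    "fit_stag",
    "fit_stag_treatments",
    "select_lambda",
    "bootstrap_growth",
    "DEFAULT_LAMBDA_GRID",
]

#: Default grid for the lasso budget, spanning 0.5-2 /day.
DEFAULT_LAMBDA_GRID = (0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0)

_FEAS_TOL = 1e-8


@dataclass
class ObservedDataset:
    """Barcode x state count matrices at sampling times.

    Parameters
    ----------
    times
        Sampling days, strictly increasing, length S >= 2.
    etas
        Harvest fractions eta_s in (0, 1], one per time.
    X
        Array of shape (S, k, B): per time point a states x barcodes count
        matrix with barcode columns aligned across times (zero-filled for
        barcodes unobserved at a time point).
    """

    times: tuple[float, ...]
    etas: tuple[float, ...]
    X: np.ndarray
    states: StateSpace | None = None
    barcodes: tuple[str, ...] = ()
    condition: str = "untreated"

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        etas = tuple(float(e) for e in self.etas)
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must have shape (S, k, B)")
        S, k, B = X.shape
        if len(times) != S or len(etas) != S:
            raise ValueError("times/etas length must match X's first axis")
        if S < 1:
            raise ValueError("at least one sampling time is required")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("sampling times must be strictly increasing")
        if any(not (0.0 < e <= 1.0) for e in etas):
            raise ValueError("harvest fractions must lie in (0, 1]")
        if np.any(X < 0):
            raise ValueError("counts must be non-negative")
        states = self.states if self.states is not None else StateSpace(k)
        if states.k != k:
            raise ValueError("state space does not match X's second axis")
        barcodes = tuple(self.barcodes) if self.barcodes else tuple(
            f"BC{b:05d}" for b in range(B)
        )
        if len(barcodes) != B:
            raise ValueError("barcode labels must match X's third axis")
        self.times, self.etas, self.X = times, etas, X
        self.states, self.barcodes = states, barcodes

    @property
    def n_times(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    @property
    def n_barcodes(self) -> int:
        return self.X.shape[2]

    @classmethod
    def from_sampled_series(cls, series) -> "ObservedDataset":
        """Build from :class:`stag.simulate.SampledSeries` (lossless)."""
        X = np.stack([h.astype(float) for h in series.harvested])
        return cls(
            series.schedule.times,
            series.schedule.fractions,
            X,
            states=series.states,
            barcodes=series.barcodes,
            condition=series.condition,
        )

    def subset_barcodes(self, idx: np.ndarray) -> "ObservedDataset":
        idx = np.asarray(idx)
        return ObservedDataset(
            self.times,
            self.etas,
            self.X[:, :, idx],
            states=self.states,
            barcodes=tuple(self.barcodes[i] for i in idx),
            condition=self.condition,
        )


@dataclass(frozen=True)
class FitConfig:
    """Budgets for the joint/treatment fit (all >= 0).

    ``lam1``/``lam2`` bound the l1 norm of the off-diagonal part of the
    joint network and of each treatment network; ``omega`` (optional, with
    ``A_pri``) bounds the Frobenius deviation of A from a prior matrix.
    """

    lam1: float = np.inf
    lam2: float = np.inf
    omega: float | None = None
    A_pri: np.ndarray | None = None
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.lam1 < 0 or self.lam2 < 0:
            raise ValueError("budgets must be >= 0")
        if self.omega is not None and self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.omega is not None and self.A_pri is None:
            raise ValueError("omega given without a prior matrix A_pri")


@dataclass
class FitResult:
    """Estimated A (and per-treatment perturbations) with fit metadata."""

    A_hat: TransitionGrowthMatrix
    error: float
    lam: float
    status: str
    deltas: dict[str, np.ndarray] = field(default_factory=dict)
    config: FitConfig | None = None

    @property
    def net_growth(self) -> np.ndarray:
        return self.A_hat.net_growth


@dataclass
class BootstrapResult:
    """Percentile bootstrap of the per-state net growth rates."""

    samples: np.ndarray  # (n_boot, k)
    level: float
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_failed: int = 0


def propagation_scaling(eta_prev: float, eta_curr: float) -> float:
    """Expected count ratio between consecutive samplings due to sampling alone.

    Harvesting eta_prev leaves a fraction (1 - eta_prev) of the culture of
    which the observed X(t_prev) is an eta_prev-fraction; harvesting
    eta_curr of the regrown remainder gives the factor
    ``(1 - eta_prev) * eta_curr / eta_prev``.
    """
    if not (0.0 < eta_prev <= 1.0) or not (0.0 < eta_curr <= 1.0):
        raise ValueError("harvest fractions must lie in (0, 1]")
    return (1.0 - eta_prev) * eta_curr / eta_prev


def _design(data: ObservedDataset) -> tuple[np.ndarray, np.ndarray]:
    """Stack the regression Y = A Z + residual over all transitions.

    Y[:, n] = X(t_s)[:, b] - c_s X(t_{s-1})[:, b]
    Z[:, n] = dt_s * c_s * X(t_{s-1})[:, b]
    """
    if data.n_times < 2:
        raise ValueError("fitting requires at least two sampling times")
    Ys, Zs = [], []
    for s in range(1, data.n_times):
        dt = data.times[s] - data.times[s - 1]
        c = propagation_scaling(data.etas[s - 1], data.etas[s])
        Xp = data.X[s - 1]
        Ys.append(data.X[s] - c * Xp)
        Zs.append(dt * c * Xp)
    return np.hstack(Ys), np.hstack(Zs)


def stag_error(data: ObservedDataset, A: TransitionGrowthMatrix | np.ndarray) -> float:
    """Sum-of-squares error of A against the observed series (Frobenius^2)."""
    M = A.A if isinstance(A, TransitionGrowthMatrix) else np.asarray(A, dtype=float)
    if M.shape != (data.k, data.k):
        raise ValueError("A dimension does not match the data")
    E = 0.0
    for s in range(1, data.n_times):
        dt = data.times[s] - data.times[s - 1]
        c = propagation_scaling(data.etas[s - 1], data.etas[s])
        pred = c * (data.X[s - 1] + dt * (M @ data.X[s - 1]))
        E += float(np.sum((data.X[s] - pred) ** 2))
    return E


def _offdiag_mask(k: int) -> np.ndarray:
    return ~np.eye(k, dtype=bool)


def _check_constraints(A: np.ndarray, lam: float, tol: float = 1e-6) -> None:
    """Post-hoc, solver-independent audit of the returned solution."""
    k = A.shape[0]
    off = A[_offdiag_mask(k)]
    if off.size and off.min() < -_FEAS_TOL:
        raise RuntimeError("solver returned a negative off-diagonal rate")
    if np.isfinite(lam) and off.sum() > lam * (1 + tol) + _FEAS_TOL:
        raise RuntimeError("solver violated the l1 transition budget")


def _fit_rows_bounded(Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Per-row least squares with non-negative off-diagonals (budget ignored).

    The objective separates across rows of A; each row solves a bounded
    least-squares problem with design Z^T shared by all rows.
    """
    k = Y.shape[0]
    A = np.zeros((k, k))
    ZT = Z.T
    for i in range(k):
        lb = np.zeros(k)
        lb[i] = -np.inf
        res = optimize.lsq_linear(ZT, Y[i], bounds=(lb, np.full(k, np.inf)),
                                  method="bvls", tol=1e-14)
        A[i] = res.x
    return A


def _project_budget(off: np.ndarray, lam: float) -> np.ndarray:
    """Euclidean projection of the off-diagonal vector onto {x >= 0, sum x <= lam}."""
    x = np.maximum(off, 0.0)
    if x.sum() <= lam:
        return x
    # water-filling threshold tau with sum(max(x - tau, 0)) = lam
    u = np.sort(x)[::-1]
    css = np.cumsum(u)
    rho_candidates = np.nonzero(u - (css - lam) / np.arange(1, x.size + 1) > 0)[0]
    rho = rho_candidates[-1]
    tau = (css[rho] - lam) / (rho + 1)
    return np.maximum(x - tau, 0.0)


def _fit_budget_qp(
    Y: np.ndarray, Z: np.ndarray, lam: float, x0: np.ndarray,
    max_iter: int = 100_000, tol: float = 1e-13,
) -> np.ndarray:
    """Full QP with the binding l1 budget, via accelerated projected gradient.

    The projection onto {off-diagonals >= 0, their sum <= lam} (diagonal
    free) is exact (simplex water-filling), so the iteration converges to
    the constrained minimizer of the quadratic objective.
    """
    k = Y.shape[0]
    mask = _offdiag_mask(k)
    G = Z @ Z.T
    H = Y @ Z.T
    L = 2.0 * float(np.linalg.eigvalsh(G).max())
    if L <= 0:
        return x0

    def project(A: np.ndarray) -> np.ndarray:
        out = A.copy()
        out[mask] = _project_budget(A[mask], lam)
        return out

    A = project(x0)
    V = A.copy()
    t_mom = 1.0
    f_prev = np.inf
    for it in range(max_iter):
        grad = 2.0 * (V @ G - H)
        A_new = project(V - grad / L)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        V = A_new + ((t_mom - 1.0) / t_new) * (A_new - A)
        A, t_mom = A_new, t_new
        if it % 200 == 199:
            R = Y - A @ Z
            f_val = float(np.sum(R * R))
            if abs(f_prev - f_val) <= tol * max(1.0, f_val):
                break
            f_prev = f_val
    return A


def fit_stag(
    data: ObservedDataset,
    lam: float = np.inf,
    tol: float = 1e-10,
) -> FitResult:
    """Fit A by constrained least squares under the l1 transition budget.

    Solution path: the unconstrained least-squares solution is accepted
    when it already satisfies all constraints (this covers the noiseless
    exact-recovery regime at machine precision); otherwise per-row bounded
    least squares (exact, BVLS) handles the non-negativity, and SLSQP is
    engaged only when the global budget binds. ``lam=inf`` disables the
    budget; ``lam=0`` forces all off-diagonals to zero, leaving per-state
    growth-only least squares.
    """
    if lam < 0:
        raise ValueError("lambda budget must be >= 0")
    Y, Z = _design(data)
    k = data.k
    znorm = np.linalg.norm(Z)
    if znorm == 0.0:
        raise ValueError(
            "degenerate data: no barcode has nonzero counts at consecutive times"
        )
    mask = _offdiag_mask(k)

    if lam == 0.0:
        # budget forces the off-diagonal to zero; the diagonal separates per state
        A = np.zeros((k, k))
        for i in range(k):
            zz = Z[i] @ Z[i]
            A[i, i] = (Y[i] @ Z[i]) / zz if zz > 0 else 0.0
        status = "separable (lambda=0)"
    else:
        status = None
        # unconstrained path: exact when no constraint is active
        sol, *_ = np.linalg.lstsq(Z.T, Y.T, rcond=None)
        A_unc = sol.T
        off = A_unc[mask]
        if off.min() >= -tol * max(1.0, np.abs(A_unc).max()):
            A_unc[mask & (A_unc < 0)] = 0.0
            if A_unc[mask].sum() <= lam + _FEAS_TOL:
                A, status = A_unc, "least-squares (constraints slack)"
        if status is None:
            A_row = _fit_rows_bounded(Y, Z)
            if A_row[mask].sum() <= lam + _FEAS_TOL:
                A, status = A_row, "bounded least-squares (budget slack)"
            else:
                x0 = A_row.copy()
                x0[mask] *= lam / x0[mask].sum()
                A = _fit_budget_qp(Y, Z, lam, x0)
                status = "projected-gradient (budget active)"

    _check_constraints(A, lam)
    tg = TransitionGrowthMatrix(A, states=data.states)
    return FitResult(tg, stag_error(data, A), float(lam), status)


def fit_stag_treatments(
    datasets: list[ObservedDataset],
    config: FitConfig | None = None,
) -> FitResult:
    """Jointly fit a shared network A and per-treatment perturbations dA_t.

    ``datasets[0]`` is the baseline (untreated) condition with dA == 0;
    each further dataset contributes a treatment perturbation. Minimizes
    the global error sum over conditions subject to

        ||A^nd||_1 <= lam1,   ||(A + dA_t)^nd||_1 <= lam2,
        A^nd >= 0,            (A + dA_t)^nd >= 0,
        ||A - A_pri||_F <= omega   (optional),

    where ^nd denotes the off-diagonal part. A vanishing ridge on dA
    (1e-9 x data scale) selects dA = 0 among ties when conditions carry
    identical information.
    """
    if config is None:
        config = FitConfig()
    if len(datasets) < 2:
        raise ValueError("need a baseline plus at least one treatment dataset")
    k = datasets[0].k
    if any(d.k != k for d in datasets):
        raise ValueError("all conditions must share the state space")
    designs = [_design(d) for d in datasets]
    n_treat = len(datasets) - 1
    mask = _offdiag_mask(k)
    mflat = mask.reshape(-1)

    pin_A = config.omega == 0.0 and config.A_pri is not None
    A_pri = None if config.A_pri is None else np.asarray(config.A_pri, dtype=float)

    scale = sum(float(np.sum(Z * Z)) for _, Z in designs)
    ridge = 1e-9 * max(scale, 1.0)

    Gs = [Z @ Z.T for _, Z in designs]
    Hs = [Y @ Z.T for Y, Z in designs]

    nvar_A = 0 if pin_A else k * k
    nvar = nvar_A + n_treat * k * k

    def unpack(v):
        if pin_A:
            A = A_pri
            rest = v
        else:
            A = v[: k * k].reshape(k, k)
            rest = v[k * k:]
        deltas = [rest[t * k * k:(t + 1) * k * k].reshape(k, k) for t in range(n_treat)]
        return A, deltas

    def f(v):
        A, deltas = unpack(v)
        val = 0.0
        for t, (Y, Z) in enumerate(designs):
            M = A if t == 0 else A + deltas[t - 1]
            R = Y - M @ Z
            val += float(np.sum(R * R))
        val += ridge * sum(float(np.sum(D * D)) for D in deltas)
        return val

    def grad(v):
        A, deltas = unpack(v)
        gA = np.zeros((k, k))
        gD = []
        for t in range(len(datasets)):
            M = A if t == 0 else A + deltas[t - 1]
            gM = 2.0 * (M @ Gs[t] - Hs[t])
            gA += gM
            if t > 0:
                gD.append(gM + 2.0 * ridge * deltas[t - 1])
        parts = [] if pin_A else [gA.reshape(-1)]
        parts += [g.reshape(-1) for g in gD]
        return np.concatenate(parts)

    cons = []
    if not pin_A and np.isfinite(config.lam1):
        jac1 = np.zeros(nvar)
        jac1[:k * k][mflat] = -1.0
        cons.append({
            "type": "ineq",
            "fun": lambda v: config.lam1 - v[:k * k][mflat].sum(),
            "jac": lambda v, j=jac1: j,
        })
    for t in range(n_treat):
        sl = slice(nvar_A + t * k * k, nvar_A + (t + 1) * k * k)
        # (A + dA_t) off-diagonals >= 0
        def g_nonneg(v, sl=sl):
            A, _ = unpack(v)
            D = v[sl].reshape(k, k)
            return (A + D)[mask]

        def j_nonneg(v, sl=sl):
            J = np.zeros((int(mask.sum()), nvar))
            rows = np.nonzero(mflat)[0]
            for r, pos in enumerate(rows):
                if not pin_A:
                    J[r, pos] = 1.0
                J[r, sl.start + pos] = 1.0
            return J

        cons.append({"type": "ineq", "fun": g_nonneg, "jac": j_nonneg})
        if np.isfinite(config.lam2):
            def g_budget(v, sl=sl):
                A, _ = unpack(v)
                D = v[sl].reshape(k, k)
                return config.lam2 - (A + D)[mask].sum()

            def j_budget(v, sl=sl):
                j = np.zeros(nvar)
                if not pin_A:
                    j[:k * k][mflat] = -1.0
                j[sl][mflat] = -1.0
                return j

            cons.append({"type": "ineq", "fun": g_budget, "jac": j_budget})
    if not pin_A and config.omega is not None:
        def g_omega(v):
            A, _ = unpack(v)
            return config.omega ** 2 - float(np.sum((A - A_pri) ** 2))

        def j_omega(v):
            A, _ = unpack(v)
            j = np.zeros(nvar)
            j[:k * k] = (-2.0 * (A - A_pri)).reshape(-1)
            return j

        cons.append({"type": "ineq", "fun": g_omega, "jac": j_omega})

    bounds = None
    if not pin_A:
        bounds = [(0.0, None) if m else (None, None) for m in mflat]
        bounds += [(None, None)] * (n_treat * k * k)

    # warm start: baseline fit scaled into budget, deltas at zero
    if pin_A:
        x0 = np.zeros(nvar)
    else:
        base = fit_stag(datasets[0], lam=config.lam1).A_hat.A.copy()
        if config.omega is not None:
            dev = np.linalg.norm(base - A_pri)
            if dev > config.omega:
                base = A_pri + (base - A_pri) * (
                    0.0 if dev == 0 else 0.99 * config.omega / dev
                )
                base[mask & (base < 0)] = 0.0
        x0 = np.concatenate([base.reshape(-1), np.zeros(n_treat * k * k)])

    res = optimize.minimize(
        f, x0, jac=grad, bounds=bounds, constraints=cons, method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    if not res.success:
        warnings.warn(f"SLSQP did not fully converge: {res.message}")
    A, deltas = unpack(res.x)
    A = A.copy()
    A[mask & (A < -_FEAS_TOL)] = 0.0
    A[mask] = np.maximum(A[mask], 0.0)
    _check_constraints(A, config.lam1)
    for t, D in enumerate(deltas):
        _check_constraints(A + D, config.lam2)
    delta_map = {
        datasets[t + 1].condition: deltas[t] for t in range(n_treat)
    }
    E_global = sum(
        stag_error(d, A if t == 0 else A + deltas[t - 1])
        for t, d in enumerate(datasets)
    )
    tg = TransitionGrowthMatrix(A, states=datasets[0].states)
    return FitResult(tg, E_global, float(config.lam1),
                     "slsqp (joint treatment fit)", delta_map, config)


def select_lambda(
    data: ObservedDataset,
    grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    split_seed: int | None = None,
) -> tuple[float, pd.DataFrame]:
    """Tune the lasso budget by a 50/50 barcode split.

    Fits on the training half for each grid value and returns the budget
    minimizing the held-out error, plus the full validation curve.
    """
    grid = tuple(float(g) for g in grid)
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    if data.n_barcodes < 2:
        raise ValueError("need at least 2 barcodes to split")
    rng = np.random.default_rng(split_seed)
    perm = rng.permutation(data.n_barcodes)
    half = data.n_barcodes // 2
    train = data.subset_barcodes(perm[:half])
    test = data.subset_barcodes(perm[half:])
    rows = []
    for lam in grid:
        fit = fit_stag(train, lam=lam)
        rows.append((lam, fit.error, stag_error(test, fit.A_hat)))
    curve = pd.DataFrame(rows, columns=["lam", "train_error", "validation_error"])
    best = float(curve.loc[curve["validation_error"].idxmin(), "lam"])
    return best, curve


def bootstrap_growth(
    data: ObservedDataset,
    n_boot: int = 1000,
    level: float = 0.90,
    seed: int | None = None,
    lam: float = np.inf,
) -> BootstrapResult:
    """Percentile bootstrap CIs for the per-state net growth rates.

    Whole barcode trajectories (columns of every X(t_s), jointly across
    times) are resampled with replacement to the original count, so the
    temporal pairing that the per-barcode residuals rely on is preserved.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    point = fit_stag(data, lam=lam).net_growth
    B = data.n_barcodes
    samples = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, B, size=B)
        boot = data.subset_barcodes(idx)
        try:
            samples.append(fit_stag(boot, lam=lam).net_growth)
        except (ValueError, RuntimeError):
            n_failed += 1
    if not samples:
        raise RuntimeError("every bootstrap replicate failed to fit")
    samples = np.asarray(samples)
    lo = (1.0 - level) / 2.0
    lower = np.quantile(samples, lo, axis=0)
    upper = np.quantile(samples, 1.0 - lo, axis=0)
    return BootstrapResult(samples, level, point, lower, upper, n_failed)
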