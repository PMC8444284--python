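# Methods

## The stochastic model

A population of cells distributed over `k` transcriptional states is a
continuous-time multi-type branching process. Per cell in state `i`, three
event types occur with exponential waiting times:

* division at rate `alpha[i]` (events/cell/day),
* death at rate `beta[i]`,
* switch to state `j` at rate `gamma[j, i]`.

Transitions conserve the total cell count; only division and death change
it. The process is simulated exactly with the direct Gillespie method
(`stag.simulate`), per barcode, since clones are independent. No
tau-leaping is used; populations at desk scale (≤ 1e6 cells) make the
direct method adequate, and a configurable event budget aborts runaway
runs. The expected counts obey `dx/dt = A x`, with `A` assembled as

```
A[i, j] = gamma[i, j]                              (i != j)
A[j, j] = alpha[j] - beta[j] - sum_i gamma[i, j]
```

so column sums are net growth rates `r = alpha - beta`. Only `r` is
identifiable from count data; `alpha` and `beta` are generative inputs to
the simulator only.

## The experimental protocol being emulated

Single founding cells carry heritable barcodes (default: one cell per
barcode, state drawn uniformly — both configurable). At each sampling day
`t_s` a fraction `eta_s` of the culture is harvested for sequencing and
the remainder reseeded. The harvest is modelled as independent
Bernoulli(`eta`) per cell (binomial thinning) — the mechanism the
estimator's expectation algebra assumes; exact-count (multivariate
hypergeometric) sampling is available as an option. Under thinning,

```
E[X_obs(t_s)] = expm(A dt) X_obs(t_{s-1}) * c_s,
c_s = (1 - eta_{s-1}) eta_s / eta_{s-1}.
```

The canonical design is weekly sampling at `eta = 0.8` for three weeks.

## Estimation

With the first-order propagator `I + A dt` (chosen for convexity; the
exact exponential is used only for simulation and projection), the fit
minimizes the squared Frobenius residual over all barcodes subject to
non-negative off-diagonals and an l1 budget `sum_{i!=j} a_ij <= lambda`.
Solution path (`stag.inference.fit_stag`):

1. the unconstrained least-squares solution is returned when it already
   satisfies all constraints (covers the noiseless regime at machine
   precision);
2. otherwise the problem separates across rows of A and is solved exactly
   per row by bounded least squares (BVLS);
3. only when the global budget binds does an accelerated projected-gradient
   iteration run, with an exact Euclidean projection onto
   `{off-diag >= 0, sum <= lambda}` (simplex water-filling).

Every returned solution is re-checked against all constraints
independently of the solver (feasibility tolerance 1e-8). `lambda = 0` is
handled in closed form (off-diagonals zero, per-state growth regression).
`lambda` defaults to cross-validation over {0.5, 0.75, ..., 2.0} with a
seeded 50/50 barcode split.

**Treatment fits** minimize the summed error over conditions in the shared
variables `(A, dA_t)` (baseline `dA = 0`) under per-condition budgets and
non-negativity, optionally inside a Frobenius ball around a prior matrix
(`omega` must be given explicitly with `A_pri`; `omega = 0` pins `A` and
is solved with `A` eliminated). The joint problem is a QP with linear (and
one quadratic) constraints, solved by SLSQP with analytic gradients. When
conditions carry identical information the split between `A` and `dA_t`
is not unique; a vanishing ridge (1e-9 x the squared data scale) on `dA`
breaks the tie toward `dA = 0`.

**Bootstrap.** Whole barcode trajectories (columns of every `X(t_s)`,
jointly across times) are resampled with replacement — the only
resampling unit under which the per-barcode residuals remain meaningful —
and percentile intervals of the refitted column sums are reported
(default 1000 replicates, 90% level).

## Spectral analysis

`A` is Metzler, so the leading eigenvalue is real. Stability (all real
parts negative) means expected extinction; the steady-state composition is
the normalized real non-negative eigenvector of the Perron root. Repeated
leading eigenvalues (e.g. the identity matrix, where any composition is a
proportional steady state) or reducible matrices set `unique = False` and
warn rather than fail; absence of a real non-negative leading eigenvector
sets `exists = False`.

**Minimal intervention.** The smallest `||dA||_1` with `A + dA` stable is
found via the positive-vector certificate: a Metzler matrix `M` is
Hurwitz iff some `d > 0` satisfies `M^T d <= -eps d`. For fixed `d` this
is linear in `dA`, so the search alternates a linear program over `dA`
(HiGHS) with an eigenvector update of `d` (left Perron vector of the
current `A + dA`), starting from `d = 1`. The certificate is exact for
the Metzler class, so no conservatism enters; every reported success is
additionally verified by direct eigendecomposition. The default margin is
`eps = 1e-3`/day — note the implied extinction timescale is `1/eps` if no
larger margin is requested. `transitions_only` mode restricts `dA` to
reductions of off-diagonal rates with the blocked cells staying in their
source state (`+delta` on the source diagonal, column sums preserved);
infeasibility (e.g. an intrinsically supercritical isolated state) is
reported explicitly, never silently.

## State definition and assignment

States come from consensus k-means over cell subsamples (100 reps of 80%
by default, k-means with 10 seeded restarts on the processed genes x cells
matrix; a PCA hook exists but no reduction is prescribed). Consensus
entries are co-clustering frequencies among co-sampled pairs; pairs never
co-sampled are tracked as undefined and excluded from the CDF-area
summary. The number of states is ranked by the drop in the relative
CDF-area change after each k (elbow), optionally averaged with a
growth-rate consistency score obtained by refitting the network on cell
subsamples (`1 - mean CV` of net growth across reps, clipped to [0, 1]).
Exact ties are reported, not broken silently.

Cells are assigned to predefined states by a rank-based single-sample
score: per cell, genes are ranked ascending (average ties); a signature of
`m` genes scores its mean rank, min-max normalized to [0, 1] via
`(raw - (m+1)/2) / (n - m)`. The normalization preserves the only property
the pipeline uses (argmax over states, comparable across signature sizes)
and is invariant to any strictly monotone transform of a cell's profile.
Argmax ties go to the first signature in declared order, flagged.

Signatures are derived by one-vs-rest Wilcoxon rank-sum tests with
Benjamini-Hochberg correction (adjusted p < 0.01, log fold change > 0.25,
up-regulated only). A rank-sum test replaces hurdle-model DE deliberately:
the test is an off-the-shelf step, not part of this package's
contribution. Gene-set collections are compared by a signed Fisher exact
score: `-log(P)` (positive) for over-represented overlap, `+log(P)` for
under-represented.

## Benchmark

`run_benchmark` sweeps states (2-10), connectivity (1 link to fully
connected) and sampling interval (1-10 days), with three sampling times
and `eta = 0.8` fixed for comparability. Transition rates are exponential
draws rescaled so their mean is exactly 0.03/day; net growth defaults to
uniform on (-0.05, 0.09)/day so the mean rate over the whole matrix stays
near 0.03/day. Per cell: 1000 single-cell founder barcodes (configurable),
a fit with `lambda` fixed at twice the true off-diagonal sum (isolating
identifiability from penalty tuning), scored by the (relative) Frobenius
distance to the generating matrix. Every grid cell is reproducible from
(seed, k, links, interval, rep); failed reps are recorded, not fatal.

## What the synthetic generator does and does not emulate

The simulator reproduces the statistical structure the estimator assumes:
independent clones, exponential event times, binomial harvest at stated
fractions. It does not model spatial structure, microenvironment, cell
cycle phase, dose-response, barcode collisions or sequencing dropout. A
green recovery test therefore certifies the estimator against its own
generative assumptions — not against technical artifacts of real
single-cell data.

## Known limitations

* **Small-clone bias of the estimator.** The regression conditions on the
  *observed* (thinned) counts, while the clone that seeds the next
  interval is the unobserved remainder. For clones of a few cells the
  cross-clone dispersion is not large relative to sampling noise, and the
  fitted `I + A dt` is attenuated by a factor
  `(C - D)(C + ((1-eta)/eta) D)^-1` (C the second-moment matrix, D the
  diagonal of means of pre-harvest clone sizes). Simultaneously the
  first-order propagator overstates growth at `r dt` beyond ~0.5. The two
  biases partially cancel but do not vanish: with weekly sampling of
  single-cell founder clones at desk scales the converged relative error
  of `A` is of order 0.4-1, independent of barcode count. The estimator
  is reliable when clones are large and overdispersed (fast growth,
  multiple samplings) or when `r dt` is small and clones are deeply
  sampled; the benchmark module maps this landscape. Bootstrap intervals
  quantify resampling variability around the (possibly biased) estimand,
  not around the truth; the calibration test therefore generates data
  from the model the estimator assumes.
* Rates are time-homogeneous within a condition; treatments act as static
  perturbations, not dose- or time-dependent ones.
* The stability margin `eps` trades intervention size against extinction
  speed; the default 1e-3/day certifies stability but implies a very long
  horizon.
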