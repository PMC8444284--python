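"""Constrained least-squares estimation of A: oracles and invariants."""

import numpy as np
import pytest

from stag import (
    FitConfig,
    ObservedDataset,
    assemble_matrix,
    bootstrap_growth,
    fit_stag,
    fit_stag_treatments,
    propagation_scaling,
    select_lambda,
    stag_error,
)
from stag.inference import DEFAULT_LAMBDA_GRID
from tests.conftest import first_order_dataset, random_rates


class TestPropagationScaling:
    @pytest.mark.parametrize(
        "prev,curr,expected",
        [(0.8, 0.8, 0.2), (0.5, 0.5, 0.5), (1.0, 0.8, 0.0), (0.8, 1.0, 0.25)],
    )
    def test_values(self, prev, curr, expected):
        assert propagation_scaling(prev, curr) == pytest.approx(expected)

    def test_rejects_zero_or_out_of_range(self):
        for prev, curr in [(0.0, 0.8), (0.8, 0.0), (1.2, 0.8), (-0.1, 0.5)]:
            with pytest.raises(ValueError):
                propagation_scaling(prev, curr)


class TestStagError:
    def test_zero_on_exact_chain(self, rng):
        A = assemble_matrix(random_rates(rng)).A
        data = first_order_dataset(rng, A)
        assert stag_error(data, A) == pytest.approx(0.0, abs=1e-18)

    def test_reduces_to_scaled_difference_at_zero_matrix(self, rng):
        X = rng.uniform(0, 10, (2, 3, 5))
        data = ObservedDataset((7.0, 14.0), (0.8, 0.8), X)
        expected = np.sum((X[1] - 0.2 * X[0]) ** 2)
        assert stag_error(data, np.zeros((3, 3))) == pytest.approx(expected)

    def test_matches_bruteforce_double_loop(self, rng):
        """Oracle: direct summation over barcodes, states and transitions."""
        A = rng.uniform(0, 0.1, (3, 3))
        X = rng.uniform(0, 10, (3, 3, 4))
        times, etas = (2.0, 5.0, 11.0), (0.5, 0.8, 0.6)
        data = ObservedDataset(times, etas, X)
        brute = 0.0
        for s in (1, 2):
            dt = times[s] - times[s - 1]
            c = (1 - etas[s - 1]) * etas[s] / etas[s - 1]
            for b in range(4):
                pred = c * (X[s - 1][:, b] + dt * A @ X[s - 1][:, b])
                brute += np.sum((X[s][:, b] - pred) ** 2)
        assert stag_error(data, A) == pytest.approx(brute, rel=1e-12)

    def test_nonincreasing_time_rejected(self, rng):
        with pytest.raises(ValueError):
            ObservedDataset((7.0, 7.0), (0.8, 0.8), np.ones((2, 2, 2)))


class TestFit:
    def test_exact_recovery_noiseless(self, rng):
        """Noiseless first-order data from known A: recovered to <= 1e-6."""
        params = random_rates(rng, k=6, n_links=8)
        A = assemble_matrix(params).A
        data = first_order_dataset(rng, A, n_barcodes=300)
        fit = fit_stag(data, lam=2 * params.gamma.sum())
        assert np.abs(fit.A_hat.A - A).max() <= 1e-6
        assert fit.error <= 1e-12

    def test_lambda_zero_forces_diagonal(self, rng):
        A = assemble_matrix(random_rates(rng)).A
        data = first_order_dataset(rng, A, noise="poisson")
        fit = fit_stag(data, lam=0.0)
        off = fit.A_hat.A[~np.eye(3, dtype=bool)]
        assert np.all(off == 0.0)
        # diagonal equals the separable per-state least-squares growth fit
        from stag.inference import _design

        Y, Z = _design(data)
        for i in range(3):
            expected = (Y[i] @ Z[i]) / (Z[i] @ Z[i])
            assert fit.A_hat.A[i, i] == pytest.approx(expected)

    def test_training_error_monotone_in_budget(self, rng):
        A = assemble_matrix(random_rates(rng, n_links=4, link_mean=0.1)).A
        data = first_order_dataset(rng, A, noise="poisson")
        errors = [fit_stag(data, lam=lam).error for lam in (0.0, 0.05, 0.2, 1.0)]
        assert all(e2 <= e1 + 1e-9 for e1, e2 in zip(errors, errors[1:]))

    def test_scaling_equivariance(self, rng):
        A = assemble_matrix(random_rates(rng)).A
        data = first_order_dataset(rng, A, noise="poisson")
        scaled = ObservedDataset(data.times, data.etas, 13.0 * data.X)
        f1 = fit_stag(data, lam=0.5)
        f2 = fit_stag(scaled, lam=0.5)
        assert np.allclose(f1.A_hat.A, f2.A_hat.A, atol=1e-7)
        assert f2.error == pytest.approx(13.0**2 * f1.error, rel=1e-6)

    def test_solution_beats_random_feasible_matrices(self, rng):
        """Convexity audit: no random feasible matrix does better."""
        A = assemble_matrix(random_rates(rng)).A
        data = first_order_dataset(rng, A, noise="poisson")
        lam = 0.2
        fit = fit_stag(data, lam=lam)
        for _ in range(100):
            M = rng.normal(0, 0.05, (3, 3))
            off = ~np.eye(3, dtype=bool)
            M[off] = np.abs(M[off])
            if M[off].sum() > lam:
                M[off] *= lam / M[off].sum()
            assert stag_error(data, M) >= fit.error - 1e-9

    def test_constraints_hold_when_budget_binds(self, rng):
        A = assemble_matrix(random_rates(rng, n_links=4, link_mean=0.1)).A
        data = first_order_dataset(rng, A, noise="poisson")
        lam = 0.05
        fit = fit_stag(data, lam=lam)
        off = fit.A_hat.A[~np.eye(3, dtype=bool)]
        assert off.min() >= -1e-10
        assert off.sum() <= lam * (1 + 1e-6) + 1e-8

    def test_degenerate_all_zero_rejected(self):
        data = ObservedDataset((7.0, 14.0), (0.8, 0.8), np.zeros((2, 3, 4)))
        with pytest.raises(ValueError, match="degenerate"):
            fit_stag(data, lam=1.0)


class TestTreatments:
    def _two_condition_data(self, rng, Delta):
        params = random_rates(rng)
        A = assemble_matrix(params).A
        d0 = first_order_dataset(rng, A)
        d1 = first_order_dataset(rng, A + Delta)
        d1.condition = "drug"
        return A, d0, d1

    def test_identical_data_gives_zero_deltas(self, rng):
        A = assemble_matrix(random_rates(rng)).A
        d0 = first_order_dataset(rng, A)
        d1 = ObservedDataset(d0.times, d0.etas, d0.X.copy(), condition="drug")
        res = fit_stag_treatments([d0, d1], FitConfig(lam1=1.0, lam2=1.0))
        scale = np.abs(res.A_hat.A).max()
        assert np.abs(res.deltas["drug"]).max() <= 1e-6 * max(scale, 1.0)

    def test_recovers_planted_perturbation(self, rng):
        Delta = np.zeros((3, 3))
        Delta[2, 0] = 0.08
        A, d0, d1 = self._two_condition_data(rng, Delta)
        res = fit_stag_treatments([d0, d1], FitConfig(lam1=1.0, lam2=1.0))
        dd = res.deltas["drug"]
        assert np.unravel_index(np.abs(dd).argmax(), dd.shape) == (2, 0)
        assert np.abs(dd - Delta).max() < 1e-4
        assert np.abs(res.A_hat.A - A).max() < 1e-4

    def test_omega_zero_pins_prior(self, rng):
        Delta = np.zeros((3, 3))
        Delta[1, 2] = 0.05
        A, d0, d1 = self._two_condition_data(rng, Delta)
        res = fit_stag_treatments(
            [d0, d1], FitConfig(lam1=1.0, lam2=1.0, omega=0.0, A_pri=A)
        )
        assert np.array_equal(res.A_hat.A, A)
        assert np.abs(res.deltas["drug"] - Delta).max() < 1e-4

    def test_omega_without_prior_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(omega=1.0)


class TestSelectLambda:
    def test_default_grid_spans_half_to_two(self):
        assert DEFAULT_LAMBDA_GRID[0] == 0.5 and DEFAULT_LAMBDA_GRID[-1] == 2.0

    def test_single_value_grid(self, rng):
        A = assemble_matrix(random_rates(rng)).A
        data = first_order_dataset(rng, A, noise="poisson")
        best, curve = select_lambda(data, grid=(0.7,), split_seed=0)
        assert best == 0.7 and len(curve) == 1

    def test_dense_truth_prefers_bigger_budget(self, rng):
        """Under-budgeting a dense true network hurts held-out error."""
        gamma = rng.uniform(0.05, 0.15, (4, 4))
        np.fill_diagonal(gamma, 0.0)
        from stag import RateParameters

        params = RateParameters(np.full(4, 0.1), np.full(4, 0.05), gamma)
        A = assemble_matrix(params).A
        data = first_order_dataset(rng, A, n_barcodes=400, noise="poisson")
        _, curve = select_lambda(data, grid=(1e-6, 2.0), split_seed=1)
        err = dict(zip(curve["lam"], curve["validation_error"]))
        assert err[2.0] <= err[1e-6]

    def test_empty_grid_rejected(self, rng):
        A = assemble_matrix(random_rates(rng)).A
        data = first_order_dataset(rng, A)
        with pytest.raises(ValueError):
            select_lambda(data, grid=())


class TestBootstrap:
    def test_single_barcode_zero_width(self, rng):
        A = assemble_matrix(random_rates(rng)).A
        data = first_order_dataset(rng, A, n_barcodes=1, noise="poisson")
        res = bootstrap_growth(data, n_boot=20, seed=0)
        assert np.allclose(res.lower, res.upper)

    def test_interval_brackets_point_estimate(self, rng):
        A = assemble_matrix(random_rates(rng)).A
        data = first_order_dataset(rng, A, n_barcodes=150, noise="poisson")
        res = bootstrap_growth(data, n_boot=100, seed=1)
        assert np.all(res.lower <= res.point + 1e-9)
        assert np.all(res.point <= res.upper + 1e-9)
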