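"""RBME likelihood: covariance algebra, closed forms, Monte-Carlo oracles,
grid evaluation, and the per-cell naive estimate."""

import numpy as np
import pandas as pd
import pytest

from spotspectra import (
    AcquisitionConfig,
    build_likelihood_matrix,
    naive_cell_occupations,
    rbme_jump_covariance,
    trajectory_log_likelihood,
)

DT = 0.00548


def _single_state_trajectory(D, sigma, n_jumps, seed, dt=DT):
    """Direct (independent) simulation of one RBME trajectory table."""
    rng = np.random.default_rng(seed)
    true = np.cumsum(rng.standard_normal((n_jumps + 1, 2)) * np.sqrt(2 * D * dt), axis=0)
    obs = true + rng.standard_normal((n_jumps + 1, 2)) * sigma
    return pd.DataFrame(
        {
            "trajectory_id": 0,
            "frame": np.arange(n_jumps + 1),
            "x_um": obs[:, 0],
            "y_um": obs[:, 1],
        }
    )


class TestJumpCovariance:
    def test_two_jump_matrix_from_definition(self):
        cov = rbme_jump_covariance(1.0, 0.035, DT, 2)
        expected = np.array([[0.013410, -0.001225], [-0.001225, 0.013410]])
        np.testing.assert_allclose(cov, expected, atol=1e-6)

    def test_zero_error_gives_independent_jumps(self):
        cov = rbme_jump_covariance(2.0, 0.0, DT, 4)
        np.testing.assert_allclose(cov, np.eye(4) * 4.0 * DT, atol=1e-15)

    def test_static_molecule_sample_covariance(self):
        # D=0, σ=0.035, n=3: jumps are pure differenced noise
        sigma, n_seq = 0.035, 100_000
        rng = np.random.default_rng(6)
        noise = rng.standard_normal((n_seq, 4)) * sigma
        jumps = np.diff(noise, axis=1)
        sample = np.cov(jumps.T)
        C = rbme_jump_covariance(0.0, sigma, DT, 3)
        se = np.sqrt(
            (np.outer(np.diag(C), np.diag(C)) + C**2) / n_seq
        )
        assert np.all(np.abs(sample - C) <= 4 * se)

    def test_positive_definite_across_grid(self, grid):
        for D in grid.diff_coefs[:: 20]:
            for s in grid.loc_errors[:: 4]:
                if D == 0 and s == 0:
                    continue
                C = rbme_jump_covariance(float(D), float(s), DT, 6)
                assert np.linalg.eigvalsh(C).min() > 0

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            rbme_jump_covariance(1.0, 0.03, 0.0, 2)
        with pytest.raises(ValueError):
            rbme_jump_covariance(1.0, 0.03, DT, 0)


class TestTrajectoryLogLikelihood:
    def test_single_zero_jump_closed_form(self):
        v = 2 * 1.0 * DT + 2 * 0.035**2
        expected = -np.log(2 * np.pi * v)  # both axes at zero displacement
        ll = trajectory_log_likelihood(np.zeros((1, 2)), 1.0, 0.035, DT)
        assert ll == pytest.approx(expected, abs=1e-12)
        assert ll == pytest.approx(2.474, abs=2e-3)

    def test_density_integrates_to_one(self):
        # n=1: integrate exp(log-likelihood) over the 2-D jump space
        D, sigma = 0.5, 0.03
        v = 2 * D * DT + 2 * sigma**2
        lim = 6 * np.sqrt(v)
        g = np.linspace(-lim, lim, 201)
        dx = g[1] - g[0]
        ll = np.array(
            [
                [trajectory_log_likelihood(np.array([[a, b]]), D, sigma, DT) for b in g]
                for a in g
            ]
        )
        total = np.exp(ll).sum() * dx * dx
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_matches_dense_multivariate_normal(self):
        from scipy.stats import multivariate_normal

        rng = np.random.default_rng(0)
        jumps = rng.standard_normal((5, 2)) * 0.1
        D, sigma = 2.0, 0.04
        C = rbme_jump_covariance(D, sigma, DT, 5)
        expected = sum(
            multivariate_normal.logpdf(jumps[:, ax], mean=np.zeros(5), cov=C)
            for ax in (0, 1)
        )
        assert trajectory_log_likelihood(jumps, D, sigma, DT) == pytest.approx(
            expected, rel=1e-10
        )

    def test_axis_exchangeability(self):
        rng = np.random.default_rng(4)
        jumps = rng.standard_normal((8, 2)) * 0.05
        a = trajectory_log_likelihood(jumps, 1.0, 0.03, DT)
        b = trajectory_log_likelihood(jumps[:, ::-1], 1.0, 0.03, DT)
        assert a == pytest.approx(b, rel=1e-12)

    @pytest.mark.parametrize("true_D", [0.05, 1.0, 10.0])
    def test_grid_mle_concentrates_at_true_D(self, grid, true_D):
        traj = _single_state_trajectory(true_D, 0.035, 2000, seed=int(true_D * 10))
        jumps = np.column_stack(
            [np.diff(traj["x_um"].to_numpy()), np.diff(traj["y_um"].to_numpy())]
        )
        lls = [
            trajectory_log_likelihood(jumps, float(d), 0.035, DT)
            for d in grid.diff_coefs
        ]
        best = grid.diff_coefs[int(np.argmax(lls))]
        # within one grid node (nodes are ~9.6% apart geometrically)
        assert abs(np.log(best / true_D)) <= 2 * np.log(grid.diff_coefs[1] / grid.diff_coefs[0])


class TestLikelihoodMatrix:
    def test_rows_normalized_and_dropped_counted(self, grid, acq):
        traj = _single_state_trajectory(1.0, 0.035, 10, seed=1)
        single = pd.DataFrame(
            {"trajectory_id": [99], "frame": [0], "x_um": [0.0], "y_um": [0.0]}
        )
        L = build_likelihood_matrix(pd.concat([traj, single]), grid, acq)
        assert L.n_trajectories == 1
        assert L.n_dropped == 1
        np.testing.assert_allclose(L.values.sum(axis=1), 1.0, atol=1e-9)

    def test_one_jump_row_equals_closed_form(self, grid, acq):
        jump = np.array([0.12, -0.05])
        traj = pd.DataFrame(
            {
                "trajectory_id": 0,
                "frame": [0, 1],
                "x_um": [0.0, jump[0]],
                "y_um": [0.0, jump[1]],
            }
        )
        L = build_likelihood_matrix(traj, grid, acq)
        v = (
            2 * grid.diff_coefs[:, None] * acq.frame_interval_s
            + 2 * grid.loc_errors[None, :] ** 2
        )
        v = np.maximum(v, 1e-14)
        log_l = -np.log(2 * np.pi * v) - (jump**2).sum() / (2 * v)
        expected = np.exp(log_l - log_l.max()).ravel()
        expected /= expected.sum()
        np.testing.assert_allclose(L.values[0], expected, rtol=1e-8, atol=1e-12)

    def test_single_state_mass_concentrates(self, grid, acq):
        traj = _single_state_trajectory(3.0, 0.035, 500, seed=3)
        L = build_likelihood_matrix(traj, grid, acq)
        d_of_col = np.repeat(grid.diff_coefs, grid.loc_errors.size)
        near = (d_of_col > 1.5) & (d_of_col < 6.0)
        assert L.values[0, near].sum() > 0.99

    def test_empty_dataset_raises(self, grid, acq):
        with pytest.raises(ValueError):
            build_likelihood_matrix(pd.DataFrame(columns=["trajectory_id", "frame", "x_um", "y_um"]), grid, acq)

    def test_kde_oracle_single_jump_density(self, grid, acq):
        # model density (n=1 jump) vs a Gaussian KDE of simulated jump
        # vectors; the model is convolved with the KDE kernel so the
        # comparison is exact up to Monte-Carlo error
        from scipy.stats import gaussian_kde, multivariate_normal

        D, sigma, n = 1.0, 0.035, 200_000
        rng = np.random.default_rng(10)
        v = 2 * D * DT + 2 * sigma**2
        samples = rng.standard_normal((2, n)) * np.sqrt(v)
        kde = gaussian_kde(samples)
        pts = np.array(
            [[0.0, 0.0], [0.05, 0.0], [0.0, -0.1], [0.1, 0.1], [-0.15, 0.05]]
        ).T
        kde_vals = kde(pts)
        conv_cov = np.diag([v, v]) + kde.covariance
        model_vals = multivariate_normal.pdf(pts.T, mean=[0, 0], cov=conv_cov)
        np.testing.assert_allclose(kde_vals, model_vals, rtol=0.05)


class TestNaiveCellOccupations:
    def test_single_trajectory_equals_its_row(self, grid, acq):
        traj = _single_state_trajectory(2.0, 0.035, 50, seed=8)
        m2d, marg = naive_cell_occupations(traj, grid, acq)
        L = build_likelihood_matrix(traj, grid, acq)
        np.testing.assert_allclose(m2d.ravel(), L.values[0], rtol=1e-10)
        assert m2d.sum() == pytest.approx(1.0)
        assert marg.sum() == pytest.approx(1.0)

    def test_single_state_cell_marginal_peaks_at_truth(self, grid, acq):
        traj = _single_state_trajectory(3.0, 0.035, 1200, seed=12)
        _, marg = naive_cell_occupations(traj, grid, acq)
        i_true = grid.nearest_diff_coef_index(3.0)
        assert abs(int(np.argmax(marg)) - i_true) <= 1
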