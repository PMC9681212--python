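"""Variational occupation inference: degenerate limits, invariances,
defocalization correction, and recovery against simulation truth."""

import numpy as np
import pandas as pd
import pytest

from spotspectra import (
    LikelihoodMatrix,
    bound_fraction,
    build_likelihood_matrix,
    correct_defocalization,
    infer_occupations,
    infer_spectrum,
    marginalize_sigma,
    naive_cell_occupations,
)
from spotspectra.simulate import DiffusiveState, SimulationModel, sample_cells
from spotspectra.statearray import defocalization_weights


def make_L(grid, values, jump_counts):
    values = np.atleast_2d(values)
    return LikelihoodMatrix(
        grid=grid,
        values=values,
        jump_counts=np.asarray(jump_counts),
        trajectory_ids=np.arange(values.shape[0]),
    )


class TestInferOccupations:
    def test_uniform_rows_give_uniform_posterior(self, grid):
        K = grid.n_states
        L = make_L(grid, np.full((20, K), 1.0 / K), np.full(20, 5))
        post = infer_occupations(L)
        np.testing.assert_allclose(post.occupations, 1.0 / K, rtol=1e-9)
        assert post.converged

    def test_spike_rows_concentrate_as_prior_vanishes(self, grid):
        K = grid.n_states
        values = np.zeros((10, K))
        values[:, 42] = 1.0
        L = make_L(grid, values, np.full(10, 8))
        post = infer_occupations(L, prior_weight=1e-9)
        assert post.occupations[42] == pytest.approx(1.0, abs=1e-6)

    def test_deterministic_and_row_order_invariant(self, two_state_L):
        p1 = infer_occupations(two_state_L)
        p2 = infer_occupations(two_state_L)
        np.testing.assert_array_equal(p1.occupations, p2.occupations)

        rng = np.random.default_rng(0)
        perm = rng.permutation(two_state_L.n_trajectories)
        shuffled = LikelihoodMatrix(
            grid=two_state_L.grid,
            values=two_state_L.values[perm],
            jump_counts=two_state_L.jump_counts[perm],
            trajectory_ids=two_state_L.trajectory_ids[perm],
        )
        p3 = infer_occupations(shuffled)
        np.testing.assert_allclose(p1.occupations, p3.occupations, atol=1e-12)

    def test_occupations_normalized(self, two_state_L):
        post = infer_occupations(two_state_L)
        assert post.occupations.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(post.occupations >= 0)

    def test_prior_weight_sensitivity_is_weak(self, two_state_L, acq):
        E = defocalization_weights(
            two_state_L.grid, acq.frame_interval_s, acq.focal_depth_um, acq.n_frames, 0.02
        )
        base = float(np.median(two_state_L.jump_counts))
        bfs = []
        for w in (base, 2 * base):
            post = correct_defocalization(
                infer_occupations(two_state_L, prior_weight=w), E
            )
            bfs.append(bound_fraction(marginalize_sigma(post)))
        assert abs(bfs[0] - bfs[1]) < 0.02

    def test_rejects_unnormalized_rows_and_bad_prior(self, grid):
        K = grid.n_states
        bad = make_L(grid, np.full((3, K), 2.0 / K), np.full(3, 4))
        with pytest.raises(ValueError):
            infer_occupations(bad)
        ok = make_L(grid, np.full((3, K), 1.0 / K), np.full(3, 4))
        with pytest.raises(ValueError):
            infer_occupations(ok, prior_weight=0.0)


class TestCorrectDefocalization:
    def test_single_bound_spike_unchanged(self, grid, acq):
        K = grid.n_states
        occ = np.zeros(K)
        occ[0] = 1.0  # slowest node: effectively immobile
        post = infer_occupations(
            make_L(grid, np.eye(K)[[0]], np.array([10])), prior_weight=1e-9
        )
        E = defocalization_weights(
            grid, acq.frame_interval_s, acq.focal_depth_um, acq.n_frames, 0.02
        )
        corrected = correct_defocalization(post, E)
        np.testing.assert_allclose(corrected.occupations, post.occupations, atol=1e-9)

    def test_fast_state_upweighted(self, grid, acq):
        # mixed raw occupations: correction must raise the fast share
        K = grid.n_states
        nD, nS = grid.shape
        occ2d = np.zeros((nD, nS))
        i_slow = grid.nearest_diff_coef_index(0.02)
        i_fast = grid.nearest_diff_coef_index(10.0)
        occ2d[i_slow, 7] = 0.5
        occ2d[i_fast, 7] = 0.5
        values = occ2d.ravel()[None, :]
        post = infer_occupations(make_L(grid, values, np.array([10])), prior_weight=1e-9)
        E = defocalization_weights(
            grid, acq.frame_interval_s, acq.focal_depth_um, acq.n_frames, 0.02
        )
        corrected = correct_defocalization(post, E)
        raw_fast = post.occupations_2d()[i_fast].sum()
        corr_fast = corrected.occupations_2d()[i_fast].sum()
        assert corr_fast > raw_fast

    def test_shape_mismatch_rejected(self, grid, acq):
        post = infer_occupations(
            make_L(grid, np.full((2, grid.n_states), 1.0 / grid.n_states), np.array([3, 3]))
        )
        with pytest.raises(ValueError):
            correct_defocalization(post, np.ones(5))


class TestMarginalizeSigma:
    def test_spike_posterior_gives_spike_spectrum(self, grid):
        K = grid.n_states
        post = infer_occupations(
            make_L(grid, np.eye(K)[[500]], np.array([10])), prior_weight=1e-9
        )
        spec = marginalize_sigma(post)
        iD = 500 // grid.loc_errors.size
        assert spec.occupations[iD] == pytest.approx(1.0, abs=1e-6)

    def test_uniform_posterior_gives_uniform_spectrum(self, grid):
        K = grid.n_states
        post = infer_occupations(make_L(grid, np.full((4, K), 1.0 / K), np.full(4, 2)))
        spec = marginalize_sigma(post)
        np.testing.assert_allclose(spec.occupations, 1.0 / grid.diff_coefs.size, rtol=1e-6)


class TestRecovery:
    def test_two_state_recovery_requires_defocalization_correction(
        self, two_state_L, acq
    ):
        """40% bound / 60% D=3: corrected spectrum recovers the bound
        occupation; the uncorrected one overestimates it substantially."""
        post = infer_occupations(two_state_L)
        E = defocalization_weights(
            two_state_L.grid, acq.frame_interval_s, acq.focal_depth_um, acq.n_frames, 0.02
        )
        bf_corrected = bound_fraction(marginalize_sigma(correct_defocalization(post, E)))
        bf_raw = bound_fraction(marginalize_sigma(post))
        assert abs(bf_corrected - 0.4) <= 0.08  # 30 cells: sampling-limited
        assert bf_raw > bf_corrected + 0.15
        assert bf_raw > 0.55  # raw estimate biased toward bound

    def test_corrected_spectrum_has_two_modes_near_truth(self, two_state_L, acq):
        spec, _ = infer_spectrum(
            two_state_L,
            acq.frame_interval_s,
            acq.focal_depth_um,
            acq.n_frames,
            bleach_prob_per_frame=0.02,
        )
        grid = two_state_L.grid
        slow = spec.occupations[grid.diff_coefs < 0.1]
        fast_band = (grid.diff_coefs > 1.5) & (grid.diff_coefs < 6.0)
        assert slow.sum() > 0.2
        assert spec.occupations[fast_band].sum() > 0.3

    def test_single_state_consistency(self, grid, acq):
        model = SimulationModel(states=[DiffusiveState(3.0, 1.0)])
        ds = sample_cells(model, acq, n_cells=20, seed=7)
        L = build_likelihood_matrix(ds, grid, acq)
        spec, _ = infer_spectrum(
            L, acq.frame_interval_s, acq.focal_depth_um, acq.n_frames, 0.02
        )
        i3 = grid.nearest_diff_coef_index(3.0)
        assert spec.occupations[i3 - 1 : i3 + 2].sum() > 0.9

    def test_state_array_mode_agrees_with_naive_estimate(self, grid, acq):
        rng = np.random.default_rng(3)
        n = 1500
        dt = acq.frame_interval_s
        pos = np.cumsum(
            rng.standard_normal((n + 1, 2)) * np.sqrt(2 * 3.0 * dt), axis=0
        ) + rng.standard_normal((n + 1, 2)) * 0.035
        cell = pd.DataFrame(
            {
                "trajectory_id": 0,
                "frame": np.arange(n + 1),
                "x_um": pos[:, 0],
                "y_um": pos[:, 1],
            }
        )
        _, naive_marg = naive_cell_occupations(cell, grid, acq)
        L = build_likelihood_matrix(cell, grid, acq)
        spec = marginalize_sigma(infer_occupations(L))
        assert int(np.argmax(naive_marg)) == int(np.argmax(spec.occupations))
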