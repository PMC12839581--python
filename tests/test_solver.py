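import numpy as np
import pytest

from dcrank import (
    CoordinateStats,
    DistributedDataset,
    KernelSpec,
    PenaltySpec,
    Shard,
    SurrogateSpec,
    compute_gradient_shift,
    coordinate_update,
    global_gradient,
    local_gradient,
    local_loss,
    solve_penalized_surrogate,
)
from dcrank.solver import pairwise_second_moments

from oracles import brute_pair_loss, grid_minimize, reference_cd_solver


class TestCoordinateUpdate:
    def test_fixed_point_when_gradient_vanishes(self, kernel):
        stats = CoordinateStats(upsilon1=0.0, upsilon2=1.0, upsilon3=0.0)
        assert coordinate_update(0.7, stats, kernel, 0.0) == pytest.approx(0.7)

    def test_small_gradient_thresholded_to_zero(self, kernel):
        stats = CoordinateStats(upsilon1=0.1, upsilon2=1.0, upsilon3=0.0)
        assert coordinate_update(0.0, stats, kernel, 0.2) == 0.0

    def test_soft_threshold_value(self, kernel):
        stats = CoordinateStats(upsilon1=-1.0, upsilon2=1.0, upsilon3=0.0)
        out = coordinate_update(0.0, stats, kernel, 0.2)
        assert out == pytest.approx(0.5333333333, abs=1e-9)

    def test_sign_antisymmetry(self, kernel, rng):
        for _ in range(20):
            b, u1, u3, pen = rng.standard_normal(4)
            u2 = float(rng.uniform(0.2, 2.0))
            pen = abs(pen)
            plus = coordinate_update(
                b, CoordinateStats(u1, u2, u3), kernel, pen
            )
            minus = coordinate_update(
                -b, CoordinateStats(-u1, u2, -u3), kernel, pen
            )
            assert plus == pytest.approx(-minus, abs=1e-14)

    def test_degenerate_column_returns_zero(self, kernel):
        stats = CoordinateStats(upsilon1=0.3, upsilon2=0.0, upsilon3=0.0)
        assert coordinate_update(0.5, stats, kernel, 0.1) == 0.0


class TestGradientShift:
    def test_single_machine_pooled_is_zero(self, small_shard, kernel, rng):
        ds = DistributedDataset([small_shard])
        s = compute_gradient_shift(ds, rng.standard_normal(3), kernel, "pooled")
        np.testing.assert_allclose(s.shift, 0.0, atol=1e-14)

    def test_identical_shards_machine_average_zero(self, small_shard, kernel, rng):
        ds = DistributedDataset(
            [small_shard, Shard(small_shard.X.copy(), small_shard.Y.copy())]
        )
        anchor = rng.standard_normal(3)
        s = compute_gradient_shift(ds, anchor, kernel, "machine-average")
        np.testing.assert_allclose(s.shift, 0.0, atol=1e-14)

    def test_equals_difference_of_gradients(self, two_shard_dataset, kernel, rng):
        anchor = rng.standard_normal(2)
        s = compute_gradient_shift(two_shard_dataset, anchor, kernel, "pooled")
        expected = local_gradient(
            two_shard_dataset.shards[0], anchor, kernel
        ) - global_gradient(two_shard_dataset, anchor, kernel, "pooled")
        np.testing.assert_allclose(s.shift, expected, atol=1e-14)


def _random_problem(rng, n=12, p=4, noise=0.5):
    X = rng.standard_normal((n, p))
    beta_true = np.zeros(p)
    beta_true[0] = 1.5
    if p > 1:
        beta_true[1] = -1.0
    Y = X @ beta_true + noise * rng.standard_normal(n)
    return Shard(X, Y)


class TestSolver:
    def test_one_dimensional_matches_grid_search(self, kernel, rng):
        """p = 1: the LLA solution matches exhaustive minimisation of the
        penalized surrogate objective on a 1e-4 grid."""
        shard = _random_problem(rng, n=6, p=1)
        lam = 0.15
        shift = np.array([0.05])
        pen = PenaltySpec("scad", lam=lam)
        rep = solve_penalized_surrogate(
            shard, SurrogateSpec(np.zeros(1), shift), pen, kernel, np.zeros(1)
        )

        def objective(b):
            from dcrank import penalty_value

            return (
                brute_pair_loss(shard.X, shard.Y, [b], 1.0)
                - shift[0] * b
                + penalty_value(b, pen)
            )

        best = grid_minimize(objective, -3.0, 3.0, res=1e-4)
        assert rep.beta[0] == pytest.approx(best, abs=2e-4)

    def test_huge_l1_penalty_returns_exact_zero(self, kernel, rng):
        shard = _random_problem(rng, n=10, p=5)
        pen = PenaltySpec("l1", lam=1e6)
        rep = solve_penalized_surrogate(
            shard, SurrogateSpec.zero(5), pen, kernel, np.full(5, 0.3)
        )
        assert np.all(rep.beta == 0.0)  # bit-exact sparsity
        assert rep.converged

    def test_objective_trace_nonincreasing(self, kernel, rng):
        for trial in range(5):
            shard = _random_problem(rng, n=14, p=6, noise=1.0)
            shift = 0.05 * rng.standard_normal(6)
            pen = PenaltySpec("scad", lam=0.2)
            rep = solve_penalized_surrogate(
                shard, SurrogateSpec(np.zeros(6), shift), pen, kernel, np.zeros(6)
            )
            trace = np.asarray(rep.objective_trace)
            assert np.all(np.diff(trace) <= 1e-10)

    def test_majorizer_dominates_smooth_part(self, kernel, rng):
        """G(b | b_bar) >= F(b) with equality at b_bar, by direct summation."""
        shard = _random_problem(rng, n=10, p=3)
        ups2 = pairwise_second_moments(shard.X)
        h, k6 = kernel.h, kernel.k6
        for _ in range(10):
            beta_bar = rng.standard_normal(3)
            l = int(rng.integers(3))
            f_bar = brute_pair_loss(shard.X, shard.Y, beta_bar, h)
            u1 = local_gradient(shard, beta_bar, kernel)[l]
            for _ in range(5):
                b = beta_bar.copy()
                b[l] += rng.uniform(-2, 2)
                f = brute_pair_loss(shard.X, shard.Y, b, h)
                g = (
                    f_bar
                    + u1 * (b[l] - beta_bar[l])
                    + (k6 * ups2[l] / h) * (b[l] - beta_bar[l]) ** 2
                )
                assert g >= f - 1e-10
            # equality at the expansion point
            assert f_bar == pytest.approx(
                brute_pair_loss(shard.X, shard.Y, beta_bar, h), abs=1e-14
            )

    def test_matches_reference_solver(self, kernel, rng):
        """Compiled incremental path agrees with a from-scratch brute-force
        LLA coordinate descent on the same zero-shift problem."""
        shard = _random_problem(rng, n=10, p=4)
        lam, a = 0.2, 3.7
        pen = PenaltySpec("scad", lam=lam, shape=a)
        # both solvers stop within sqrt(tol) of the fixed point, so compare
        # at a tightened tolerance
        rep = solve_penalized_surrogate(
            shard, SurrogateSpec.zero(4), pen, kernel, np.zeros(4), tol=1e-16
        )
        ref = reference_cd_solver(
            shard.X, shard.Y, np.zeros(4), lam, a, kernel.h, kernel.k6,
            np.zeros(4), tol=1e-16,
        )
        np.testing.assert_allclose(rep.beta, ref, atol=1e-6)

    def test_constant_column_pinned_to_zero(self, kernel, rng):
        X = rng.standard_normal((12, 3))
        X[:, 1] = 2.0  # degenerate: no pairwise variation
        Y = X[:, 0] + 0.1 * rng.standard_normal(12)
        shard = Shard(X, Y)
        rep = solve_penalized_surrogate(
            shard, SurrogateSpec.zero(3), PenaltySpec("scad", lam=0.05),
            kernel, np.array([0.0, 5.0, 0.0]),
        )
        assert rep.beta[1] == 0.0
        assert rep.degenerate_columns == 1

    def test_nonconvergence_flagged_not_raised(self, kernel, rng):
        shard = _random_problem(rng, n=12, p=4, noise=2.0)
        rep = solve_penalized_surrogate(
            shard, SurrogateSpec.zero(4), PenaltySpec("scad", lam=0.01),
            kernel, np.zeros(4), max_sweeps=1,
        )
        assert not rep.converged
        assert rep.sweeps == 1

    def test_surrogate_solution_improves_loss(self, kernel, rng):
        shard = _random_problem(rng, n=12, p=4)
        pen = PenaltySpec("scad", lam=0.1)
        rep = solve_penalized_surrogate(
            shard, SurrogateSpec.zero(4), pen, kernel, np.zeros(4)
        )
        assert local_loss(shard, rep.beta, kernel) <= local_loss(
            shard, np.zeros(4), kernel
        )
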