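import numpy as np
import pytest

from dcrank import (
    DistributedDataset,
    KernelSpec,
    Shard,
    global_gradient,
    global_loss,
    local_gradient,
    local_loss,
    pairwise_residual_diffs,
)

from oracles import brute_pair_gradient, brute_pair_loss, central_difference_gradient


class TestResidualDiffs:
    def test_pure_response_differences(self):
        shard = Shard(np.zeros((2, 3)), [1.0, 0.0])
        rd = pairwise_residual_diffs(shard, np.ones(3))
        assert rd.omega[0, 1] == 1.0
        assert rd.omega[1, 0] == -1.0

    def test_beta_zero_gives_response_diffs(self, small_shard):
        rd = pairwise_residual_diffs(small_shard, np.zeros(3))
        expected = small_shard.Y[:, None] - small_shard.Y[None, :]
        np.testing.assert_allclose(rd.omega, expected)

    def test_antisymmetry_and_shift_invariance(self, small_shard, rng):
        beta = rng.standard_normal(3)
        rd = pairwise_residual_diffs(small_shard, beta)
        np.testing.assert_allclose(rd.omega, -rd.omega.T, atol=1e-14)
        shifted = Shard(small_shard.X, small_shard.Y + 17.3)
        rd2 = pairwise_residual_diffs(shifted, beta)
        np.testing.assert_allclose(rd.omega, rd2.omega, atol=1e-12)

    def test_incremental_update_matches_recompute(self, small_shard, rng):
        beta = rng.standard_normal(3)
        rd = pairwise_residual_diffs(small_shard, beta)
        rd.move_coordinate(small_shard, 1, beta[1] + 0.37)
        beta2 = beta.copy()
        beta2[1] += 0.37
        fresh = pairwise_residual_diffs(small_shard, beta2)
        np.testing.assert_allclose(rd.omega, fresh.omega, atol=1e-12)

    def test_dimension_mismatch_raises(self, small_shard):
        with pytest.raises(ValueError):
            pairwise_residual_diffs(small_shard, np.zeros(5))


class TestLocalLoss:
    def test_two_point_example(self, kernel):
        shard = Shard(np.zeros((2, 1)), [1.0, 0.0])
        assert local_loss(shard, [0.0], kernel) == pytest.approx(1.0, abs=1e-14)

    def test_two_point_wide_bandwidth(self):
        shard = Shard(np.zeros((2, 1)), [1.0, 0.0])
        val = local_loss(shard, [0.0], KernelSpec(h=2.0))
        assert val == pytest.approx(1.109375, abs=1e-12)

    @pytest.mark.parametrize("h", [0.5, 1.0, 3.0])
    def test_constant_response_gives_origin_value(self, h):
        shard = Shard(np.zeros((4, 2)), np.full(4, 2.0))
        assert local_loss(shard, np.zeros(2), KernelSpec(h=h)) == pytest.approx(
            0.375 * h, abs=1e-14
        )

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            Shard(np.zeros((1, 2)), [1.0])

    def test_matches_brute_force(self, small_shard, kernel, rng):
        beta = rng.standard_normal(3)
        expected = brute_pair_loss(small_shard.X, small_shard.Y, beta, 1.0)
        assert local_loss(small_shard, beta, kernel) == pytest.approx(
            expected, abs=1e-12
        )

    def test_translation_and_permutation_invariance(self, small_shard, kernel, rng):
        beta = rng.standard_normal(3)
        base = local_loss(small_shard, beta, kernel)
        shifted = Shard(small_shard.X, small_shard.Y - 4.2)
        assert local_loss(shifted, beta, kernel) == pytest.approx(base, abs=1e-12)
        perm = rng.permutation(small_shard.n)
        shuffled = Shard(small_shard.X[perm], small_shard.Y[perm])
        assert local_loss(shuffled, beta, kernel) == pytest.approx(base, abs=1e-12)

    def test_convex_along_lines(self, small_shard, kernel, rng):
        beta = rng.standard_normal(3)
        d = rng.standard_normal(3)
        ts = np.linspace(-2, 2, 81)
        vals = np.array([local_loss(small_shard, beta + t * d, kernel) for t in ts])
        assert np.all(np.diff(vals, 2) >= -1e-10)


class TestGradients:
    def test_identical_rows_zero_gradient(self, kernel):
        X = np.tile([[1.0, 2.0]], (4, 1))
        shard = Shard(X, [3.0, 1.0, 2.0, 0.5])
        np.testing.assert_allclose(
            local_gradient(shard, np.zeros(2), kernel), 0.0, atol=1e-14
        )

    def test_matches_finite_differences(self, small_shard, kernel, rng):
        beta = rng.standard_normal(3) * 0.5
        fd = central_difference_gradient(
            lambda b: local_loss(small_shard, b, kernel), beta
        )
        np.testing.assert_allclose(
            local_gradient(small_shard, beta, kernel), fd, atol=1e-6
        )

    def test_matches_brute_force(self, small_shard, kernel, rng):
        beta = rng.standard_normal(3)
        expected = brute_pair_gradient(small_shard.X, small_shard.Y, beta, 1.0)
        np.testing.assert_allclose(
            local_gradient(small_shard, beta, kernel), expected, atol=1e-12
        )

    def test_response_shift_leaves_gradient(self, small_shard, kernel, rng):
        beta = rng.standard_normal(3)
        g = local_gradient(small_shard, beta, kernel)
        shifted = Shard(small_shard.X, small_shard.Y + 9.9)
        np.testing.assert_allclose(
            local_gradient(shifted, beta, kernel), g, atol=1e-13
        )


class TestGlobalGradient:
    def test_single_machine_both_modes_equal_local(self, small_shard, kernel, rng):
        ds = DistributedDataset([small_shard])
        beta = rng.standard_normal(3)
        g_local = local_gradient(small_shard, beta, kernel)
        for mode in ("pooled", "machine-average"):
            np.testing.assert_allclose(
                global_gradient(ds, beta, kernel, mode), g_local, atol=1e-14
            )

    def test_machine_average_is_mean_of_shard_gradients(
        self, two_shard_dataset, kernel, rng
    ):
        beta = rng.standard_normal(2)
        grads = [local_gradient(s, beta, kernel) for s in two_shard_dataset.shards]
        np.testing.assert_allclose(
            global_gradient(two_shard_dataset, beta, kernel, "machine-average"),
            np.mean(grads, axis=0),
            atol=1e-15,
        )

    def test_pooled_matches_brute_force_thirty_pairs(
        self, two_shard_dataset, kernel, rng
    ):
        beta = rng.standard_normal(2)
        pooled = two_shard_dataset.concatenated()
        expected = brute_pair_gradient(pooled.X, pooled.Y, beta, 1.0)
        np.testing.assert_allclose(
            global_gradient(two_shard_dataset, beta, kernel, "pooled"),
            expected,
            atol=1e-12,
        )
        assert global_loss(two_shard_dataset, beta, kernel) == pytest.approx(
            brute_pair_loss(pooled.X, pooled.Y, beta, 1.0), abs=1e-12
        )

    def test_unknown_mode_raises(self, two_shard_dataset, kernel):
        with pytest.raises(ValueError):
            global_gradient(two_shard_dataset, np.zeros(2), kernel, "broadcast")


def test_dataset_validation(rng):
    X = rng.standard_normal((6, 2))
    Y = rng.standard_normal(6)
    with pytest.raises(ValueError):
        DistributedDataset.from_arrays(X, Y, m=4)  # 6 rows don't split into 4
    with pytest.raises(ValueError):
        DistributedDataset([])
    with pytest.raises(ValueError):
        Shard(X, Y[:5])
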