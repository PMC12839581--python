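"""Pairwise (U-statistic) convoluted rank losses and gradients.

Each machine holds a shard ``{(Y_i, X_i)}`` and contributes the local loss

    L_hat_{j,h}(beta) = 1/(n(n-1)) * sum_{i != k} L_h(omega_{i,k}),
    omega_{i,k} = (Y_i - X_i'beta) - (Y_k - X_k'beta),

an average over all ordered within-shard pairs of residual differences.
Because L_h' is odd and the pair differences are antisymmetric, the gradient
collapses to a row-sum form that avoids materialising p-dimensional pair
differences: with residuals ``r_i = Y_i - X_i'beta`` and
``w_i = sum_j L_h'(r_i - r_j)``,

    grad_l = -2/(n(n-1)) * sum_i w_i X_{i,l}.

The global objective is the same U-statistic over all N(N-1) pooled pairs.
Since cross-machine pairs require co-resident raw data, a second
"machine-average" mode returns the mean of per-shard local gradients (an
incomplete U-statistic transmitting only p numbers per machine).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelSpec, smoothed_loss, smoothed_loss_derivative

__all__ = [
    "Shard",
    "DistributedDataset",
    "ResidualDiffs",
    "pairwise_residual_diffs",
    "local_loss",
    "local_gradient",
    "global_loss",
    "global_gradient",
]

logger = logging.getLogger(__name__)

# row-chunk size for O(n^2) pairwise broadcasts, keeps peak memory ~64 MB
_CHUNK_ELEMS = 2**23


@dataclass
class Shard:
    """One machine's data block: covariates X (n x p) and responses Y (n)."""

    X: np.ndarray
    Y: np.ndarray
    machine_id: int = 0

    def __post_init__(self):
        self.X = np.ascontiguousarray(np.asarray(self.X, dtype=float))
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D array")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but Y has {self.Y.shape[0]}"
            )
        if self.X.shape[0] < 2:
            raise ValueError("a shard needs at least 2 observations (pairs)")
        if not (np.isfinite(self.X).all() and np.isfinite(self.Y).all()):
            raise ValueError("shard contains non-finite values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def residuals(self, beta: np.ndarray) -> np.ndarray:
        beta = _check_beta(beta, self.p)
        return self.Y - self.X @ beta


@dataclass
class DistributedDataset:
    """An m-way partition of the full sample across node machines."""

    shards: list

    def __post_init__(self):
        if not self.shards:
            raise ValueError("dataset needs at least one shard")
        p = self.shards[0].p
        if any(s.p != p for s in self.shards):
            raise ValueError("all shards must share the covariate dimension")
        sizes = {s.n for s in self.shards}
        if len(sizes) > 1:
            logger.warning("unequal shard sizes %s; common-n conventions use shard 1", sizes)

    @property
    def m(self) -> int:
        return len(self.shards)

    @property
    def N(self) -> int:
        return sum(s.n for s in self.shards)

    @property
    def n(self) -> int:
        return self.shards[0].n

    @property
    def p(self) -> int:
        return self.shards[0].p

    @classmethod
    def from_arrays(cls, X, Y, m: int = None, assignment=None) -> "DistributedDataset":
        """Partition (X, Y) into shards, by an assignment vector or into m
        contiguous equal blocks."""
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float).ravel()
        if assignment is not None:
            assignment = np.asarray(assignment)
            ids = np.unique(assignment)
            shards = [
                Shard(X[assignment == g], Y[assignment == g], machine_id=k + 1)
                for k, g in enumerate(ids)
            ]
        else:
            if m is None or m < 1:
                raise ValueError("need an assignment vector or a machine count m >= 1")
            if X.shape[0] % m:
                raise ValueError(f"{X.shape[0]} rows do not split evenly into m={m} shards")
            n = X.shape[0] // m
            shards = [
                Shard(X[j * n : (j + 1) * n], Y[j * n : (j + 1) * n], machine_id=j + 1)
                for j in range(m)
            ]
        return cls(shards)

    def concatenated(self) -> Shard:
        """All shards pooled into one block (the global-estimator view)."""
        X = np.concatenate([s.X for s in self.shards], axis=0)
        Y = np.concatenate([s.Y for s in self.shards])
        return Shard(X, Y, machine_id=0)


@dataclass
class ResidualDiffs:
    """All ordered-pair residual differences omega_{i,j} within one shard.

    ``omega[i, j] = Y_i - Y_j - (X_i - X_j)'beta`` with zero diagonal;
    antisymmetric by construction.  ``move_coordinate`` applies a rank-one
    O(n^2) update when a single coefficient changes.
    """

    omega: np.ndarray
    beta: np.ndarray = field(repr=False)

    def move_coordinate(self, shard: Shard, l: int, new_value: float) -> None:
        delta = new_value - self.beta[l]
        if delta != 0.0:
            x = shard.X[:, l]
            self.omega -= (x[:, None] - x[None, :]) * delta
            self.beta[l] = new_value


def _check_beta(beta, p: int) -> np.ndarray:
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.shape[0] != p:
        raise ValueError(f"beta has length {beta.shape[0]}, expected p={p}")
    return beta


def pairwise_residual_diffs(shard: Shard, beta) -> ResidualDiffs:
    """Materialise the n x n matrix of residual differences at ``beta``."""
    r = shard.residuals(beta)
    return ResidualDiffs(omega=r[:, None] - r[None, :], beta=_check_beta(beta, shard.p).copy())


def _pair_loss_sum(r: np.ndarray, kernel: KernelSpec) -> float:
    """Sum of L_h over all ordered pairs i != j of residuals (chunked)."""
    n = r.shape[0]
    chunk = max(1, _CHUNK_ELEMS // n)
    total = 0.0
    for s in range(0, n, chunk):
        block = r[s : s + chunk, None] - r[None, :]
        total += float(smoothed_loss(block, kernel).sum())
    # remove the n diagonal terms L_h(0)
    return total - n * float(smoothed_loss(0.0, kernel))


def _pair_derivative_row_sums(r: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """w_i = sum_j L_h'(r_i - r_j) over all j (chunked broadcast)."""
    n = r.shape[0]
    chunk = max(1, _CHUNK_ELEMS // n)
    w = np.empty(n)
    for s in range(0, n, chunk):
        block = r[s : s + chunk, None] - r[None, :]
        w[s : s + chunk] = smoothed_loss_derivative(block, kernel).sum(axis=1)
    return w


def local_loss(shard: Shard, beta, kernel: KernelSpec) -> float:
    """The shard's convoluted rank loss: mean of L_h over ordered pairs."""
    r = shard.residuals(beta)
    n = shard.n
    return _pair_loss_sum(r, kernel) / (n * (n - 1))


def local_gradient(shard: Shard, beta, kernel: KernelSpec) -> np.ndarray:
    """Gradient of the shard loss; entry l is
    ``-1/(n(n-1)) sum_{i!=j} L_h'(omega_ij) (X_il - X_jl)``."""
    r = shard.residuals(beta)
    n = shard.n
    w = _pair_derivative_row_sums(r, kernel)
    return (-2.0 / (n * (n - 1))) * (shard.X.T @ w)


def global_loss(dataset: DistributedDataset, beta, kernel: KernelSpec) -> float:
    """Full-sample U-statistic loss over all N(N-1) pooled pairs."""
    return local_loss(dataset.concatenated(), beta, kernel)


def global_gradient(
    dataset: DistributedDataset, beta, kernel: KernelSpec, mode: str = "pooled"
) -> np.ndarray:
    """Gradient of the global objective.

    ``mode="pooled"``: exact gradient of the N(N-1)-pair U-statistic over the
    concatenated sample (matches the printed global loss; default).
    ``mode="machine-average"``: mean of the per-shard local gradients, the
    incomplete-U approximation a federated deployment would transmit.
    """
    if mode == "pooled":
        return local_gradient(dataset.concatenated(), beta, kernel)
    if mode == "machine-average":
        grads = [local_gradient(s, beta, kernel) for s in dataset.shards]
        return np.mean(grads, axis=0)
    raise ValueError(f"unknown gradient mode {mode!r}")
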