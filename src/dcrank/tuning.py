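"""HBIC tuning-parameter selection and the geometric lambda grid.

The penalty level is selected without cross-validation by the
high-dimensional Bayesian information criterion

    HBIC(lam) = log L(beta_hat_lam) + |M_lam| * (log log n) (log p) / n,

where L is the objective value at the path solution and M_lam its support.
The grid head lambda_{1,1} is the sup-norm of the machine-1 local gradient at
beta = 0 (at which the all-zero vector is still a solution); the grid decays
geometrically over L points spanning one decade.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .kernels import KernelSpec
from .objective import Shard, local_gradient
from .penalties import PenaltySpec
from .solver import SurrogateSpec, solve_penalized_surrogate

__all__ = ["TuningResult", "initial_lambda", "lambda_grid", "hbic", "select_lambda"]

logger = logging.getLogger(__name__)

#: floor applied to the (possibly nonpositive) surrogate loss inside log()
HBIC_LOSS_FLOOR = 1e-12


@dataclass
class TuningResult:
    """Lambda path summary: decreasing grid, HBIC values, support sizes and
    the index of the minimiser (ties broken toward larger lambda)."""

    grid: np.ndarray
    hbic_values: np.ndarray
    support_sizes: np.ndarray
    chosen_index: int

    @property
    def chosen_lambda(self) -> float:
        return float(self.grid[self.chosen_index])

    @property
    def path(self) -> list:
        """(lambda, HBIC, support size) triples along the grid."""
        return [
            (float(l), float(h), int(s))
            for l, h, s in zip(self.grid, self.hbic_values, self.support_sizes)
        ]


def initial_lambda(shard: Shard, kernel: KernelSpec) -> float:
    """Grid head lambda_{1,1}: sup-norm of the machine-1 rank-loss gradient
    at beta = 0 (computed from raw response differences only)."""
    return float(np.abs(local_gradient(shard, np.zeros(shard.p), kernel)).max())


def lambda_grid(lambda_head: float, L: int = 50) -> np.ndarray:
    """Decreasing geometric grid of length L with ratio 0.1^{1/(L-1)}, so the
    last value is exactly one tenth of the head."""
    if not (lambda_head > 0):
        raise ValueError("lambda_head must be positive")
    if L < 2:
        raise ValueError("grid needs at least 2 points")
    ratio = 0.1 ** (1.0 / (L - 1))
    return lambda_head * ratio ** np.arange(L)


def hbic(surrogate_loss_value: float, support_size: int, n: int, p: int) -> float:
    """HBIC value; natural logs throughout.

    The surrogate loss can be nonpositive because of its linear shift term;
    it is floored at 1e-12 (with a warning) so the criterion stays total.
    """
    if n < 3:
        raise ValueError("HBIC needs n >= 3 so that log log n is positive")
    if p < 2:
        raise ValueError("HBIC needs p >= 2")
    if surrogate_loss_value < HBIC_LOSS_FLOOR:
        warnings.warn(
            "nonpositive surrogate loss floored at 1e-12 inside HBIC", RuntimeWarning
        )
        surrogate_loss_value = HBIC_LOSS_FLOOR
    return float(
        np.log(surrogate_loss_value)
        + support_size * np.log(np.log(n)) * np.log(p) / n
    )


def select_lambda(
    shard1: Shard,
    surrogate: SurrogateSpec,
    grid,
    penalty: PenaltySpec,
    kernel: KernelSpec,
    beta_init=None,
    tol: float = 1e-7,
    max_sweeps: int = 500,
    path_max_sweeps: int = 100,
):
    """Warm-started path solve over a decreasing grid with HBIC selection.

    For each lambda (largest first) the penalized surrogate problem is solved
    on machine 1, warm-starting from the previous solution; the HBIC uses the
    surrogate loss value at the solution (which is the plain local loss when
    the shift is zero, i.e. for the initial local fit).  Ties are broken
    toward the larger lambda (the sparser model).

    Path solves run under a smaller sweep budget (``path_max_sweeps``, the
    usual pathwise-optimisation economy); the chosen lambda is then refit to
    the full budget, warm-started from its path solution, so the returned
    estimate always honours ``tol``/``max_sweeps``.

    Path solutions in the regime the side constraint of the penalized
    surrogate problem is meant to exclude — a diverged solve, or a
    nonpositive surrogate loss (where the floored HBIC would be spuriously
    small) — are recorded on the path but skipped by the argmin unless no
    valid fit exists.

    Returns ``(TuningResult, beta_at_chosen_lambda, reports)``.
    """
    from .solver import _pair_loss_nb  # local import avoids a cycle in docs tools

    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError("grid must be a nonempty 1-D array")
    if grid.size > 1 and np.any(np.diff(grid) >= 0):
        raise ValueError("grid must be strictly decreasing")
    n, p = shard1.n, shard1.p
    beta = (
        np.zeros(p) if beta_init is None else np.asarray(beta_init, dtype=float).copy()
    )
    last_valid = beta.copy()
    hbics = np.empty(grid.size)
    supports = np.empty(grid.size, dtype=int)
    best = None
    best_idx = None
    best_any = None
    best_any_idx = 0
    reports = []
    budget = min(path_max_sweeps, max_sweeps)
    for i, lam in enumerate(grid):
        pen = replace(penalty, lam=float(lam))
        rep = solve_penalized_surrogate(
            shard1, surrogate, pen, kernel, beta_init=beta, tol=tol, max_sweeps=budget
        )
        beta = rep.beta
        reports.append(rep)
        r = shard1.Y - shard1.X @ beta
        loss = float(_pair_loss_nb(r, kernel.h)) - float(surrogate.shift @ beta)
        supports[i] = int(np.count_nonzero(beta))
        hbics[i] = hbic(loss, supports[i], n, p)
        # A non-converged but bounded fit is still a meaningful (imprecise)
        # minimiser and keeps its HBIC; only the pathological regime the
        # side constraint excludes (divergence, nonpositive surrogate loss)
        # is barred from selection.
        valid = (not rep.diverged) and loss >= HBIC_LOSS_FLOOR
        if valid:
            last_valid = beta.copy()
            # strict <: earlier (larger) lambda wins ties
            if best is None or hbics[i] < best:
                best = hbics[i]
                best_idx = i
                best_beta = beta.copy()
        else:
            logger.warning(
                "lambda=%.4g excluded from HBIC selection (diverged=%s, "
                "surrogate loss %.3g)", lam, rep.diverged, loss,
            )
            beta = last_valid.copy()  # do not poison later warm starts
        if best_any is None or hbics[i] < best_any:
            best_any = hbics[i]
            best_any_idx = i
    if best_idx is None:  # no valid fit anywhere: fall back to the raw argmin
        logger.warning("no valid path fit; falling back to the floored HBIC argmin")
        best_idx = best_any_idx
        best_beta = reports[best_idx].beta.copy()
    if not reports[best_idx].usable and max_sweeps > budget:
        # refit the winner to the full budget from its path solution
        pen = replace(penalty, lam=float(grid[best_idx]))
        rep = solve_penalized_surrogate(
            shard1, surrogate, pen, kernel, beta_init=best_beta,
            tol=tol, max_sweeps=max_sweeps,
        )
        if not rep.diverged:
            best_beta = rep.beta
            reports[best_idx] = rep
    if supports.max() == supports.min() and supports.max() in (0, p):
        logger.warning("all path fits degenerate (support sizes all %d)", supports.max())
    result = TuningResult(
        grid=grid, hbic_values=hbics, support_sizes=supports, chosen_index=int(best_idx)
    )
    return result, best_beta, reports
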