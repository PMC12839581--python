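"""Folded-concave and L1 penalties: SCAD (default), MCP and the lasso.

SCAD with tuning parameter lambda and shape a > 2 (default 3.7):

    p_lam(t) = lam*t                          for 0 <= t < lam,
             = (a*lam*t - (t^2+lam^2)/2)/(a-1) for lam <= t <= a*lam,
             = (a+1)*lam^2/2                   for t > a*lam,

linear near zero (so small coefficients are thresholded like the lasso),
quadratic transition, constant tail (so large coefficients are unbiased).
MCP: derivative max(lam - t/gamma, 0), gamma > 1.  L1 is the convex boundary
case.  All families are even, vanish at zero, are nondecreasing on [0, inf)
and have p_lam(t)/t nonincreasing — the properties the LLA solver relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PenaltySpec", "penalty_value", "penalty_derivative"]

_DEFAULT_SHAPE = {"scad": 3.7, "mcp": 3.0, "l1": None}


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty family with level ``lam`` >= 0 and shape parameter.

    ``shape`` is a for SCAD (must exceed 2; default 3.7) or gamma for MCP
    (must exceed 1); ignored for L1.  ``lam`` is constant across
    communication rounds (lambda_t = lambda_1).
    """

    family: str = "scad"
    lam: float = 0.0
    shape: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.family not in _DEFAULT_SHAPE:
            raise ValueError(f"unknown penalty family {self.family!r}")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.shape is None:
            object.__setattr__(self, "shape", _DEFAULT_SHAPE[self.family])
        if self.family == "scad" and not (self.shape > 2):
            raise ValueError("SCAD requires shape a > 2")
        if self.family == "mcp" and not (self.shape > 1):
            raise ValueError("MCP requires shape gamma > 1")


def penalty_value(t, spec: PenaltySpec):
    """p_lam(|t|), vectorised and even in t."""
    t = np.abs(np.asarray(t, dtype=float))
    lam, a = spec.lam, spec.shape
    if spec.family == "l1":
        out = lam * t
    elif spec.family == "scad":
        out = np.where(
            t < lam,
            lam * t,
            np.where(
                t <= a * lam,
                (a * lam * t - 0.5 * (t * t + lam * lam)) / (a - 1),
                0.5 * (a + 1) * lam * lam,
            ),
        )
    else:  # mcp
        out = np.where(t <= a * lam, lam * t - t * t / (2 * a), 0.5 * a * lam * lam)
    return out if out.ndim else float(out)


def penalty_derivative(t, spec: PenaltySpec):
    """p_lam'(t) for t >= 0 (callers pass absolute values).

    The right derivative at 0 equals lam for SCAD/MCP/L1 (k8 = 1), which is
    what makes the lambda-grid head a genuine all-zero threshold.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("penalty_derivative expects nonnegative t; pass |t|")
    lam, a = spec.lam, spec.shape
    if spec.family == "l1":
        out = np.full_like(t, lam)
    elif spec.family == "scad":
        out = np.where(
            t < lam, lam, np.where(t <= a * lam, (a * lam - t) / (a - 1), 0.0)
        )
    else:  # mcp
        out = np.maximum(lam - t / a, 0.0)
    return out if out.ndim else float(out)
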