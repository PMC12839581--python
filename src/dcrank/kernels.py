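"""Smoothing kernels and the convolution-smoothed rank loss.

The Wilcoxon rank loss ``|u|`` is convex but not differentiable at the
origin, which complicates high-dimensional optimisation.  Convolving it with
a compactly supported kernel density ``K_h(v) = K(v/h)/h`` yields the smooth
convex loss

    L_h(u) = \\int |u - v| K_h(v) dv,

which equals ``|u|`` outside ``[-h, h]`` and is a polynomial inside.  The
population minimiser of the induced pairwise rank objective coincides with
the true regression coefficient for every bandwidth ``h > 0``, so ``h``
controls numerical smoothness only; the default is ``h = 1``.

For the Epanechnikov kernel ``K(u) = (3/4)(1 - u^2)`` on ``[-1, 1]`` the
loss has the closed form

    L_h(u) = 3u^2/(4h) - u^4/(8h^3) + 3h/8       for |u| < h,
    L_h(u) = |u|                                  for |u| >= h,

with derivative ``3u/(2h) - u^3/(2h^3)`` inside and ``sign(u)`` outside.
Other symmetric densities on ``[-1, 1]`` are accepted and evaluated by
Gauss-Legendre quadrature, but the Epanechnikov closed form is the supported
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KernelSpec", "kernel_value", "smoothed_loss", "smoothed_loss_derivative"]

#: supremum of each named kernel over its support (the k6 curvature constant)
_KERNEL_SUP = {"epanechnikov": 0.75, "uniform": 0.5, "triangular": 1.0}


def kernel_value(v, name: str = "epanechnikov"):
    """Evaluate the kernel density K at ``v`` (vectorised, total function).

    All supported kernels are symmetric probability densities on [-1, 1]:
    Epanechnikov ``(3/4)(1 - v^2)``, uniform ``1/2`` and triangular
    ``1 - |v|``, each multiplied by the indicator of the support.
    """
    v = np.asarray(v, dtype=float)
    inside = np.abs(v) <= 1.0
    if name == "epanechnikov":
        out = np.where(inside, 0.75 * (1.0 - v * v), 0.0)
    elif name == "uniform":
        out = np.where(inside, 0.5, 0.0)
    elif name == "triangular":
        out = np.where(inside, 1.0 - np.abs(v), 0.0)
    else:
        raise ValueError(f"unknown kernel {name!r}")
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class KernelSpec:
    """A smoothing kernel with bandwidth.

    Attributes
    ----------
    name : str
        Kernel identifier; ``"epanechnikov"`` (default), ``"uniform"`` or
        ``"triangular"``.
    h : float
        Bandwidth, strictly positive.  Default 1.0.
    k6 : float
        Supremum of K over its support; enters the quadratic-majorizer
        curvature ``2 k6 / h`` used by the coordinate solver.  Filled in
        automatically from the kernel name.
    """

    name: str = "epanechnikov"
    h: float = 1.0
    k6: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.name not in _KERNEL_SUP:
            raise ValueError(f"unknown kernel {self.name!r}")
        if not (self.h > 0):
            raise ValueError(f"bandwidth must be positive, got {self.h}")
        if self.k6 is None:
            object.__setattr__(self, "k6", _KERNEL_SUP[self.name])
        elif not (self.k6 > 0):
            raise ValueError("k6 must be positive")

    def value(self, v):
        return kernel_value(v, self.name)


def _gauss_legendre_nodes(order: int = 96):
    x, w = np.polynomial.legendre.leggauss(order)
    return x, w


def smoothed_loss(u, kernel: KernelSpec):
    """Convolution-smoothed rank loss L_h(u) (vectorised).

    Closed form for the Epanechnikov kernel; Gauss-Legendre quadrature of
    ``\\int |u - hv| K(v) dv`` for the other supported kernels.
    """
    u = np.asarray(u, dtype=float)
    h = kernel.h
    if kernel.name == "epanechnikov":
        au = np.abs(u)
        u2 = u * u
        inner = 0.75 * u2 / h - 0.125 * u2 * u2 / h**3 + 0.375 * h
        out = np.where(au >= h, au, inner)
    else:
        x, w = _gauss_legendre_nodes()
        kv = kernel.value(x) * w
        out = np.abs(u[..., None] - h * x) @ kv
    return out if out.ndim else float(out)


def smoothed_loss_derivative(u, kernel: KernelSpec):
    """Derivative L_h'(u): odd, bounded in [-1, 1], equals sign(u) for |u| >= h."""
    u = np.asarray(u, dtype=float)
    h = kernel.h
    if kernel.name == "epanechnikov":
        t = u / h
        inner = 1.5 * t - 0.5 * t**3
        out = np.where(np.abs(u) >= h, np.sign(u), inner)
    else:
        x, w = _gauss_legendre_nodes()
        kv = kernel.value(x) * w
        out = np.sign(u[..., None] - h * x) @ kv
    return out if out.ndim else float(out)
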