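"""Independent reference implementations used as test oracles.

Everything here is written from the defining formulas by direct summation or
enumeration (naive double loops, 1-D grid search), deliberately sharing no
code with the package's vectorised / compiled paths.
"""

import numpy as np


def epa_loss(u: float, h: float) -> float:
    """Epanechnikov-smoothed rank loss, scalar closed form."""
    if abs(u) >= h:
        return abs(u)
    return 3 * u**2 / (4 * h) - u**4 / (8 * h**3) + 3 * h / 8


def epa_deriv(u: float, h: float) -> float:
    if u >= h:
        return 1.0
    if u <= -h:
        return -1.0
    return 3 * u / (2 * h) - u**3 / (2 * h**3)


def brute_pair_loss(X, Y, beta, h) -> float:
    """Mean of L_h over all ordered residual-difference pairs, naive loop."""
    X, Y, beta = np.asarray(X, float), np.asarray(Y, float), np.asarray(beta, float)
    n = len(Y)
    r = Y - X @ beta
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                total += epa_loss(r[i] - r[j], h)
    return total / (n * (n - 1))


def brute_pair_gradient(X, Y, beta, h) -> np.ndarray:
    """Gradient of brute_pair_loss by direct summation over ordered pairs."""
    X, Y, beta = np.asarray(X, float), np.asarray(Y, float), np.asarray(beta, float)
    n, p = X.shape
    r = Y - X @ beta
    g = np.zeros(p)
    for i in range(n):
        for j in range(n):
            if i != j:
                g -= epa_deriv(r[i] - r[j], h) * (X[i] - X[j])
    return g / (n * (n - 1))


def central_difference_gradient(f, beta, eps=1e-6) -> np.ndarray:
    beta = np.asarray(beta, float)
    g = np.zeros_like(beta)
    for l in range(beta.size):
        e = np.zeros_like(beta)
        e[l] = eps
        g[l] = (f(beta + e) - f(beta - e)) / (2 * eps)
    return g


def scad_value(t, lam, a=3.7) -> float:
    t = abs(t)
    if t < lam:
        return lam * t
    if t <= a * lam:
        return (a * lam * t - (t**2 + lam**2) / 2) / (a - 1)
    return (a + 1) * lam**2 / 2


def grid_minimize(f, lo, hi, res=1e-4) -> float:
    """Argmin of a scalar function on [lo, hi] by exhaustive grid search."""
    grid = np.arange(lo, hi + res, res)
    vals = np.array([f(b) for b in grid])
    return float(grid[np.argmin(vals)])


def reference_cd_solver(X, Y, shift, lam, a, h, k6, beta0, tol=1e-7, max_sweeps=500):
    """Plain-python LLA coordinate descent on the naive double-loop objective.

    Uses the same closed-form coordinate update as the paper's algorithm but
    recomputes every pairwise quantity from scratch by brute force at each
    step — an independent check on the package's incremental compiled path.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n, p = X.shape
    beta = np.asarray(beta0, float).copy()
    ups2 = np.array(
        [
            sum(
                (X[i, l] - X[j, l]) ** 2
                for i in range(n)
                for j in range(n)
                if i != j
            )
            / (n * (n - 1))
            for l in range(p)
        ]
    )
    for _ in range(max_sweeps):
        pen_w = np.array(
            [
                lam
                if abs(b) < lam
                else max(a * lam - abs(b), 0.0) / (a - 1)
                for b in beta
            ]
        )
        maxd2 = 0.0
        for l in range(p):
            if ups2[l] <= 0:
                beta[l] = 0.0
                continue
            u1 = brute_pair_gradient(X, Y, beta, h)[l]
            step = h / (2 * ups2[l] * k6)
            z = beta[l] - step * (u1 - shift[l])
            new = np.sign(z) * max(abs(z) - step * pen_w[l], 0.0)
            maxd2 = max(maxd2, (new - beta[l]) ** 2)
            beta[l] = new
        if maxd2 < tol:
            break
    return beta
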