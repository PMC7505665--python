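"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the code paths they check: the SVM oracle solves
the dual quadratic program with a generic constrained optimizer, the FDR
oracle applies the step-up rule literally, the octant oracle walks
explicit angle ranges, and the sphere oracle enumerates lattice points.
"""

import numpy as np
from scipy import optimize


def qp_svm(X, y, C=1.0):
    """Linear soft-margin SVM via its dual QP (SLSQP), returning (w, b)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    Yx = y[:, None] * X
    Q = Yx @ Yx.T
    cons = {
        "type": "eq",
        "fun": lambda a: a @ y,
        "jac": lambda a: y,
    }
    res = optimize.minimize(
        lambda a: 0.5 * a @ Q @ a - a.sum(),
        np.full(n, 0.01),
        jac=lambda a: Q @ a - np.ones(n),
        method="SLSQP",
        bounds=[(0.0, C)] * n,
        constraints=[cons],
        options={"maxiter": 5000, "ftol": 1e-16},
    )
    a = res.x
    w = (a * y) @ X
    margin = (a > 1e-5 * C) & (a < C * (1 - 1e-5))
    b = float(np.mean(y[margin] - X[margin] @ w)) if margin.any() else 0.0
    return w, b


def bh_stepup(p, q):
    """Literal Benjamini-Hochberg step-up: reject all p <= p[(k)] where
    k = max{i : p[(i)] <= i*q/m}."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order]
    below = np.flatnonzero(ranked <= (np.arange(1, m + 1) * q / m))
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below[-1] + 1]] = True
    return reject


def octant_by_angle(zx, zy):
    """Explicit angle-range octant rule (boundary joins the sector it opens).

    Octant layout on the (x, y) weight plane: O1 centred at 90 degrees,
    then clockwise O2 at 45, O3 at 0, O4 at -45, O5 at -90, O6 at -135,
    O7 at 180, O8 at 135.
    """
    theta = np.degrees(np.arctan2(zy, zx))
    if 67.5 <= theta < 112.5:
        return 1
    if 22.5 <= theta < 67.5:
        return 2
    if -22.5 <= theta < 22.5:
        return 3
    if -67.5 <= theta < -22.5:
        return 4
    if -112.5 <= theta < -67.5:
        return 5
    if -157.5 <= theta < -112.5:
        return 6
    if theta >= 157.5 or theta < -157.5:
        return 7
    return 8  # 112.5 <= theta < 157.5


def sphere_count(radius):
    """Enumerate integer lattice points with squared norm <= radius^2."""
    r = int(np.ceil(radius))
    count = 0
    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dz in range(-r, r + 1):
                if dx * dx + dy * dy + dz * dz <= radius * radius + 1e-9:
                    count += 1
    return count
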