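"""Independent brute-force oracles used to validate the analytic mechanics.

Everything here deliberately avoids the package's elastica/elliptic code
paths: rods are discretized into bending-spring chains and handled with
generic eigenvalue and constrained-minimization machinery.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize


def discretized_buckling_force(h: float, kappa: float, n_seg: int = 400) -> float:
    """Critical load of an N-segment pinned chain from the Hessian zero crossing.

    Segments of length ds with bending springs kappa/ds at interior joints;
    pinned ends impose zero net transverse displacement (sum of tangent
    angles zero to linear order).  The straight state loses stability when
    the smallest eigenvalue of the projected bending Hessian equals F*ds.
    """
    ds = h / n_seg
    lap = np.zeros((n_seg, n_seg))
    for i in range(n_seg - 1):
        lap[i, i] += 1.0
        lap[i + 1, i + 1] += 1.0
        lap[i, i + 1] -= 1.0
        lap[i + 1, i] -= 1.0
    # project out the uniform rotation (forbidden by the pinned-end closure)
    ones = np.ones((n_seg, 1)) / np.sqrt(n_seg)
    proj = np.eye(n_seg) - ones @ ones.T
    evals = eigh(proj @ lap @ proj, eigvals_only=True)
    lam = np.min(evals[evals > 1e-10])
    return kappa / ds * lam / ds


def discretized_elastica_energy(h: float, x: float, kappa: float,
                                n_seg: int = 120) -> float:
    """Minimum bending energy of a pinned chain at fixed end-to-end distance.

    Tangent angles theta_i are optimized under the two closure constraints
    (end-to-end projection x, zero transverse offset) with SLSQP.  Returns
    energy in the same units as kappa*length^-1.
    """
    ds = h / n_seg
    s = (np.arange(n_seg) + 0.5) / n_seg

    def energy(theta):
        return kappa / (2 * ds) * np.sum(np.diff(theta) ** 2)

    def grad(theta):
        g = np.zeros_like(theta)
        d = np.diff(theta)
        g[:-1] -= kappa / ds * d
        g[1:] += kappa / ds * d
        return g

    cons = [
        {"type": "eq", "fun": lambda th: ds * np.sum(np.cos(th)) - x},
        {"type": "eq", "fun": lambda th: ds * np.sum(np.sin(th))},
    ]
    # first-mode-like initial guess with the right end shortening scale
    amp = 1.2 * np.sqrt(max(2.0 * (1.0 - x / h), 1e-6))
    best = None
    for a0 in (amp, 1.5 * amp):
        theta0 = a0 * np.cos(np.pi * s)
        res = minimize(energy, theta0, jac=grad, constraints=cons,
                       method="SLSQP",
                       options={"maxiter": 800, "ftol": 1e-12})
        if res.success and (best is None or res.fun < best):
            best = res.fun
    if best is None:
        raise RuntimeError("discretized elastica minimization failed")
    return best


def discretized_teardrop_ratio(n_seg: int = 90) -> float:
    """Energy of a closed one-hinge chain relative to the closed circle.

    The joint between the last and first segment is a free hinge (no
    bending spring); closure requires the endpoint displacements to vanish.
    Pure geometry: the ratio is independent of kappa and size.
    """
    kappa, length = 1.0, 1.0
    ds = length / n_seg

    def energy(theta):
        return kappa / (2 * ds) * np.sum(np.diff(theta) ** 2)

    cons = [
        {"type": "eq", "fun": lambda th: ds * np.sum(np.cos(th))},
        {"type": "eq", "fun": lambda th: ds * np.sum(np.sin(th))},
    ]
    s = (np.arange(n_seg) + 0.5) / n_seg
    alpha = np.radians(130.0)
    theta0 = alpha * (1.0 - 2.0 * s)  # teardrop-like: turn from +alpha to -alpha
    res = minimize(energy, theta0, constraints=cons, method="SLSQP",
                   options={"maxiter": 2000, "ftol": 1e-14})
    assert res.success, res.message
    circle = 2.0 * np.pi ** 2 * kappa / length
    return res.fun / circle


def common_tangent_points(a1: float, a2: float, eps: float) -> tuple[float, float]:
    """Tangent points of the lower common tangent of y=a1 c^2 and y=eps+a2 c^2.

    Found by matching the Legendre intercepts of the two parabolas with a
    bracketed root solve (independent of the closed-form construction).
    """
    from scipy.optimize import brentq

    def gap(slope):
        b1 = -slope ** 2 / (4 * a1)
        b2 = eps - slope ** 2 / (4 * a2)
        return b1 - b2

    s = brentq(gap, 1e-12, 1e6)
    return s / (2 * a1), s / (2 * a2)


def spearman_p_enumeration(rx: np.ndarray, ry: np.ndarray) -> float:
    """Two-sided exact Spearman p-value by plain-Python permutation count."""
    import itertools
    import math

    n = len(rx)
    denom = n * (n * n - 1)
    d = rx - ry
    rho_obs = 1.0 - 6.0 * float(np.dot(d, d)) / denom
    count = 0
    for perm in itertools.permutations(range(1, n + 1)):
        dd = sum((perm[i] - rx[i]) ** 2 for i in range(n))
        rho = 1.0 - 6.0 * dd / denom
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / math.factorial(n)
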