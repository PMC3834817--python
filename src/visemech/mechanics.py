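"""Continuum mechanics of double- and single-stranded DNA.

Covers the mechanical primitives the vise model is built from:

* Euler buckling threshold of a short duplex (critical force and the
  buckling length at the constant ~9 pN base-pairing force),
* planar hinged-hinged elastica shapes and bending energies at fixed end
  shortening (the post-buckling conformations of the target strand),
* closed minicircle energetics with 0, 1 (teardrop) or 2 flexible kinks,
* force-extension thermodynamics of single-stranded DNA modelled as an
  extensible freely jointed chain (FJC).

The elastica is handled through the classical pendulum solution.  Writing
``k = sin(alpha/2)`` for the end tangent angle ``alpha``, a pinned-pinned
first-mode buckled rod of contour ``h`` and end-to-end distance ``x``
satisfies

    x/h = 2 E(k)/K(k) - 1,        F = kappa (2 K(k)/h)^2,

with K, E the complete elliptic integrals, and its bending energy has the
closed form ``U = F (x - h (1 - 2 k^2))``.  These relations are tabulated
once on a fine grid of ``x/h`` and interpolated, which makes ensemble sums
over many thousands of states cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp
from scipy.optimize import brentq
from scipy.special import ellipe, ellipk

from .params import MechParams, ParameterError


class DomainError(ValueError):
    """Raised when an argument is outside the physically meaningful domain."""


class SolverError(RuntimeError):
    """Raised when a boundary-value or root solve fails to converge."""


# ---------------------------------------------------------------------------
# Euler buckling
# ---------------------------------------------------------------------------

def buckling_force(h: float, params: MechParams) -> float:
    """Critical Euler buckling force pi^2 kappa / h^2 of a rod of length h (nm) in pN."""
    h = float(h)
    if h <= 0:
        raise DomainError(f"rod length must be > 0, got {h}")
    return np.pi ** 2 * params.kappa / h ** 2


def buckling_length(force: float, params: MechParams) -> float:
    """Buckling length pi*sqrt(kappa/F) at constant compressive force (pN) in nm.

    Exact inverse of :func:`buckling_force`.  Divide by ``params.rise_ds``
    for the equivalent length in base pairs.
    """
    force = float(force)
    if force <= 0:
        raise DomainError(f"force must be > 0, got {force}")
    return np.pi * np.sqrt(params.kappa / force)


def buckling_length_bp(force: float, params: MechParams) -> float:
    """Buckling length at constant force expressed in base pairs."""
    return buckling_length(force, params) / params.rise_ds


def arc_bending_energy(contour: float, radius: float, params: MechParams) -> float:
    """WLC bending energy kappa*L/(2 R^2) of a constant-curvature arc, in kBT.

    For a closed circle (``radius = contour / 2 pi``) this equals
    ``2 pi^2 kappa / L``, the minicircle ground-state energy.
    """
    if contour <= 0 or radius <= 0:
        raise DomainError("contour and radius must be > 0")
    return params.kappa * contour / (2.0 * radius ** 2) / params.kbt


# ---------------------------------------------------------------------------
# Elastica (pinned-pinned, planar, first mode)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElasticaSolution:
    """One planar pinned-pinned elastica at fixed end shortening.

    Attributes
    ----------
    rod_length, end_to_end:
        Contour h and end-to-end distance x (nm).
    energy:
        Bending energy (kBT); zero iff the rod is straight.
    shape:
        Sampled centreline, array of (s, x, y) rows in nm.
    max_curvature:
        Peak local curvature in degrees per base pair.
    mode_parameter:
        Elliptic modulus k = sin(alpha/2) of the pendulum solution.
    """

    rod_length: float
    end_to_end: float
    energy: float
    shape: np.ndarray
    max_curvature: float
    mode_parameter: float


def _rho_of_k(k: float) -> float:
    m = k * k
    return 2.0 * ellipe(m) / ellipk(m) - 1.0


@lru_cache(maxsize=1)
def _elastica_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Tabulate k(rho), u(rho) and c(rho) for rho = x/h on a fine grid.

    u is the dimensionless bending energy ``U h / kappa`` and c the
    dimensionless peak curvature ``c_max * h``.
    """
    rho = np.linspace(1e-4, 1.0, 4001)
    k = np.empty_like(rho)
    k[-1] = 0.0
    for i, r in enumerate(rho[:-1]):
        k[i] = brentq(lambda kk: _rho_of_k(kk) - r, 1e-12, 0.9999999, xtol=1e-14)
    m = k * k
    bigk = ellipk(m)
    u = 4.0 * bigk ** 2 * (rho - 1.0 + 2.0 * k * k)
    u[-1] = 0.0
    c = 4.0 * bigk * k  # c_max * h = 2 sqrt(F/kappa) k * h = 4 K k
    return rho, k, u, c


def elastica_energy(h, x, params: MechParams):
    """Bending energy (kBT) of a pinned-pinned elastica of contour ``h`` at end-to-end ``x``.

    Vectorized over ``x`` (nm).  ``x = h`` gives exactly 0.
    """
    x = np.asarray(x, dtype=float)
    if h <= 0:
        raise DomainError("contour must be > 0")
    if np.any(x <= 0) or np.any(x > h * (1 + 1e-12)):
        raise DomainError("end-to-end distance must satisfy 0 < x <= h")
    rho_grid, _, u_grid, _ = _elastica_tables()
    u = np.interp(np.minimum(x / h, 1.0), rho_grid, u_grid)
    return (params.kappa / h) * u / params.kbt


def elastica_profile(h: float, end_to_end: float, params: MechParams,
                     n_points: int = 201) -> ElasticaSolution:
    """Solve the minimum-energy buckled shape at fixed end shortening.

    The rod is inextensible, planar, pinned (torque-free) at both ends and
    in its first buckling mode; ``end_to_end = h`` returns the straight rod.
    """
    if h <= 0:
        raise DomainError("contour must be > 0")
    if end_to_end <= 0 or end_to_end > h * (1 + 1e-12):
        raise DomainError("end-to-end distance must satisfy 0 < x <= h")
    rho = min(end_to_end / h, 1.0)
    if rho >= 1.0 - 1e-13:
        s = np.linspace(0.0, h, n_points)
        shape = np.column_stack([s, s, np.zeros_like(s)])
        return ElasticaSolution(h, h, 0.0, shape, 0.0, 0.0)
    try:
        k = brentq(lambda kk: _rho_of_k(kk) - rho, 1e-12, 0.9999999, xtol=1e-14)
    except ValueError as exc:  # pragma: no cover - brentq bracket is analytic
        raise SolverError(f"elastica solve failed for rho={rho}: {exc}") from exc
    m = k * k
    bigk = ellipk(m)
    force = params.kappa * (2.0 * bigk / h) ** 2
    energy = force * (end_to_end - h * (1.0 - 2.0 * k * k)) / params.kbt
    alpha = 2.0 * np.arcsin(k)

    # integrate the pendulum equation theta'' = -(F/kappa) sin(theta) from a
    # moment-free end (theta(0)=alpha, theta'(0)=0) to obtain the centreline
    lam2 = params.kappa / force

    def rhs(s, y):
        theta, dtheta, _, _ = y
        return [dtheta, -np.sin(theta) / lam2, np.cos(theta), np.sin(theta)]

    s_eval = np.linspace(0.0, h, n_points)
    sol = solve_ivp(rhs, (0.0, h), [alpha, 0.0, 0.0, 0.0], t_eval=s_eval,
                    rtol=1e-10, atol=1e-12, method="RK45")
    if not sol.success:
        raise SolverError(f"elastica shape integration failed: {sol.message}")
    shape = np.column_stack([sol.t, sol.y[2], sol.y[3]])
    c_max = 2.0 * np.sqrt(force / params.kappa) * k  # rad/nm, at the midpoint
    max_curv_deg_per_bp = np.degrees(c_max * params.rise_ds)
    return ElasticaSolution(h, end_to_end, energy, shape, max_curv_deg_per_bp, k)


# ---------------------------------------------------------------------------
# Minicircles: circle, teardrop, doubly kinked
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def teardrop_energy_ratio() -> float:
    """Energy of the one-hinge closed elastica ('teardrop') over the circle's.

    Within the closed one-hinge pendulum-elastica family the closure
    constraint ``2 E(k) = K(k)`` determines the shape uniquely; its bending
    energy relative to the closed circle ``2 pi^2 kappa / L`` is a pure
    number (independent of size and stiffness), approximately 0.712.
    """
    kstar = brentq(lambda k: 2.0 * ellipe(k * k) - ellipk(k * k), 0.5, 0.999,
                   xtol=1e-15)
    m = kstar * kstar
    bigk = ellipk(m)
    return float(4.0 * bigk ** 2 * (2.0 * m - 1.0) / (2.0 * np.pi ** 2))


def minicircle_energy(circ_bp: int, n_kinks: int, params: MechParams) -> float:
    """Bending energy (kBT) of a DNA minicircle with 0, 1 or 2 flexible kinks.

    Kinks are fully flexible torque-free hinges and torsion is ignored.  One
    kink relaxes the circle to the teardrop; two diametrically opposite kinks
    fold the circle into two straight arms with zero bending energy.
    """
    if circ_bp < 3:
        raise DomainError("minicircle must contain at least 3 bp")
    if n_kinks not in (0, 1, 2):
        raise DomainError(f"n_kinks must be 0, 1 or 2, got {n_kinks}")
    contour = circ_bp * params.rise_ds
    circle = 2.0 * np.pi ** 2 * params.kappa / contour / params.kbt
    if n_kinks == 0:
        return circle
    if n_kinks == 1:
        return circle * teardrop_energy_ratio()
    return 0.0


# ---------------------------------------------------------------------------
# Single-stranded DNA: extensible freely jointed chain
# ---------------------------------------------------------------------------

_SS_FMAX = 300.0  # pN; beyond this the chain is treated as inextensible


def _langevin(u):
    u = np.asarray(u, dtype=float)
    small = u < 1e-4
    with np.errstate(over="ignore"):
        out = np.where(small, u / 3.0, 1.0 / np.tanh(np.where(small, 1.0, u))
                       - 1.0 / np.where(small, 1.0, u))
    return out


@lru_cache(maxsize=8)
def _ss_tables(ss_kuhn: float, ss_stretch_mod: float, kbt: float
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-nucleotide FJC tables: fractional extension xi(F), and the reduced
    stretching free energy e(xi) = integral F dxi (units pN, per unit contour).

    ``xi`` is extension over contour; multiply energies by the contour length
    to get pN nm.
    """
    force = np.concatenate([np.linspace(0.0, 30.0, 3001),
                            np.linspace(30.02, _SS_FMAX, 2700)])
    u = force * ss_kuhn / kbt
    xi = _langevin(u) * (1.0 + force / ss_stretch_mod)
    # e(xi): integral of F dxi along the curve
    e = cumulative_trapezoid(force, xi, initial=0.0)
    return xi, force, e


def _ss_reduced_energy(xi, params: MechParams):
    """Reduced FJC stretching energy per unit contour (pN) at fractional extension xi.

    Returns ``inf`` beyond the maximum extension reachable at 300 pN.
    """
    xi = np.asarray(xi, dtype=float)
    xi_grid, _, e_grid = _ss_tables(params.ss_kuhn, params.ss_stretch_mod, params.kbt)
    out = np.interp(xi, xi_grid, e_grid)
    return np.where(xi > xi_grid[-1], np.inf, out)


def ss_max_extension(n_nt, params: MechParams):
    """Largest extension (nm) of an n-nt ssDNA reachable within the force table."""
    xi_grid, _, _ = _ss_tables(params.ss_kuhn, params.ss_stretch_mod, params.kbt)
    return np.asarray(n_nt, dtype=float) * params.ss_contour_per_nt * xi_grid[-1]


def ss_chain_force(n_nt: int, extension, params: MechParams):
    """Tension (pN) in an n-nt ssDNA held at the given end-to-end extension (nm).

    Extensible freely jointed chain: ``x/L = [coth(Fb/kBT) - kBT/Fb](1 + F/S)``
    inverted numerically.  Vectorized over ``extension``.
    """
    if n_nt < 0:
        raise DomainError("nucleotide count must be >= 0")
    extension = np.asarray(extension, dtype=float)
    if np.any(extension < 0):
        raise DomainError("extension must be >= 0")
    if n_nt == 0:
        if np.any(extension > 0):
            raise DomainError("a 0-nt chain cannot be extended")
        return np.zeros_like(extension)
    contour = n_nt * params.ss_contour_per_nt
    xi = extension / contour
    xi_grid, f_grid, _ = _ss_tables(params.ss_kuhn, params.ss_stretch_mod, params.kbt)
    if np.any(xi > xi_grid[-1]):
        raise DomainError(
            f"extension beyond the chain's reachable contour "
            f"({xi_grid[-1]:.3f} x contour at {_SS_FMAX:.0f} pN)")
    return np.interp(xi, xi_grid, f_grid)


def ss_chain_energy(n_nt: int, extension, params: MechParams):
    """Stretching free energy (kBT) of an n-nt ssDNA at the given extension (nm).

    The work integral of :func:`ss_chain_force`; convex in extension, zero at
    zero extension, extensive in the number of nucleotides.  Geometrically
    unreachable extensions return ``inf`` (an infeasibility sentinel used by
    the ensemble module) rather than raising, so Boltzmann weights vanish
    cleanly.
    """
    if n_nt < 0:
        raise DomainError("nucleotide count must be >= 0")
    extension = np.asarray(extension, dtype=float)
    if np.any(extension < 0):
        raise DomainError("extension must be >= 0")
    if n_nt == 0:
        return np.where(extension > 0, np.inf, 0.0)
    contour = n_nt * params.ss_contour_per_nt
    return _ss_reduced_energy(extension / contour, params) * contour / params.kbt


def ss_free_energy_per_nt(force: float, params: MechParams) -> float:
    """Free energy released per nucleotide, g_nt(F) = int_0^F x_nt(F') dF', in kBT.

    This is the thermodynamic gain of transferring one nucleotide into a
    ssDNA segment held at constant tension F; the equilibrium unzipping
    plateau of a duplex with base-pairing energy ``dg`` per bp sits where
    ``dg = 2 g_nt(F)``.
    """
    if force < 0:
        raise DomainError("force must be >= 0")
    xi_grid, f_grid, _ = _ss_tables(params.ss_kuhn, params.ss_stretch_mod, params.kbt)
    mask = f_grid <= force
    f = np.append(f_grid[mask], force)
    x = np.append(xi_grid[mask], np.interp(force, f_grid, xi_grid))
    g = np.trapezoid(x, f) * params.ss_contour_per_nt
    return g / params.kbt


def unzipping_plateau_force(params: MechParams) -> float:
    """Equilibrium unzipping force (pN) of the stem, solving dg_bp_stem = 2 g_nt(F)."""
    return brentq(lambda f: 2.0 * ss_free_energy_per_nt(f, params) - params.dg_bp_stem,
                  1e-3, _SS_FMAX, xtol=1e-10)


def calibrate_stem_energy(params: MechParams, force: float = 9.0) -> MechParams:
    """Return params with ``dg_bp_stem`` set so the unzipping plateau sits at ``force`` pN."""
    if force <= 0:
        raise DomainError("force must be > 0")
    return params.replace(dg_bp_stem=2.0 * ss_free_energy_per_nt(force, params))
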