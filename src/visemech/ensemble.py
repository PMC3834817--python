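"""Statistical-mechanical ensemble model of the molecular vise.

A vise is a DNA hairpin whose loop apex is hybridized to a variable-length
"target" duplex.  The base-pairing energy of the all-A-T stem applies a
near-constant ~9 pN compressive force to the target through two ssDNA
tethers.  The model enumerates coarse-grained conformations, Boltzmann
weights them, and averages the FRET efficiency of the dye pair at the
stem-loop junction.

State variables (one-dimensional collinear closure):

* ``m`` - number of unzipped stem base pairs (0 .. at_block, exhaustive);
* ``x`` - end-to-end distance of the duplex target (nm, 0.1-nm grid);
* ``r`` - dye-to-dye separation (nm, 0.1-nm grid, ``r <= x``).

The 2m unzipped stem nucleotides span ``r`` between the dyes through the
open fork; the two ssDNA tethers (the unhybridized halves of the loop)
together span ``x - r`` from the target ends inward to the dyes (the fork
equilibrates off-centre, so the pair acts as one combined chain).  The
state energy is

    E = m dg_bp_stem + U_ss(2m nt; r) + U_ss(t1 + t2 nt; x - r)
        + G_bend(target; x)

with all terms in kBT, where ``G_bend`` is the elastica bending energy
dressed with the finite-temperature measure terms (see
:func:`target_bend_weight_energy`).  Geometrically unreachable states carry
an infinite energy sentinel and vanish from the partition sum.  Sums over
the grid (not continuous integrals) define the partition function;
prediction involves no random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import mechanics
from .mechanics import DomainError
from .params import MechParams, params_key


class DesignError(ValueError):
    """Raised for geometrically impossible vise designs."""


MISMATCH_CODES = ("GG", "GA", "GT", "AA", "CT", "CA", "TT", "CC")


@dataclass(frozen=True)
class Mismatch:
    """A single base-pairing mismatch in the target strand.

    ``position`` is the nucleotide offset from the target apex (the centre
    of the target strand); ``ddg`` is the thermodynamic destabilization of
    the duplex relative to the intact pair, in kBT (>= 0).  A melt bubble
    that covers the mismatch position is cheaper by ``ddg``.
    """

    code: str
    position: int = 0
    ddg: float = 0.0

    def __post_init__(self) -> None:
        if self.code not in MISMATCH_CODES:
            raise DesignError(f"unknown mismatch code {self.code!r}; "
                              f"expected one of {MISMATCH_CODES}")
        if self.ddg < 0:
            raise DesignError("mismatch ddg must be >= 0")


@dataclass(frozen=True)
class ViseDesign:
    """Geometry of one molecular-vise construct.

    ``loop_len`` nt hairpin loop, ``stem_len`` bp stem of which the
    ``at_block`` bp adjacent to the loop are unzippable A-T pairs, and a
    ``target_len`` bp duplex formed at the loop apex.  The unhybridized
    loop nucleotides split into two tethers of ``(loop_len - target_len)/2``
    nt each; an odd difference is split as (k, k+1) and flagged.
    """

    loop_len: int
    target_len: int
    stem_len: int = 49
    at_block: int = 39
    mismatch: Mismatch | None = None
    loop_id: str | None = None

    def __post_init__(self) -> None:
        if self.target_len < 1 or self.loop_len < 1:
            raise DesignError("loop_len and target_len must be >= 1")
        if self.target_len > self.loop_len:
            raise DesignError(
                f"target ({self.target_len} bp) cannot exceed the loop "
                f"({self.loop_len} nt)")
        if self.at_block > self.stem_len:
            raise DesignError("at_block cannot exceed stem_len")
        if self.loop_id is None:
            object.__setattr__(self, "loop_id", f"loop{self.loop_len}")

    @property
    def tether_nts(self) -> tuple[int, int]:
        """Nucleotide counts of the two ssDNA tethers (integer split)."""
        free = self.loop_len - self.target_len
        return free // 2, free - free // 2

    @property
    def odd_split(self) -> bool:
        """True when the tethers differ by one nucleotide."""
        t1, t2 = self.tether_nts
        return t1 != t2


@dataclass(frozen=True)
class GridSpec:
    """Discretization of the conformational state space.

    ``dx``/``dr`` are the grids of the target end-to-end distance and the
    dye separation (nm); ``hinge_step_deg`` and ``n_melt_max`` control the
    kinked (melted-bubble) states of the MWLC extension.
    """

    dx: float = 0.1
    dr: float = 0.1
    hinge_step_deg: float = 5.0
    n_melt_max: int = 6
    thermal_bend: bool = True

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dr <= 0 or self.hinge_step_deg <= 0:
            raise DomainError("grid steps must be > 0")
        if self.n_melt_max < 1:
            raise DomainError("n_melt_max must be >= 1")

    def key(self) -> tuple:
        return (self.dx, self.dr, self.hinge_step_deg, self.n_melt_max,
                self.thermal_bend)


DEFAULT_GRID = GridSpec()


@dataclass(frozen=True)
class ConformationState:
    """One point of the conformational ensemble."""

    m: int
    x_target: float
    r_dye: float
    n_melt: int = 0
    hinge_angle: float = np.pi
    energy_terms: Mapping[str, float] | None = None

    @property
    def energy(self) -> float:
        if self.energy_terms is None:
            raise ValueError("state has not been evaluated")
        return float(sum(self.energy_terms.values()))


@dataclass
class FretCurve:
    """FRET efficiency versus target length for one loop and condition."""

    loop_id: str
    condition: str
    target_len: np.ndarray
    e: np.ndarray
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.target_len = np.asarray(self.target_len)
        self.e = np.asarray(self.e, dtype=float)
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
        if self.target_len.shape != self.e.shape:
            raise ValueError("target_len and e must have matching shapes")
        if np.any(np.diff(self.target_len) <= 0):
            raise ValueError("target lengths must be strictly increasing")
        if np.any((self.e < -1e-9) | (self.e > 1 + 1e-9)):
            raise ValueError("FRET efficiencies must lie in [0, 1]")
        if self.sem is not None and np.any(self.sem < 0):
            raise ValueError("sem must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "loop_id": self.loop_id, "condition": self.condition,
            "target_len": self.target_len, "E": self.e,
        })
        df["sem"] = self.sem if self.sem is not None else np.nan
        return df

    def local_minimum(self, min_depth: float = 0.0) -> int | None:
        """Target length of the curve's interior local minimum, if any.

        Returns the target length of the deepest strictly interior local
        minimum of E (lower than both neighbours), or None when E has no
        interior minimum (monotone or edge-minimal curve).  ``min_depth``
        additionally requires the minimum to sit at least that far below
        the highest point on each side, filtering dips smaller than the
        measurement scale.
        """
        e = self.e
        interior = np.nonzero((e[1:-1] < e[:-2]) & (e[1:-1] <= e[2:]))[0] + 1
        if min_depth > 0:
            interior = np.array([
                i for i in interior
                if min(e[:i].max(), e[i + 1:].max()) - e[i] >= min_depth
            ], dtype=int)
        if interior.size == 0:
            return None
        best = interior[np.argmin(e[interior])]
        return int(self.target_len[best])


def curves_to_frame(curves: Iterable[FretCurve]) -> pd.DataFrame:
    return pd.concat([c.to_frame() for c in curves], ignore_index=True)


def curves_from_frame(df: pd.DataFrame) -> list[FretCurve]:
    out = []
    for (loop_id, condition), sub in df.groupby(["loop_id", "condition"], sort=False):
        sub = sub.sort_values("target_len")
        sem = sub["sem"].to_numpy() if "sem" in sub and sub["sem"].notna().all() else None
        out.append(FretCurve(str(loop_id), str(condition),
                             sub["target_len"].to_numpy(), sub["E"].to_numpy(), sem))
    return out


# ---------------------------------------------------------------------------
# FRET
# ---------------------------------------------------------------------------

def fret_efficiency(separation, r0: float):
    """Foerster point-dipole FRET efficiency E = 1/(1 + (r/R0)^6)."""
    if r0 <= 0:
        raise DomainError("Foerster radius must be > 0")
    separation = np.asarray(separation, dtype=float)
    if np.any(separation < 0):
        raise DomainError("separation must be >= 0")
    return 1.0 / (1.0 + (separation / r0) ** 6)


# ---------------------------------------------------------------------------
# State grids and energies
# ---------------------------------------------------------------------------

@dataclass
class StateGrid:
    """The discretized duplex (n_melt = 0) state space of one design.

    ``energy`` has shape ``(len(x), len(r), len(m))``; infeasible states are
    ``inf``.  Component tensors broadcast against that shape.
    """

    design: ViseDesign
    params: MechParams
    grid: GridSpec
    x: np.ndarray
    r: np.ndarray
    m: np.ndarray
    bend: np.ndarray      # (nx,)
    stem: np.ndarray      # (nm,)
    dye_chain: np.ndarray  # (nr, nm)
    tethers: np.ndarray   # (nx, nr), inf where r > x or unreachable
    energy: np.ndarray    # (nx, nr, nm)

    @property
    def n_candidates(self) -> int:
        return self.energy.size

    @property
    def n_feasible(self) -> int:
        return int(np.isfinite(self.energy).sum())

    def min_energy_state(self) -> ConformationState:
        if not np.isfinite(self.energy).any():
            raise DesignError("empty feasible state set")
        i, j, k = np.unravel_index(np.argmin(self.energy), self.energy.shape)
        terms = {
            "stem": float(self.stem[k]),
            "ss_stem": float(self.dye_chain[j, k]),
            "ss_tethers": float(self.tethers[i, j]),
            "bend": float(self.bend[i]),
            "bubble": 0.0,
        }
        return ConformationState(m=int(self.m[k]), x_target=float(self.x[i]),
                                 r_dye=float(self.r[j]), energy_terms=terms)


def _wf_log_measure(delta: np.ndarray) -> np.ndarray:
    """Log of the stiff-chain fluctuation measure B(delta) around the elastica.

    In the stiff (weakly bending) limit the worm-like chain's end-to-end
    distribution factorizes as ``P(x) ~ B(delta) exp(-U_elastica(x)/kBT)``
    with ``delta = pi^2 (1 - x/L) lp / L`` (the Wilhelm-Frey mode sum),

        B(delta) = sum_{l>=1} (-1)^(l+1) l^2 exp(-(l^2 - 1) delta).

    B -> 1 away from full extension and vanishes with an essential
    singularity at x = L: a thermalized chain is never exactly straight.
    Evaluated by the direct series for large delta and by its Jacobi-theta
    (Poisson-resummed) form for small delta, where the alternating series
    cancels catastrophically in floating point.
    """
    delta = np.asarray(delta, dtype=float)
    out = np.full(delta.shape, -np.inf)
    big = delta >= 0.15
    if np.any(big):
        l = np.arange(1, 61)[None, :]
        d = delta[big][:, None]
        s = ((-1.0) ** (l + 1) * l ** 2 * np.exp(-(l ** 2 - 1) * d)).sum(axis=1)
        out[big] = np.log(np.maximum(s, 1e-300))
    small = (~big) & (delta > 0)
    if np.any(small):
        d = delta[small][:, None]
        a = np.pi ** 2 * (np.arange(0, 6)[None, :] + 0.5) ** 2
        s0p = (2.0 * np.sqrt(np.pi)
               * (-0.5 * d ** -1.5 + a * d ** -2.5) * np.exp(-a / d)).sum(axis=1)
        out[small] = delta[small] + np.log(np.maximum(s0p / 2.0, 1e-300))
    return out


def target_bend_weight_energy(h_nm: float, x, params: MechParams,
                              thermal: bool = True):
    """Effective bending free energy (kBT) weighting target end-to-end states.

    The elastica ground-state energy plus, when ``thermal`` is on, the
    -kBT ln B fluctuation-measure term of the finite-temperature worm-like
    chain (see :func:`_wf_log_measure`).  The measure term produces the
    small thermal shortening of the buckling transition relative to the
    zero-temperature Euler estimate; it vanishes for strongly bent states,
    where the elastica energy dominates.
    """
    x = np.asarray(x, dtype=float)
    e = mechanics.elastica_energy(h_nm, x, params)
    if not thermal:
        return e
    rho = np.minimum(x / h_nm, 1.0)
    delta = np.pi ** 2 * (1.0 - rho) * params.lp_ds / h_nm
    # directional (vector) end-to-end density: the closure axis is fixed by
    # the tethers, so the radial-shell factor 4 pi x^2 is divided out;
    # capped at the bent rod's transverse extent where the shell picture ends
    vector_measure = 2.0 * np.log(np.maximum(rho, 0.4))
    return e - _wf_log_measure(delta) + vector_measure


def _fork_chain_energy(m: np.ndarray, r: np.ndarray,
                       params: MechParams) -> np.ndarray:
    """Effective free energy (kBT) of the 2m unzipped stem nt spanning r.

    The stretching work of the 2m-nt chain plus the saddle-point prefactor
    of its end-to-end density, ``(3/2) ln(2m)``: the directional density of
    an n-segment chain scales as ``n^(-3/2) exp(-n i(xi))``, so unzipping
    carries a translational-entropy cost on top of the base-pairing and
    stretching terms.  Shape (len(r), len(m)); unreachable spans are inf.
    """
    contour = 2.0 * m[None, :] * params.ss_contour_per_nt       # (1, nm)
    with np.errstate(divide="ignore", invalid="ignore"):
        xi = np.where(contour > 0, r[:, None] / np.where(contour > 0, contour, 1.0),
                      np.inf)
    xi = np.where((contour == 0) & (r[:, None] == 0), 0.0, xi)
    red = mechanics._ss_reduced_energy(np.where(np.isfinite(xi), xi, 0.0), params)
    entropy = np.where(m > 0, 1.5 * np.log(np.maximum(2.0 * m, 1.0)), 0.0)
    return np.where(np.isfinite(xi),
                    red * contour / params.kbt + entropy[None, :], np.inf)


def _tether_energy(design: ViseDesign, params: MechParams, span) -> np.ndarray:
    """Combined stretching energy (kBT) of both tethers spanning ``x - r`` (nm).

    The fork position equilibrates, so the optimal division of the span
    between the two tethers is proportional to their contour lengths; by the
    extensivity of the FJC the pair is then exactly equivalent to a single
    chain of ``t1 + t2`` nucleotides spanning the full distance.  (For the
    symmetric even split this reduces to twice the per-tether energy at span
    ``(x - r)/2``.)
    """
    t1, t2 = design.tether_nts
    return mechanics.ss_chain_energy(t1 + t2, span, params)


def enumerate_states(design: ViseDesign, params: MechParams,
                     grid: GridSpec = DEFAULT_GRID) -> StateGrid:
    """Build the duplex-only (WLC) state grid with all energy components.

    States violating the geometric closure (dye separation exceeding the
    target span, tethers or fork ssDNA stretched beyond reach) carry an
    infinite energy and never contribute weight.
    """
    h_nm = design.target_len * params.rise_ds
    x = np.arange(grid.dx, h_nm - 1e-9, grid.dx)
    x = np.append(x, h_nm)
    r = np.arange(0.0, x[-1] + 1e-9, grid.dr)
    m = np.arange(0, design.at_block + 1)

    bend = target_bend_weight_energy(h_nm, x, params, grid.thermal_bend)  # (nx,)
    stem = m * params.dg_bp_stem                                # (nm,)

    dye_chain = _fork_chain_energy(m, r, params)                # (nr, nm)

    span = x[:, None] - r[None, :]                              # (nx, nr)
    feasible = span >= -1e-12
    teth = np.full_like(span, np.inf)
    teth[feasible] = _tether_energy(design, params, np.maximum(span[feasible], 0.0))

    energy = (bend[:, None, None] + teth[:, :, None]
              + stem[None, None, :] + dye_chain[None, :, :])
    if not np.isfinite(energy).any():
        raise DesignError("empty feasible state set for this design/grid")
    return StateGrid(design, params, grid, x, r, m, bend, stem, dye_chain, teth, energy)


def state_energy(state: ConformationState, design: ViseDesign,
                 params: MechParams) -> tuple[float, dict[str, float]]:
    """Energy (kBT) of a single conformational state, with a named breakdown.

    Geometric infeasibility yields an ``inf`` total, never a silent wrong
    number.  For melted states (``n_melt > 0``) the duplex arms are straight
    and the bubble terms of the meltable-WLC extension apply.
    """
    if not 0 <= state.m <= design.at_block:
        raise DomainError("m outside 0..at_block")
    if state.n_melt < 0 or state.n_melt >= design.target_len:
        raise DomainError("n_melt must satisfy 0 <= n_melt < target_len")
    terms: dict[str, float] = {}
    terms["stem"] = state.m * params.dg_bp_stem
    terms["ss_stem"] = float(mechanics.ss_chain_energy(2 * state.m, state.r_dye, params))
    span = state.x_target - state.r_dye
    terms["ss_tethers"] = (float(_tether_energy(design, params, span))
                           if span >= 0 else np.inf)
    if state.n_melt == 0:
        terms["bend"] = float(mechanics.elastica_energy(
            design.target_len * params.rise_ds, state.x_target, params))
        terms["bubble"] = 0.0
    else:
        from . import mwlc  # local import; mwlc builds on this module
        terms["bend"] = 0.0  # straight rigid arms flanking the kink
        bb = mwlc.bubble_energy(state.n_melt, np.pi - state.hinge_angle, params,
                                design=design)
        terms["bubble"] = bb.dg_bubble_bp + bb.dg_bubble_coop + bb.dg_bubble_bend
    total = float(sum(terms.values()))
    return total, terms


# ---------------------------------------------------------------------------
# Ensemble averages and curve prediction
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSummary:
    """Partition-function-level observables of one design under one model."""

    e_fret: float
    free_energy: float            # -ln Z, kBT, same reference for wlc and mwlc
    channel_means: dict[str, float]
    mean_m: float
    p_melted: float               # total weight of n_melt > 0 states


def wlc_summary(design: ViseDesign, params: MechParams,
                grid: GridSpec = DEFAULT_GRID) -> EnsembleSummary:
    """Boltzmann summary of the duplex-only (WLC) ensemble."""
    sg = enumerate_states(design, params, grid)
    e = sg.energy
    emin = np.nanmin(np.where(np.isfinite(e), e, np.nan))
    w = np.exp(-(np.where(np.isfinite(e), e, np.inf) - emin))
    z = w.sum()
    ef = fret_efficiency(sg.r + params.dye_offset, params.forster_radius)
    e_fret = float((w.sum(axis=(0, 2)) * ef).sum() / z)
    wsafe = np.where(np.isfinite(e), w, 0.0)
    dye_safe = np.where(np.isfinite(sg.dye_chain), sg.dye_chain, 0.0)
    teth_safe = np.where(np.isfinite(sg.tethers), sg.tethers, 0.0)
    bend_safe = np.where(np.isfinite(sg.bend), sg.bend, 0.0)
    channel_means = {
        "stem": float((wsafe.sum(axis=(0, 1)) * sg.stem).sum() / z),
        "ss_stem": float((wsafe.sum(axis=0) * dye_safe).sum() / z),
        "ss_tethers": float((wsafe.sum(axis=2) * teth_safe).sum() / z),
        "bend": float((wsafe.sum(axis=(1, 2)) * bend_safe).sum() / z),
        "bubble": 0.0,
    }
    mean_m = float((wsafe.sum(axis=(0, 1)) * sg.m).sum() / z)
    return EnsembleSummary(e_fret=e_fret, free_energy=float(emin - np.log(z)),
                           channel_means=channel_means, mean_m=mean_m, p_melted=0.0)


_CURVE_CACHE: dict[tuple, "FretCurve"] = {}


def predict_fret_curve(loop_len: int, target_lens: Sequence[int],
                       params: MechParams | None = None, mode: str = "wlc",
                       grid: GridSpec = DEFAULT_GRID,
                       mismatch: Mismatch | None = None,
                       condition: str = "model",
                       design_kwargs: Mapping | None = None) -> FretCurve:
    """Predicted ensemble-average FRET versus target length for one loop.

    ``mode='wlc'`` restricts the ensemble to fully duplex targets;
    ``mode='mwlc'`` adds melted-bubble kink states.  Prediction is
    deterministic for a fixed grid; results are memoized on
    (params, design, targets, mode, grid).
    """
    if mode not in ("wlc", "mwlc"):
        raise ValueError(f"mode must be 'wlc' or 'mwlc', got {mode!r}")
    params = params if params is not None else MechParams()
    target_lens = tuple(int(t) for t in target_lens)
    kwargs = dict(design_kwargs or {})
    key = (params_key(params), loop_len, target_lens, mode, grid.key(),
           mismatch, tuple(sorted(kwargs.items())), condition)
    if key in _CURVE_CACHE:
        return _CURVE_CACHE[key]
    es = []
    for h in target_lens:
        design = ViseDesign(loop_len=loop_len, target_len=h, mismatch=mismatch,
                            **kwargs)
        if mode == "wlc":
            es.append(wlc_summary(design, params, grid).e_fret)
        else:
            from . import mwlc
            es.append(mwlc.mwlc_summary(design, params, grid).e_fret)
    curve = FretCurve(loop_id=f"loop{loop_len}", condition=condition,
                      target_len=np.array(target_lens), e=np.array(es))
    _CURVE_CACHE[key] = curve
    return curve


def clear_curve_cache() -> None:
    _CURVE_CACHE.clear()


# ---------------------------------------------------------------------------
# Fitting measured curves
# ---------------------------------------------------------------------------

@dataclass
class ScaleFit:
    """Per-loop multiplicative scale factor between model and measurement."""

    scale: float
    residuals: np.ndarray
    target_len: np.ndarray

    @property
    def sse(self) -> float:
        return float(np.sum(self.residuals ** 2))


def fit_scale_factors(model: Sequence[FretCurve], measured: Sequence[FretCurve]
                      ) -> dict[str, ScaleFit]:
    """Least-squares multiplicative factor per loop, a = sum(m d)/sum(m^2).

    The scale factor is the model's only adjustable parameter: it absorbs
    the instrument-dependent FRET range without shifting the curve shape.
    """
    model_by_loop = {c.loop_id: c for c in model}
    out: dict[str, ScaleFit] = {}
    for meas in measured:
        if meas.loop_id not in model_by_loop:
            continue
        mod = model_by_loop[meas.loop_id]
        common = np.intersect1d(mod.target_len, meas.target_len)
        if common.size == 0:
            raise ValueError(f"no overlapping target lengths for {meas.loop_id}")
        mvals = mod.e[np.isin(mod.target_len, common)]
        dvals = meas.e[np.isin(meas.target_len, common)]
        a = float(np.dot(mvals, dvals) / np.dot(mvals, mvals))
        out[meas.loop_id] = ScaleFit(scale=a, residuals=dvals - a * mvals,
                                     target_len=common)
    if not out:
        raise ValueError("no loop ids in common between model and measured curves")
    return out


@dataclass
class LpFit:
    """Result of a persistence-length scan against measured curves."""

    lp_hat: float
    lp_grid: np.ndarray
    sse: np.ndarray
    scale_factors: dict[str, float]


def fit_persistence_length(measured: Sequence[FretCurve], params: MechParams,
                           lp_grid: Sequence[float], mode: str = "wlc",
                           grid: GridSpec = DEFAULT_GRID) -> LpFit:
    """Scan lp_ds, refit per-loop scale factors, return the residual-minimizing lp.

    Model curves at each lp are memoized, so repeated fits against new noisy
    data (e.g. in a recovery study) cost only the least-squares step.
    """
    lp_grid = np.asarray(sorted(lp_grid), dtype=float)
    if lp_grid.size < 2:
        raise ValueError("lp grid must contain at least two points")
    sse = np.empty_like(lp_grid)
    fits_at_best: dict[str, float] = {}
    for i, lp in enumerate(lp_grid):
        p = params.replace(lp_ds=lp)
        model = [predict_fret_curve(int(c.loop_id.removeprefix("loop")),
                                    tuple(int(t) for t in c.target_len), p,
                                    mode=mode, grid=grid) for c in measured]
        fits = fit_scale_factors(model, measured)
        sse[i] = sum(f.sse for f in fits.values())
        if i == int(np.argmin(sse[:i + 1])):
            fits_at_best = {k: f.scale for k, f in fits.items()}
    best = int(np.argmin(sse))
    return LpFit(lp_hat=float(lp_grid[best]), lp_grid=lp_grid, sse=sse,
                 scale_factors=fits_at_best)


def lp_for_minimum_at(target_len: int, loop_lens: Sequence[int],
                      params: MechParams, lp_grid: Sequence[float],
                      scan_targets: Sequence[int] | None = None,
                      grid: GridSpec = DEFAULT_GRID) -> float:
    """Persistence length at which the predicted FRET minimum shifts to ``target_len``.

    The buckling minimum marches to shorter target lengths as the duplex
    softens, so the quantity reported is the onset boundary: scanning
    ``lp_ds`` downward over ``lp_grid``, the largest lp at which any of the
    given loops' predicted minima sits at the requested target length,
    interpolated half a grid step toward the neighbouring lp whose minimum
    is still longer.  Raises if the grid fails to bracket the shift.
    """
    lp_grid = np.asarray(sorted(lp_grid), dtype=float)
    if lp_grid.size < 2:
        raise ValueError("lp grid must contain at least two points")

    def min_locations(lp: float) -> list[int | None]:
        p = params.replace(lp_ds=lp)
        locs = []
        for loop in loop_lens:
            targets = (scan_targets if scan_targets is not None
                       else range(18, loop + 1))
            curve = predict_fret_curve(loop, tuple(targets), p, mode="wlc",
                                       grid=grid)
            locs.append(curve.local_minimum(min_depth=0.01))
        return locs

    seen = []
    for i in range(lp_grid.size - 1, -1, -1):
        locs = min_locations(lp_grid[i])
        seen.append((lp_grid[i], locs))
        if any(loc == target_len for loc in locs if loc is not None):
            if i + 1 < lp_grid.size:
                return float(0.5 * (lp_grid[i] + lp_grid[i + 1]))
            return float(lp_grid[i])
    raise ValueError(
        f"lp grid {lp_grid[0]}..{lp_grid[-1]} never places the FRET minimum "
        f"at {target_len} bp (observed: {seen})")
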