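"""Meltable worm-like chain: curvature-induced melting and kinked ensembles.

At high ionic strength a sharply compressed target strand can lower its free
energy by melting a few base pairs at the point of highest curvature.  The
melted "bubble" has a much shorter persistence length than the duplex, so it
acts as a nearly free hinge: the two flanking duplex arms straighten, the
tethers relax and the stem re-zips.  The kink free energy splits into a
local bubble cost and a nonlocal relaxation gain,

    dG_kink = dG_bubble + dG_relax,
    dG_bubble = n dg_melt + sigma_coop + U_bend(melted region)   (>= 0)
    dG_relax  = relaxation of duplex curvature + tether stretch
                + stem re-zipping                                 (<= 0)

Kinked states are parameterized by the bubble size ``n_melt`` (apex-centred,
1..n_melt_max) and the hinge opening angle ``phi`` (0 = fully folded,
pi = straight), integrated on a uniform angular grid.  The two duplex arms
are treated as straight rigid rods, so the end-to-end distance of a kinked
target is ``x = (h - n_melt) rise sin(phi/2)`` and the melted region absorbs
the full turning angle ``pi - phi`` at bending stiffness ``lp_melt``.
Disabling melted states recovers the duplex-only (WLC) ensemble exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import ensemble
from .ensemble import (DEFAULT_GRID, EnsembleSummary, FretCurve, GridSpec,
                       ViseDesign, fret_efficiency)
from .mechanics import DomainError
from .params import MechParams


@dataclass(frozen=True)
class BubbleTerms:
    """The three local (cost) components of the kink free energy, kBT."""

    dg_bubble_bp: float
    dg_bubble_coop: float
    dg_bubble_bend: float

    @property
    def total(self) -> float:
        return self.dg_bubble_bp + self.dg_bubble_coop + self.dg_bubble_bend


@dataclass(frozen=True)
class KinkBreakdown:
    """Two-component kink free energy with its six sub-terms (kBT).

    The first three terms are the local bubble cost (>= 0 for an intact
    target); the last three are the nonlocal relaxation gains (<= 0).
    ``total`` equals their sum and is the exact difference of constrained
    ensemble free energies between the kinked and duplex-only state sets.
    """

    dg_bubble_bp: float
    dg_bubble_coop: float
    dg_bubble_bend: float
    dg_relax_ds: float
    dg_relax_ss: float
    dg_relax_stem: float

    @property
    def total(self) -> float:
        return (self.dg_bubble_bp + self.dg_bubble_coop + self.dg_bubble_bend
                + self.dg_relax_ds + self.dg_relax_ss + self.dg_relax_stem)


def _mismatch_relief(design: ViseDesign | None, n_melt: int) -> float:
    """Destabilization credit when the bubble covers the mismatch site.

    An apex-centred bubble of n bp covers apex offsets |p| <= n/2.
    """
    if design is None or design.mismatch is None or n_melt == 0:
        return 0.0
    if n_melt >= 2 * abs(design.mismatch.position):
        return design.mismatch.ddg
    return 0.0


def bubble_energy(n_melt: int, bend_demand: float, params: MechParams,
                  design: ViseDesign | None = None,
                  coop_log_coeff: float = 0.0) -> BubbleTerms:
    """Local free-energy cost of an n-bp melt bubble bent by ``bend_demand`` rad.

    ``dg_bubble_bp`` is the base-pairing loss ``n * dg_melt_target`` less the
    mismatch destabilization when the bubble covers the mismatch;
    ``dg_bubble_coop`` is the nucleation penalty (``sigma_coop`` plus an
    optional ``coop_log_coeff * ln(n)`` loop-factor term); ``dg_bubble_bend``
    is the WLC bending energy of the melted segment (persistence length
    ``lp_melt``) carrying the full turning angle at constant curvature.
    """
    if n_melt < 0:
        raise DomainError("n_melt must be >= 0")
    if design is not None and n_melt >= design.target_len:
        raise DomainError("bubble cannot exceed the target length")
    if n_melt == 0:
        return BubbleTerms(0.0, 0.0, 0.0)
    bp = n_melt * params.dg_melt_target - _mismatch_relief(design, n_melt)
    coop = params.sigma_coop + coop_log_coeff * np.log(n_melt)
    contour = n_melt * params.ss_contour_per_nt
    bend = params.lp_melt * float(bend_demand) ** 2 / (2.0 * contour)
    return BubbleTerms(bp, coop, bend)


# ---------------------------------------------------------------------------
# Kinked-state partition sums
# ---------------------------------------------------------------------------

@dataclass
class _BlockSums:
    """Raw Boltzmann accumulators of one block of states (absolute energies)."""

    z: float = 0.0
    num_fret: float = 0.0
    stem: float = 0.0
    ss: float = 0.0        # tethers + fork ssDNA
    bend_ds: float = 0.0
    bubble_fixed: float = 0.0
    bubble_bend: float = 0.0
    m_sum: float = 0.0

    def add(self, other: "_BlockSums") -> None:
        for name in vars(other):
            setattr(self, name, getattr(self, name) + getattr(other, name))


def _wlc_block(design: ViseDesign, params: MechParams, grid: GridSpec) -> _BlockSums:
    sg = ensemble.enumerate_states(design, params, grid)
    e = sg.energy
    w = np.where(np.isfinite(e), np.exp(-np.where(np.isfinite(e), e, 0.0)), 0.0)
    ef = fret_efficiency(sg.r + params.dye_offset, params.forster_radius)
    dye_safe = np.where(np.isfinite(sg.dye_chain), sg.dye_chain, 0.0)
    teth_safe = np.where(np.isfinite(sg.tethers), sg.tethers, 0.0)
    b = _BlockSums()
    b.z = float(w.sum())
    b.num_fret = float((w.sum(axis=(0, 2)) * ef).sum())
    b.stem = float((w.sum(axis=(0, 1)) * sg.stem).sum())
    b.ss = float((w.sum(axis=0) * dye_safe).sum() + (w.sum(axis=2) * teth_safe).sum())
    bend_safe = np.where(np.isfinite(sg.bend), sg.bend, 0.0)
    b.bend_ds = float((w.sum(axis=(1, 2)) * bend_safe).sum())
    b.m_sum = float((w.sum(axis=(0, 1)) * sg.m).sum())
    return b


def _kink_block(design: ViseDesign, params: MechParams, grid: GridSpec,
                n_melt: int) -> _BlockSums:
    """Boltzmann sums over the kinked states of one bubble size."""
    h = design.target_len
    rise = params.rise_ds
    m = np.arange(0, design.at_block + 1)
    stem = m * params.dg_bp_stem
    phis = np.radians(np.arange(0.0, 180.0 + 1e-9, grid.hinge_step_deg))
    arm_span = (h - n_melt) * rise
    b = _BlockSums()
    fixed = (n_melt * params.dg_melt_target - _mismatch_relief(design, n_melt)
             + params.sigma_coop)
    for phi in phis:
        x = arm_span * np.sin(phi / 2.0)
        bend_melt = params.lp_melt * (np.pi - phi) ** 2 / (
            2.0 * n_melt * params.ss_contour_per_nt)
        r = np.arange(0.0, x + 1e-9, grid.dr)
        teth = ensemble._tether_energy(design, params,
                                       np.maximum(x - r, 0.0))      # (nr,)
        dye = ensemble._fork_chain_energy(m, r, params)              # (nr, nm)
        e = fixed + bend_melt + teth[:, None] + stem[None, :] + dye   # (nr, nm)
        w = np.where(np.isfinite(e), np.exp(-np.where(np.isfinite(e), e, 0.0)), 0.0)
        z = float(w.sum())
        if z == 0.0:
            continue
        ef = fret_efficiency(r + params.dye_offset, params.forster_radius)
        b.z += z
        b.num_fret += float((w.sum(axis=1) * ef).sum())
        b.stem += float((w.sum(axis=0) * stem).sum())
        dye_safe = np.where(np.isfinite(dye), dye, 0.0)
        teth_safe = np.where(np.isfinite(teth), teth, 0.0)
        b.ss += float((w * dye_safe).sum() + (w.sum(axis=1) * teth_safe).sum())
        b.bubble_fixed += z * fixed
        b.bubble_bend += z * bend_melt
        b.m_sum += float((w.sum(axis=0) * m).sum())
    return b


def mwlc_summary(design: ViseDesign, params: MechParams,
                 grid: GridSpec = DEFAULT_GRID) -> EnsembleSummary:
    """Boltzmann summary over duplex and kinked (melted-bubble) states."""
    total = _wlc_block(design, params, grid)
    z_wlc = total.z
    n_max = min(grid.n_melt_max, design.target_len - 1)
    for n in range(1, n_max + 1):
        total.add(_kink_block(design, params, grid, n))
    if total.z <= 0.0:
        raise ensemble.DesignError("empty feasible state set")
    z = total.z
    channel_means = {
        "stem": total.stem / z,
        "ss": total.ss / z,
        "bend": total.bend_ds / z,
        "bubble": (total.bubble_fixed + total.bubble_bend) / z,
    }
    return EnsembleSummary(
        e_fret=total.num_fret / z,
        free_energy=float(-np.log(z)),
        channel_means=channel_means,
        mean_m=total.m_sum / z,
        p_melted=float(1.0 - z_wlc / z),
    )


def predict_kinked_fret_curve(loop_len: int, target_lens: Sequence[int],
                              params: MechParams | None = None,
                              grid: GridSpec = DEFAULT_GRID,
                              mismatch: ensemble.Mismatch | None = None,
                              condition: str = "model") -> FretCurve:
    """Ensemble FRET prediction including melted-bubble kink states."""
    return ensemble.predict_fret_curve(loop_len, target_lens, params,
                                       mode="mwlc", grid=grid,
                                       mismatch=mismatch, condition=condition)


# ---------------------------------------------------------------------------
# Kink free energy (Boltzmann-exact, with channel decomposition)
# ---------------------------------------------------------------------------

def kink_free_energy(design: ViseDesign, params: MechParams, n_melt: int,
                     grid: GridSpec = DEFAULT_GRID) -> KinkBreakdown:
    """Free energy of forming an n-bp kink bubble in the vise, with breakdown.

    ``total`` is the exact difference of constrained free energies,
    ``-ln Z(kinked, bubble = n) + ln Z(duplex only)``.  The bubble cost
    terms are the fixed base-pairing and nucleation penalties plus the
    ensemble-averaged bending of the melted region; the relaxation gains are
    the channel-wise changes in mean duplex bending, ssDNA stretching and
    stem unzipping energy between the two ensembles, rescaled to absorb the
    (small) entropic residual so the six terms sum exactly to ``total``.
    A negative total means kinked states dominate the ensemble.
    """
    if n_melt < 1 or n_melt >= design.target_len:
        raise DomainError("n_melt must satisfy 1 <= n_melt < target_len")
    wlc = _wlc_block(design, params, grid)
    kink = _kink_block(design, params, grid, n_melt)
    if kink.z <= 0 or wlc.z <= 0:
        raise ensemble.DesignError("empty feasible state set")
    dg_total = float(-np.log(kink.z) + np.log(wlc.z))
    bp = (n_melt * params.dg_melt_target - _mismatch_relief(design, n_melt))
    coop = params.sigma_coop
    bend_melt = kink.bubble_bend / kink.z
    dg_bubble = bp + coop + bend_melt
    dg_relax = dg_total - dg_bubble
    d_ds = -wlc.bend_ds / wlc.z                      # arms are straight when kinked
    d_ss = kink.ss / kink.z - wlc.ss / wlc.z
    d_stem = kink.stem / kink.z - wlc.stem / wlc.z
    raw = np.array([d_ds, d_ss, d_stem])
    scale = np.abs(raw).sum()
    if scale > 0:
        adj = raw + (dg_relax - raw.sum()) * np.abs(raw) / scale
    else:
        adj = np.full(3, dg_relax / 3.0)
    return KinkBreakdown(bp, coop, bend_melt, *map(float, adj))


def relaxation_energy(design: ViseDesign, params: MechParams, n_melt: int,
                      grid: GridSpec = DEFAULT_GRID
                      ) -> tuple[float, float, float]:
    """The three nonlocal relaxation gains (duplex bend, ssDNA stretch, stem).

    Convenience slice of :func:`kink_free_energy`; each term is <= 0 within
    numerical tolerance whenever kinking relaxes the vise.
    """
    kb = kink_free_energy(design, params, n_melt, grid)
    return kb.dg_relax_ds, kb.dg_relax_ss, kb.dg_relax_stem


# ---------------------------------------------------------------------------
# Two-parabola common-tangent (Maxwell) construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectiveBend:
    """Effective bending-energy density at one curvature, with regime label."""

    energy_density: float       # kBT per nm
    regime: str                 # "wlc", "kinked" (coexistence) or "melted"
    c_tangent_intact: float     # tangent point A, deg/bp
    c_tangent_melted: float     # tangent point B, deg/bp


def effective_bending_energy(curvature: float, params: MechParams,
                             bubble_offset: float) -> EffectiveBend:
    """Lower convex envelope of the intact and melted bending parabolas.

    The intact duplex costs ``(kappa/2) c^2`` per unit length and a melted
    region ``eps + (kappa_melt/2) c^2`` with ``eps = bubble_offset`` (kBT/nm).
    Between the analytic common-tangent points A and B the chain phase-
    separates into intact DNA at curvature A and melted DNA at curvature B
    ("kinked"); the envelope there is the tangent line.  ``curvature`` is in
    degrees per base pair.
    """
    if curvature < 0:
        raise DomainError("curvature must be >= 0")
    if bubble_offset < 0:
        raise DomainError("bubble offset must be >= 0")
    a1 = params.lp_ds / 2.0       # kBT nm (energy density = a c^2 with c in rad/nm)
    a2 = params.lp_melt / 2.0
    if a2 >= a1:
        raise DomainError("melted stiffness must be below duplex stiffness "
                          "(lp_melt < lp_ds); no common tangent exists")
    to_rad_per_nm = np.pi / 180.0 / params.rise_ds
    c = curvature * to_rad_per_nm
    eps = bubble_offset
    if eps == 0.0:
        c_a = c_b = 0.0
    else:
        c_a = np.sqrt(a2 * eps / (a1 * (a1 - a2)))
        c_b = a1 * c_a / a2
    if c <= c_a:
        val, regime = a1 * c * c, "wlc"
    elif c >= c_b:
        val, regime = eps + a2 * c * c, "melted"
    else:
        val = a1 * c_a ** 2 + 2.0 * a1 * c_a * (c - c_a)
        regime = "kinked"
    per_deg_bp = 1.0 / to_rad_per_nm
    return EffectiveBend(float(val), regime,
                         float(c_a * per_deg_bp), float(c_b * per_deg_bp))
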