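#!/usr/bin/env python
"""Cross-check the ensemble's thermal bending weight against Monte Carlo.

The vise ensemble weights each target end-to-end distance x by

    exp(-U_elastica(x)/kBT) * B(delta) / max(x/L, 0.4)^2,

i.e. the elastica ground-state energy dressed with the Wilhelm-Frey
stiff-chain fluctuation measure and the directional (vector) end-to-end
density of the collinear closure.  This script samples the exact
end-to-end distribution of a discrete worm-like chain with free ends by
umbrella-sampled Metropolis Monte Carlo (pivot moves, WHAM stitching) and
prints the residual between the sampled -ln P_vec(x) and the model, for a
few contour-to-persistence-length ratios t = L/lp covering the vise's
target strands (t ~ 0.15-0.45).

Expected outcome: residuals of a few tenths of kBT over x/L in (0.45, 1),
i.e. the model reproduces the finite-temperature WLC free energy to well
under thermal accuracy in the regime the FRET predictions probe.

Runtime is ~5-10 minutes per t value; this is a validation tool, not part
of the test suite.  Usage:

    python scripts/validate_thermal_measure.py [t ...]   # default: 0.2 0.3
"""

from __future__ import annotations

import sys

import numpy as np
from scipy.optimize import brentq


def _rodrigues(v, axis, ct, st):
    cross = np.cross(axis[:, None, :], v)
    dot = (v * axis[:, None, :]).sum(-1, keepdims=True)
    return (v * ct[:, None, None] + cross * st[:, None, None]
            + axis[:, None, :] * dot * (1 - ct[:, None, None]))


def sample_window(t: float, rho0: float, n_seg: int = 24, walkers: int = 64,
                  steps: int = 30000, burn: int = 8000, bias_k: float = 4000.0,
                  seed: int = 1) -> np.ndarray:
    """Biased samples of rho = |R|/L around rho0 for a chain of stiffness N/t."""
    rng = np.random.default_rng(seed)
    k = n_seg / t
    try:
        phi = brentq(lambda p: np.sin(p / 2) / (p / 2) - rho0, 1e-6,
                     2 * np.pi - 1e-6)
    except ValueError:
        phi = 1e-4
    ang = np.linspace(0, phi, n_seg)
    tang = np.repeat(np.stack([np.cos(ang), np.sin(ang), 0 * ang], 1)[None],
                     walkers, axis=0)
    bend = k * (1 - (tang[:, 1:] * tang[:, :-1]).sum(-1)).sum(-1)
    rho = np.linalg.norm(tang.sum(1) / n_seg, axis=1)
    out = []
    for step in range(steps):
        i = int(rng.integers(1, n_seg))
        axis = rng.normal(size=(walkers, 3))
        axis /= np.linalg.norm(axis, axis=1, keepdims=True)
        theta = rng.normal(scale=0.22, size=walkers)
        ct, st = np.cos(theta), np.sin(theta)
        suffix = _rodrigues(tang[:, i:, :], axis, ct, st)
        cand = np.concatenate([tang[:, :i, :], suffix], axis=1)
        bend_new = k * (1 - (cand[:, 1:] * cand[:, :-1]).sum(-1)).sum(-1)
        rho_new = np.linalg.norm(cand.sum(1) / n_seg, axis=1)
        d_e = (bend_new - bend) + 0.5 * bias_k * ((rho_new - rho0) ** 2
                                                  - (rho - rho0) ** 2)
        accept = rng.random(walkers) < np.exp(-np.clip(d_e, -60, 60))
        tang[accept] = cand[accept]
        bend[accept] = bend_new[accept]
        rho[accept] = rho_new[accept]
        if step >= burn and step % 4 == 0:
            out.append(rho.copy())
    return np.concatenate(out)


def wham(centers, samples, bias_k, edges):
    mids = 0.5 * (edges[:-1] + edges[1:])
    hist = np.array([np.histogram(s, bins=edges)[0] for s in samples], float)
    counts = hist.sum(1)
    bias = 0.5 * bias_k * (mids[None, :] - np.asarray(centers)[:, None]) ** 2
    f = np.zeros(len(centers))
    for _ in range(5000):
        denom = (counts[:, None] * np.exp(np.clip(f[:, None] - bias,
                                                  -700, 700))).sum(0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, hist.sum(0) / denom, 0.0)
        f_new = -np.log(np.maximum(
            (p[None, :] * np.exp(-np.clip(bias, 0, 700))).sum(1), 1e-300))
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < 1e-9:
            break
        f = f_new
    return mids, p


def main() -> None:
    from visemech.ensemble import target_bend_weight_energy
    from visemech.params import MechParams

    ts = [float(a) for a in sys.argv[1:]] or [0.20, 0.30]
    bias_k = 4000.0
    for t in ts:
        centers = np.arange(0.30, 1.005, 0.025)
        samples = [sample_window(t, c, seed=1 + int(c * 1000), bias_k=bias_k)
                   for c in centers]
        edges = np.linspace(0.28, 1.0, 181)
        mids, p = wham(centers, samples, bias_k, edges)
        good = p > 0
        mids, p = mids[good], p[good]
        g_vec_mc = -np.log(p) + 2 * np.log(mids)   # radial -> directional

        params = MechParams()
        h = params.lp_ds * t
        model = np.asarray(target_bend_weight_energy(h, mids * h, params))
        anchor = np.argmin(np.abs(mids - 0.9))
        resid = (g_vec_mc - model) - (g_vec_mc[anchor] - model[anchor])
        sel = (mids > 0.45) & (mids < 0.97)
        print(f"t = {t:.2f}: max |residual| for x/L in (0.45, 0.97): "
              f"{np.abs(resid[sel]).max():.2f} kBT")
        for rho_probe in (0.5, 0.6, 0.7, 0.8, 0.9):
            i = np.argmin(np.abs(mids - rho_probe))
            print(f"    x/L = {mids[i]:.2f}: MC - model = {resid[i]:+.2f} kBT")


if __name__ == "__main__":
    main()
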