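"""Synthetic data generators emulating the vise experiments.

Every generator is a pure function of its spec and seed (numpy PCG64 via
``default_rng``), so outputs are bit-reproducible across runs and
platforms.  Two kinds of raw data are emulated:

* FRET curves (replicate means with SEM) for the five loop sizes, built
  from the package's own ensemble model plus additive Gaussian noise
  truncated to [0, 1] - the statistical structure of gel-derived curves
  averaged over four independent replicates;
* three-channel gel band intensities, generated by the exact inverse of
  the quantify module's crosstalk correction, scaled by a random per-band
  brightness and multiplied by log-normal channel noise.

The generators define the study conditions for the recovery and coverage
tests; they do not model gel images, electrophoretic mobility or dye
photophysics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import mwlc
from .ensemble import FretCurve, Mismatch, ViseDesign, predict_fret_curve
from .params import MechParams
from .quantify import ChannelTriple, CorrectionFactors, MetricSpec

RNG_ALGORITHM = "PCG64"  # numpy default_rng; fixed for cross-platform determinism


@dataclass(frozen=True)
class SynthSpec:
    """Conditions of a synthetic experiment.

    Defaults echo the study conditions: four independent replicates and a
    per-point FRET noise of 0.02, with 5% multiplicative intensity noise
    for channel data.
    """

    loops: tuple[int, ...] = (30, 36, 40, 46, 50)
    targets_by_loop: Mapping[int, tuple[int, ...]] | None = None
    params: MechParams = field(default_factory=MechParams)
    noise_sd: float = 0.02
    n_replicates: int = 4
    seed: int = 0
    channel_noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.channel_noise_cv < 0:
            raise ValueError("noise levels must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def targets(self, loop: int) -> tuple[int, ...]:
        if self.targets_by_loop is not None:
            return tuple(self.targets_by_loop[loop])
        return tuple(range(18, min(loop, 48) + 1))


def synth_fret_curves(spec: SynthSpec, mode: str = "wlc",
                      condition: str = "synthetic") -> list[FretCurve]:
    """Noisy replicate-averaged FRET curves from the ensemble model.

    Per replicate, ``E_obs = clip(E_model + N(0, noise_sd), 0, 1)``; the
    reported E is the replicate mean and sem the replicate standard error.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for loop in spec.loops:
        targets = spec.targets(loop)
        model = predict_fret_curve(loop, targets, spec.params, mode=mode)
        reps = np.clip(model.e[None, :] + rng.normal(
            0.0, spec.noise_sd, size=(spec.n_replicates, len(targets))), 0.0, 1.0)
        e = reps.mean(axis=0)
        sem = (reps.std(axis=0, ddof=1) / np.sqrt(spec.n_replicates)
               if spec.n_replicates > 1 else np.zeros(len(targets)))
        out.append(FretCurve(loop_id=model.loop_id, condition=condition,
                             target_len=np.array(targets), e=e, sem=sem))
    return out


def synth_channel_table(true_e: Mapping[str, float],
                        corr: CorrectionFactors = CorrectionFactors(),
                        spec: SynthSpec = SynthSpec()) -> list[ChannelTriple]:
    """Channel triples whose noise-free extraction recovers ``true_e`` exactly.

    Forward model (inverse of the quantify correction): with band
    brightness B, ``A_GG = B (1 - E)``, ``A_RR = B E`` and
    ``A_GR = gamma B E + alpha A_GG + delta A_RR``.  Brightness is drawn
    log-uniform over a decade (its value cancels in extraction) and each
    channel then receives independent log-normal noise of coefficient of
    variation ``channel_noise_cv``.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(np.log1p(spec.channel_noise_cv ** 2))
    out = []
    for construct, e in true_e.items():
        if not 0.0 <= e <= 1.0:
            raise ValueError(f"true E for {construct!r} must be in [0, 1]")
        b = 10.0 ** rng.uniform(3.0, 4.0)
        a_gg = b * (1.0 - e)
        a_rr = b * e
        a_gr = corr.gamma * b * e + corr.alpha * a_gg + corr.delta * a_rr
        noise = (np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=3))
                 if spec.channel_noise_cv > 0 else np.ones(3))
        out.append(ChannelTriple(construct, a_gg * noise[0], a_gr * noise[1],
                                 a_rr * noise[2]))
    return out


KCAL_PER_KBT_298 = 0.5924  # kcal/mol per kBT at 298 K


@dataclass(frozen=True)
class MismatchPanelResult:
    records_true: dict[str, float]      # noise-free dE per code
    records_noisy: dict[str, float]     # dE with curve noise applied
    ddg_kcal: dict[str, float]


def synth_mismatch_panel(ddg_kcal: Mapping[str, float],
                         spec: SynthSpec = SynthSpec(loops=(36,)),
                         metric: MetricSpec = MetricSpec(),
                         params: MechParams | None = None) -> MismatchPanelResult:
    """Flexibility panel for the eight single mismatches from the MWLC model.

    Each mismatch's literature destabilization (kcal/mol) maps linearly to
    the model's bubble relief (kBT at 298 K); flexibility is the two-point
    dE metric on the predicted kinked-ensemble curve, with additive noise
    ``noise_sd * sqrt(2/n_replicates)`` emulating the replicate-averaged
    difference of two curve points.  The noise-free values serve as ground
    truth for rank-recovery tests.
    """
    if len(ddg_kcal) != 8:
        raise ValueError("expected the eight single-mismatch codes")
    params = params if params is not None else spec.params
    rng = np.random.default_rng(spec.seed)
    loop = spec.loops[0]
    targets = (metric.h_ref, metric.h_kink)
    true: dict[str, float] = {}
    for code, ddg in ddg_kcal.items():
        mm = Mismatch(code=code, position=0, ddg=float(ddg) / KCAL_PER_KBT_298)
        curve = predict_fret_curve(loop, targets, params, mode="mwlc", mismatch=mm)
        true[code] = float(curve.e[1] - curve.e[0])
    scale = spec.noise_sd * np.sqrt(2.0 / spec.n_replicates)
    noisy = {code: v + rng.normal(0.0, scale) for code, v in true.items()}
    return MismatchPanelResult(true, noisy, dict(ddg_kcal))


#: Synthetic stand-in for a literature mismatch destabilization table
#: (kcal/mol), ordered like the nearest-neighbor stability ranking of the
#: eight single mismatches (G-G most stable, C-C least).  These are
#: illustrative inputs for tests and examples, not measured constants.
SYNTHETIC_DDG_TABLE = {
    "GG": 0.6, "GA": 1.0, "GT": 1.6, "AA": 2.0,
    "CT": 2.7, "CA": 3.0, "TT": 3.3, "CC": 3.8,
}
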