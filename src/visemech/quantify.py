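"""Downstream quantification: channel-based FRET extraction, flexibility
metrics for mismatched targets, and exact rank statistics.

Gel-scanner data arrive as three integrated band intensities per construct:
``A_GG`` (green excitation, green emission), ``A_GR`` (green excitation, red
emission) and ``A_RR`` (red excitation, red emission).  The standard
three-cube correction removes donor leakage (alpha) and acceptor direct
excitation (delta) from the sensitized-emission channel and normalizes by
the detection-efficiency ratio gamma.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .ensemble import MISMATCH_CODES, FretCurve
from .mechanics import DomainError


@dataclass(frozen=True)
class ChannelTriple:
    """Raw three-channel band intensities (arbitrary units) for one construct."""

    construct: str
    a_gg: float
    a_gr: float
    a_rr: float

    def __post_init__(self) -> None:
        if min(self.a_gg, self.a_gr, self.a_rr) < 0:
            raise DomainError("band intensities must be >= 0")


@dataclass(frozen=True)
class CorrectionFactors:
    """Crosstalk corrections: donor leakage alpha, direct excitation delta,
    detection-efficiency ratio gamma."""

    alpha: float = 0.08
    delta: float = 0.05
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.delta < 0:
            raise DomainError("alpha and delta must be >= 0")
        if self.gamma <= 0:
            raise DomainError("gamma must be > 0")


class UndefinedFretError(ValueError):
    """Raised when a band's corrected intensities admit no FRET value."""


@dataclass(frozen=True)
class FretResult:
    e: float
    clamped: bool


def fret_from_channels(triple: ChannelTriple,
                       corr: CorrectionFactors = CorrectionFactors()) -> FretResult:
    """FRET efficiency from a three-channel intensity triple.

    Sensitized emission ``F = A_GR - alpha A_GG - delta A_RR``; efficiency
    ``E = F / (F + gamma A_GG)``, clamped to [0, 1] with the ``clamped``
    flag set when crosstalk over-subtraction pushed it out of range.  The
    result is invariant under a common rescaling of all three intensities.
    """
    f = triple.a_gr - corr.alpha * triple.a_gg - corr.delta * triple.a_rr
    denom = f + corr.gamma * triple.a_gg
    if denom <= 0:
        raise UndefinedFretError(
            f"construct {triple.construct!r}: corrected total intensity "
            f"{denom:.4g} <= 0; FRET is undefined for this band")
    e = f / denom
    clamped = not (0.0 <= e <= 1.0)
    return FretResult(float(min(max(e, 0.0), 1.0)), clamped)


def fret_from_channel_table(triples: Sequence[ChannelTriple],
                            corr: CorrectionFactors = CorrectionFactors()
                            ) -> dict[str, FretResult]:
    return {t.construct: fret_from_channels(t, corr) for t in triples}


# ---------------------------------------------------------------------------
# Mismatch flexibility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricSpec:
    """Definition of the two-point FRET contrast metric dE = E(h_kink) - E(h_ref)."""

    loop_id: str = "loop36"
    h_kink: int = 34
    h_ref: int = 24


@dataclass(frozen=True)
class MismatchRecord:
    """Flexibility of one target variant: dE_FRET, higher = more flexible."""

    code: str               # mismatch identity or "intact"
    position: int           # nt offset from the target apex
    ddg: float              # literature destabilization, kcal/mol (input)
    flexibility: float      # dE_FRET, dimensionless

    def __post_init__(self) -> None:
        if self.code != "intact" and self.code not in MISMATCH_CODES:
            raise DomainError(f"unknown mismatch code {self.code!r}")
        if self.code == "intact" and self.ddg != 0:
            raise DomainError("intact targets have ddg = 0")
        if self.code != "intact" and self.ddg < 0:
            raise DomainError("mismatch ddg must be >= 0")


def _curve_value(curve: FretCurve, h: int) -> float:
    idx = np.nonzero(curve.target_len == h)[0]
    if idx.size == 0:
        raise ValueError(
            f"curve {curve.loop_id}/{curve.condition} lacks target length {h} "
            f"(has {list(map(int, curve.target_len))})")
    return float(curve.e[idx[0]])


def flexibility_metric(curves: Mapping[str, FretCurve],
                       spec: MetricSpec = MetricSpec(),
                       ddg: Mapping[str, float] | None = None
                       ) -> list[MismatchRecord]:
    """dE_FRET flexibility for each construct's curve at the metric's loop.

    ``curves`` maps a construct label (mismatch code or "intact") to its
    FRET curve for ``spec.loop_id``; ``ddg`` optionally supplies the
    literature destabilization (kcal/mol) recorded on each output row.
    """
    out = []
    for code, curve in curves.items():
        if curve.loop_id != spec.loop_id:
            raise ValueError(f"curve for {code!r} is {curve.loop_id}, "
                             f"metric expects {spec.loop_id}")
        de = _curve_value(curve, spec.h_kink) - _curve_value(curve, spec.h_ref)
        out.append(MismatchRecord(code=code, position=0,
                                  ddg=float((ddg or {}).get(code, 0.0)),
                                  flexibility=de))
    return out


# ---------------------------------------------------------------------------
# Exact Spearman rank correlation
# ---------------------------------------------------------------------------

_MAX_EXACT_N = 9


def spearman_exact(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman's rho with a two-sided exact permutation p-value.

    rho uses midranks.  For tie-free samples of n <= 9 the p-value is the
    exact fraction of all n! rank permutations with |rho| at least as large
    as observed; with ties or larger n the large-sample approximation is
    used and a warning is issued.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input has undefined rank correlation")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    tie_free = (np.unique(x).size == n) and (np.unique(y).size == n)
    if tie_free:
        rho = 1.0 - 6.0 * np.sum((rx - ry) ** 2) / (n ** 3 - n)
    else:
        rho = float(np.corrcoef(rx, ry)[0, 1])
    if not tie_free or n > _MAX_EXACT_N:
        warnings.warn(
            "ties or n > 9: falling back to the large-sample Spearman p-value",
            stacklevel=2)
        return float(rho), float(stats.spearmanr(x, y).pvalue)
    # exact enumeration over all n! permutations of one rank vector
    perms = np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)
    rho_all = 1.0 - 6.0 * ((perms - rx[None, :]) ** 2).sum(axis=1) / (n ** 3 - n)
    count = int(np.sum(np.abs(rho_all) >= abs(rho) - 1e-12))
    return float(rho), count / math.factorial(n)
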