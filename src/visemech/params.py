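"""Mechanical and thermodynamic parameters of the molecular-vise model.

All quantities are kept in a single internal unit system:

* lengths in nanometres (nm),
* forces in piconewtons (pN),
* energies in units of the thermal energy ``kB*T`` at the parameter set's
  own temperature,
* per-base-pair free energies in kBT/bp, positive meaning a cost to open.

The Boltzmann constant is ``0.0138065 pN nm / K``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any, Mapping

KB_PN_NM_PER_K: float = 0.0138065
"""Boltzmann constant in pN nm per kelvin."""


class ParameterError(ValueError):
    """Raised for physically inadmissible parameter values."""


@dataclass(frozen=True)
class MechParams:
    """Mechanical/thermodynamic constants of duplex DNA, ssDNA and the dyes.

    Parameters
    ----------
    lp_ds:
        Persistence length of double-stranded DNA (nm). The bending modulus
        is ``kappa = lp_ds * kB * T``.
    rise_ds:
        Helical rise of B-form DNA (nm per base pair).
    temperature:
        Absolute temperature (K).
    lp_melt:
        Persistence length of a locally melted (bubble) region (nm); must be
        smaller than ``lp_ds``.
    ss_contour_per_nt:
        Contour length of single-stranded DNA per nucleotide (nm).
    ss_kuhn:
        Kuhn length of the ssDNA freely jointed chain (nm).
    ss_stretch_mod:
        ssDNA stretch modulus (pN); ``inf`` gives the inextensible FJC.
    dg_bp_stem:
        Base-pairing free energy of one A-T stem base pair (kBT/bp, > 0 = cost
        to unzip).  With the default ssDNA parameterization the default of
        1.3 kBT/bp puts the stem's equilibrium unzipping plateau at 10.0 pN,
        consistent with the ~9 pN A-T unzipping force within the ssDNA-model
        uncertainty; use :func:`visemech.mechanics.calibrate_stem_energy` to
        pin the plateau to an exact force.
    dg_melt_target:
        Free energy to melt one base pair of the target duplex (kBT/bp).
    sigma_coop:
        Bubble nucleation (cooperativity/loop factor) penalty (kBT), paid
        once per bubble regardless of its size.
    forster_radius:
        Foerster radius R0 of the dye pair (nm).
    dye_offset:
        Fixed separation added to the model's dye-to-dye distance (nm).
    """

    lp_ds: float = 46.5
    rise_ds: float = 0.34
    temperature: float = 298.0
    lp_melt: float = 1.0
    ss_contour_per_nt: float = 0.59
    ss_kuhn: float = 1.5
    ss_stretch_mod: float = 800.0
    dg_bp_stem: float = 1.3  # unzipping plateau 10.0 pN, ~the 9 pN A-T force
    dg_melt_target: float = 2.5
    sigma_coop: float = 26.0  # reference-condition calibration; see saltmodel
    forster_radius: float = 6.2
    dye_offset: float = 0.0

    def __post_init__(self) -> None:
        positive = (
            "lp_ds", "rise_ds", "temperature", "lp_melt", "ss_contour_per_nt",
            "ss_kuhn", "ss_stretch_mod", "dg_bp_stem", "forster_radius",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.lp_melt >= self.lp_ds:
            raise ParameterError(
                f"lp_melt ({self.lp_melt}) must be smaller than lp_ds ({self.lp_ds})"
            )
        if self.dg_melt_target < 0 or self.sigma_coop < 0 or self.dye_offset < 0:
            raise ParameterError("dg_melt_target, sigma_coop and dye_offset must be >= 0")

    @property
    def kbt(self) -> float:
        """Thermal energy kB*T in pN nm."""
        return KB_PN_NM_PER_K * self.temperature

    @property
    def kappa(self) -> float:
        """Bending modulus of dsDNA, lp_ds * kB * T, in pN nm^2."""
        return self.lp_ds * self.kbt

    @property
    def kappa_melt(self) -> float:
        """Bending modulus of a melted region, lp_melt * kB * T, in pN nm^2."""
        return self.lp_melt * self.kbt

    def replace(self, **changes: float) -> "MechParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


# Mapping between the nested config-file layout and the flat dataclass.
_CONFIG_SECTIONS: dict[str, dict[str, str]] = {
    "dsDNA": {"persistence_length_nm": "lp_ds", "rise_nm_per_bp": "rise_ds"},
    "ssDNA": {
        "contour_nm_per_nt": "ss_contour_per_nt",
        "kuhn_length_nm": "ss_kuhn",
        "stretch_modulus_pN": "ss_stretch_mod",
        "melt_persistence_length_nm": "lp_melt",
    },
    "thermodynamics": {
        "temperature_K": "temperature",
        "stem_bp_energy_kbt": "dg_bp_stem",
        "target_melt_energy_kbt_per_bp": "dg_melt_target",
        "bubble_cooperativity_kbt": "sigma_coop",
    },
    "dyes": {"forster_radius_nm": "forster_radius", "dye_offset_nm": "dye_offset"},
}


def params_from_config(config: Mapping[str, Any], base: MechParams | None = None) -> MechParams:
    """Build a :class:`MechParams` from a nested config mapping.

    Unknown sections or keys raise :class:`ParameterError` naming the key, so
    a typo never silently falls back to a default.
    """
    base = base if base is not None else MechParams()
    changes: dict[str, float] = {}
    for section, entries in config.items():
        if section not in _CONFIG_SECTIONS:
            raise ParameterError(f"unknown config section {section!r}")
        if not isinstance(entries, Mapping):
            raise ParameterError(f"config section {section!r} must be a mapping")
        known = _CONFIG_SECTIONS[section]
        for key, value in entries.items():
            if key not in known:
                raise ParameterError(f"unknown config key {section}.{key}")
            changes[known[key]] = float(value)
    return base.replace(**changes)


def params_to_config(params: MechParams) -> dict[str, dict[str, float]]:
    """Inverse of :func:`params_from_config` (round-trips exactly)."""
    out: dict[str, dict[str, float]] = {}
    for section, entries in _CONFIG_SECTIONS.items():
        out[section] = {key: getattr(params, attr) for key, attr in entries.items()}
    return out


def params_key(params: MechParams) -> tuple:
    """Hashable identity of a parameter set (used for model-curve caching)."""
    return tuple(getattr(params, f.name) for f in fields(params))
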