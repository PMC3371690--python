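"""Materials for cell-like media: elemental compositions and scaling rules.

The liquid-water dielectric model is the only medium for which the package
carries a full energy-loss function.  Other biological materials (cytoplasm,
nuclear material, dense organelles) are handled by scaling the water cross
sections:

* inelastic interactions scale with the electron-density ratio, optionally
  refined by the ratio of Bethe logarithms with each material's Bragg-rule
  mean excitation energy;
* elastic scattering scales with the Z^2-weighted atom density ratio.

This mirrors the pragmatic use of per-element (atomic) interaction data for
heterogeneous cell phantoms while keeping a single condensed-phase loss
function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import (
    N_AVOGADRO,
    WATER_DENSITY_G_CM3,
    WATER_ELECTRON_DENSITY_NM3,
    WATER_MOLECULE_DENSITY_NM3,
)

__all__ = ["Element", "Material", "material_from_composition", "WATER",
           "CYTOPLASM", "NUCLEUS", "ORGANELLE", "bragg_mean_excitation_energy"]


@dataclass(frozen=True)
class Element:
    symbol: str
    z: int
    atomic_mass: float
    mean_excitation_ev: float  # ICRU-style elemental I value


ELEMENTS: dict[str, Element] = {
    "H": Element("H", 1, 1.008, 19.2),
    "C": Element("C", 6, 12.011, 78.0),
    "N": Element("N", 7, 14.007, 82.0),
    "O": Element("O", 8, 15.999, 95.0),
    "P": Element("P", 15, 30.974, 173.0),
}

#: Z^2-weighted atom density of water (nm^-3), reference for elastic scaling.
WATER_Z2_DENSITY_NM3 = WATER_MOLECULE_DENSITY_NM3 * (2 * 1**2 + 8**2)


def bragg_mean_excitation_energy(mass_fractions: dict[str, float]) -> float:
    """Bragg-additivity mean excitation energy (eV).

    Electron-weighted log-average of the elemental I values:
    ln I = sum_i (w_i Z_i/A_i ln I_i) / sum_i (w_i Z_i/A_i).
    """
    num = 0.0
    den = 0.0
    for sym, w in mass_fractions.items():
        el = ELEMENTS[sym]
        weight = w * el.z / el.atomic_mass
        num += weight * math.log(el.mean_excitation_ev)
        den += weight
    if den <= 0:
        raise ValueError("composition has no electrons")
    return math.exp(num / den)


@dataclass(frozen=True)
class Material:
    """A homogeneous medium defined by elemental mass fractions and density."""

    name: str
    mass_fractions: dict[str, float] = field(hash=False)
    density_g_cm3: float = 1.0

    def __post_init__(self) -> None:
        if self.density_g_cm3 < 0:
            raise ValueError("density must be non-negative")
        total = sum(self.mass_fractions.values())
        if self.density_g_cm3 > 0 and abs(total - 1.0) > 1.0e-6:
            raise ValueError("mass fractions must sum to 1")

    @property
    def electron_density_nm3(self) -> float:
        n = 0.0
        for sym, w in self.mass_fractions.items():
            el = ELEMENTS[sym]
            n += w * el.z / el.atomic_mass
        return self.density_g_cm3 * N_AVOGADRO * n / 1.0e21

    @property
    def z2_atom_density_nm3(self) -> float:
        n = 0.0
        for sym, w in self.mass_fractions.items():
            el = ELEMENTS[sym]
            n += w * el.z * el.z / el.atomic_mass
        return self.density_g_cm3 * N_AVOGADRO * n / 1.0e21

    @property
    def mean_excitation_ev(self) -> float:
        return bragg_mean_excitation_energy(self.mass_fractions)

    # -- scaling factors relative to liquid water ---------------------------

    def inelastic_scale(self, bethe_log_arg_ev: float | None = None,
                        water_i_ev: float = 69.0) -> float:
        """Multiplier for water inelastic inverse mean free paths.

        Electron-density ratio; if ``bethe_log_arg_ev`` (the 2*m_e*v^2-like
        argument of the Bethe logarithm for the projectile of interest) is
        given, a logarithmic mean-excitation-energy correction is applied.
        """
        if self.density_g_cm3 == 0.0:
            return 0.0
        scale = self.electron_density_nm3 / WATER_ELECTRON_DENSITY_NM3
        if bethe_log_arg_ev is not None:
            num = math.log(max(bethe_log_arg_ev / self.mean_excitation_ev, 1.001))
            den = math.log(max(bethe_log_arg_ev / water_i_ev, 1.001))
            scale *= num / den
        return scale

    def elastic_scale(self) -> float:
        """Multiplier for water elastic inverse mean free paths."""
        if self.density_g_cm3 == 0.0:
            return 0.0
        return self.z2_atom_density_nm3 / WATER_Z2_DENSITY_NM3


def material_from_composition(
    fractions: dict[str, float], density_g_cm3: float, name: str = "custom"
) -> Material:
    """Build a material from (possibly unnormalised) mass fractions.

    Fractions are over the biological elements H, C, N, O, P; they are
    renormalised to sum to exactly one.
    """
    if any(v < 0 for v in fractions.values()):
        raise ValueError("mass fractions must be non-negative")
    unknown = set(fractions) - set(ELEMENTS)
    if unknown:
        raise ValueError(f"unknown elements: {sorted(unknown)}")
    total = sum(fractions.values())
    if total <= 0:
        raise ValueError("at least one mass fraction must be positive")
    norm = {k: v / total for k, v in fractions.items() if v > 0}
    return Material(name=name, mass_fractions=norm, density_g_cm3=density_g_cm3)


WATER = material_from_composition({"H": 0.1119, "O": 0.8881}, WATER_DENSITY_G_CM3, "water")

#: Cytoplasm: O 58%, C 20%, H 9%, N 8.5%, P 4.5% at 1 g/cm^3.
CYTOPLASM = material_from_composition(
    {"O": 0.58, "C": 0.20, "H": 0.09, "N": 0.085, "P": 0.045}, 1.0, "cytoplasm"
)

#: Nuclear material: O 74.5%, H 11%, C 9%, N 3%, P 2.5% at 1 g/cm^3.
NUCLEUS = material_from_composition(
    {"O": 0.745, "H": 0.11, "C": 0.09, "N": 0.03, "P": 0.025}, 1.0, "nucleus"
)

#: Organelle overdensities: nuclear composition at 10 g/cm^3.
ORGANELLE = material_from_composition(
    {"O": 0.745, "H": 0.11, "C": 0.09, "N": 0.03, "P": 0.025}, 10.0, "organelle"
)

#: Empty space outside the cell (no interactions).
VACUUM = Material(name="vacuum", mass_fractions={}, density_g_cm3=0.0)
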