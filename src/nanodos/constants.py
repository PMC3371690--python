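"""Physical constants and liquid-water reference quantities.

Internal unit system used throughout the package:

* lengths in nanometres,
* energies in electronvolts,
* momentum transfer ``q`` in atomic units (a.u., i.e. units of hbar/a0),
* cross sections in nm^2, inverse mean free paths in nm^-1.

With ``q`` in a.u. a free electron of momentum q carries kinetic energy
``RYDBERG_EV * q**2`` (eV), which is the form used for kinematic limits and
for the quadratic dispersion of the energy-loss function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Bohr radius a0 = hbar^2 / (e^2 m_e), in nm.
BOHR_RADIUS_NM = 0.052917721

#: Rydberg energy, eV.  A free electron with momentum q (a.u.) has E = RY * q^2.
RYDBERG_EV = 13.605693

#: Electron rest energy m_e c^2, eV.
ELECTRON_REST_EV = 510998.95

#: e^2 in Gaussian units, eV nm.
E2_EV_NM = 1.4399645

#: hbar c, eV nm.
HBAR_C_EV_NM = 197.3269804

#: Classical electron radius, nm.
R_E_NM = E2_EV_NM / ELECTRON_REST_EV

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23

#: 1 eV in joule.
EV_TO_J = 1.602176634e-19

# Liquid water at standard conditions.
WATER_DENSITY_G_CM3 = 1.0
WATER_MOLAR_MASS = 18.01528
WATER_ELECTRONS_PER_MOLECULE = 10

#: Water molecules per nm^3 at 1 g/cm^3.
WATER_MOLECULE_DENSITY_NM3 = (
    N_AVOGADRO * WATER_DENSITY_G_CM3 / WATER_MOLAR_MASS / 1.0e21
)

#: Electrons per nm^3 in liquid water at 1 g/cm^3.
WATER_ELECTRON_DENSITY_NM3 = WATER_MOLECULE_DENSITY_NM3 * WATER_ELECTRONS_PER_MOLECULE

# Projectile rest masses, eV/c^2.
PROTON_REST_EV = 938.27208816e6
ALPHA_REST_EV = 3727.3794066e6


def plasma_energy_ev(electron_density_nm3: float) -> float:
    """Plasma energy E_p = hbar * sqrt(4 pi n_e e^2 / m_e) for a free-electron
    gas of number density ``electron_density_nm3`` (nm^-3), in eV.

    For liquid water (334.3 electrons/nm^3) this evaluates to ~21.5 eV, which
    is why the energy-loss function of water peaks close to 21 eV.
    """
    if electron_density_nm3 < 0:
        raise ValueError("electron density must be non-negative")
    return HBAR_C_EV_NM * math.sqrt(4.0 * math.pi * R_E_NM * electron_density_nm3)


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of the constants entering the inelastic-scattering formulae."""

    bohr_radius_nm: float = BOHR_RADIUS_NM
    electron_rest_ev: float = ELECTRON_REST_EV
    rydberg_ev: float = RYDBERG_EV
    hbar_c_ev_nm: float = HBAR_C_EV_NM

    def __post_init__(self) -> None:
        for name in ("bohr_radius_nm", "electron_rest_ev", "rydberg_ev", "hbar_c_ev_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def beta_squared(kinetic_ev: float, rest_ev: float) -> float:
    """Relativistic beta^2 of a particle of kinetic energy ``kinetic_ev``."""
    gamma = 1.0 + kinetic_ev / rest_ev
    return 1.0 - 1.0 / (gamma * gamma)
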