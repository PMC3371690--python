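"""Photon transport in water: photoelectric, Compton and Rayleigh channels.

Valid for 1 keV - 1 MeV photons.  The incoherent channel uses the exact
Klein-Nishina cross section on free electrons (times the electron density);
scattered-photon energies are drawn with Kahn's rejection method, which
samples the Klein-Nishina differential exactly.  Photoelectric and coherent
coefficients are log-log interpolations of a compact fixture table.  Pair
production is impossible below 1.022 MeV and is a hard error here.

All secondary electrons are handed to the event-by-event electron transport
(or deposited locally in pilot/dose mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

import numpy as np

from .constants import ELECTRON_REST_EV, R_E_NM, WATER_ELECTRON_DENSITY_NM3
from .electron import (
    ElectronTables,
    ParticleState,
    TransportConfig,
    _deflect,
    transport_electron,
)

__all__ = [
    "PhotonModel",
    "PhotonTransportConfig",
    "PhotonHistory",
    "photon_interact",
    "transport_photon",
    "klein_nishina_total_nm2",
    "klein_nishina_dcs",
    "sample_compton_energy",
]

#: K-shell binding energy of oxygen (the dominant photoabsorber in water), eV.
K_SHELL_BINDING_EV = 543.1

_CM2G_TO_PER_NM = 1.0e-7  # mu/rho [cm^2/g] * rho [g/cm^3] -> nm^-1


def klein_nishina_total_nm2(e_ev: float) -> float:
    """Total Klein-Nishina cross section per free electron, nm^2."""
    k = e_ev / ELECTRON_REST_EV
    if k <= 0:
        raise ValueError("photon energy must be positive")
    pre = 2.0 * math.pi * R_E_NM**2
    t1 = (1.0 + k) / (k * k) * (2.0 * (1.0 + k) / (1.0 + 2.0 * k) - math.log(1.0 + 2.0 * k) / k)
    t2 = math.log(1.0 + 2.0 * k) / (2.0 * k)
    t3 = -(1.0 + 3.0 * k) / (1.0 + 2.0 * k) ** 2
    return pre * (t1 + t2 + t3)


def klein_nishina_dcs(e_ev: float, e_scattered_ev) -> np.ndarray | float:
    """d(sigma)/dE' per electron (nm^2/eV) vs scattered-photon energy E'."""
    k = e_ev / ELECTRON_REST_EV
    ep = np.asarray(e_scattered_ev, dtype=float)
    emin = e_ev / (1.0 + 2.0 * k)
    eps = ep / e_ev
    cos_t = 1.0 - (e_ev / ep - 1.0) / k
    valid = (ep >= emin * (1 - 1e-12)) & (ep <= e_ev * (1 + 1e-12))
    sin2 = 1.0 - np.clip(cos_t, -1.0, 1.0) ** 2
    val = (
        math.pi
        * R_E_NM**2
        / (k * e_ev)
        * (eps + 1.0 / eps - sin2)
    )
    out = np.where(valid, val, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def sample_compton_energy(e_ev: float, rng) -> tuple[float, float]:
    """(scattered photon energy, cos of photon scattering angle), exact KN.

    Kahn's composition-rejection algorithm on eps = E'/E.
    """
    k = e_ev / ELECTRON_REST_EV
    eps0 = 1.0 / (1.0 + 2.0 * k)
    alpha1 = math.log(1.0 / eps0)
    alpha2 = 0.5 * (1.0 - eps0 * eps0)
    while True:
        if rng.random() * (alpha1 + alpha2) < alpha1:
            eps = eps0 * math.exp(alpha1 * rng.random())
        else:
            eps = math.sqrt(eps0 * eps0 + (1.0 - eps0 * eps0) * rng.random())
        one_minus_cos = (1.0 - eps) / (k * eps)
        cos_t = 1.0 - one_minus_cos
        sin2 = one_minus_cos * (2.0 - one_minus_cos)
        greject = 1.0 - eps * sin2 / (1.0 + eps * eps)
        if rng.random() <= greject:
            return eps * e_ev, cos_t


class PhotonModel:
    """Channel cross sections and per-interaction physics for photons."""

    def __init__(self, electron_density_nm3: float = WATER_ELECTRON_DENSITY_NM3,
                 density_g_cm3: float = 1.0) -> None:
        text = resources.files("nanodos.data").joinpath("photon_xs.tsv").read_text()
        rows = [
            tuple(float(v) for v in line.split())
            for line in text.splitlines()
            if line.strip() and not line.startswith("#")
        ]
        self._log_e = np.log([r[0] * 1.0e3 for r in rows])  # eV
        self._log_pe = np.log([r[1] for r in rows])
        self._log_ray = np.log([r[2] for r in rows])
        self.electron_density_nm3 = electron_density_nm3
        self.density_g_cm3 = density_g_cm3

    def _interp(self, log_tab: np.ndarray, e_ev: float) -> float:
        x = math.log(min(max(e_ev, math.exp(self._log_e[0])), math.exp(self._log_e[-1])))
        return math.exp(float(np.interp(x, self._log_e, log_tab)))

    def mu_photoelectric(self, e_ev: float) -> float:
        """Photoelectric attenuation coefficient, nm^-1."""
        return self._interp(self._log_pe, e_ev) * self.density_g_cm3 * _CM2G_TO_PER_NM

    def mu_rayleigh(self, e_ev: float) -> float:
        return self._interp(self._log_ray, e_ev) * self.density_g_cm3 * _CM2G_TO_PER_NM

    def mu_compton(self, e_ev: float) -> float:
        return klein_nishina_total_nm2(e_ev) * self.electron_density_nm3

    def mu_pair(self, e_ev: float) -> float:
        """Pair production: impossible below the 1.022 MeV threshold."""
        if e_ev < 2.0 * ELECTRON_REST_EV:
            raise ValueError("pair production below 1.022 MeV is impossible")
        raise NotImplementedError("pair production is outside this model's domain")

    def mu_total(self, e_ev: float) -> float:
        """Total attenuation coefficient (sum of the open channels), nm^-1."""
        return self.mu_photoelectric(e_ev) + self.mu_rayleigh(e_ev) + self.mu_compton(e_ev)


@dataclass
class PhotonInteraction:
    kind: str  # photoelectric | compton | rayleigh
    position_nm: tuple[float, float, float]
    electron_energy_ev: float
    electron_direction: tuple[float, float, float] | None
    scattered_energy_ev: float
    scattered_direction: tuple[float, float, float] | None
    local_deposit_ev: float


def photon_interact(
    model: PhotonModel, state: ParticleState, rng
) -> PhotonInteraction:
    """Sample one photon interaction at the current position.

    Channel probabilities follow the channel cross sections.  Compton
    scattering uses exact Klein-Nishina kinematics (scattered energy within
    [E/(1+2E/m_e c^2), E]); the photoelectron carries E - B_K with the
    K-shell binding deposited locally; Rayleigh changes direction only.
    """
    e = state.kinetic_energy_ev
    if not (1.0e3 < e < 1.0e6):
        raise ValueError("photon energy outside the 1 keV - 1 MeV model domain")
    x, y, z = state.position_nm
    ux, uy, uz = state.direction
    mu_pe = model.mu_photoelectric(e)
    mu_c = model.mu_compton(e)
    mu_r = model.mu_rayleigh(e)
    r = rng.random() * (mu_pe + mu_c + mu_r)
    if r < mu_pe:
        # photoelectron: dipole-like sin^2 polar distribution
        while True:
            cos_t = 1.0 - 2.0 * rng.random()
            if rng.random() <= 1.0 - cos_t * cos_t:
                break
        phi = 2.0 * math.pi * rng.random()
        d = _deflect(ux, uy, uz, cos_t, phi)
        b = min(K_SHELL_BINDING_EV, e)
        return PhotonInteraction(
            "photoelectric", (x, y, z), e - b, d, 0.0, None, b
        )
    if r < mu_pe + mu_c:
        e_sc, cos_t = sample_compton_energy(e, rng)
        phi = 2.0 * math.pi * rng.random()
        d_sc = _deflect(ux, uy, uz, cos_t, phi)
        # electron direction from momentum conservation (photon momenta E/c)
        px = e * ux - e_sc * d_sc[0]
        py = e * uy - e_sc * d_sc[1]
        pz = e * uz - e_sc * d_sc[2]
        norm = math.sqrt(px * px + py * py + pz * pz)
        d_el = (px / norm, py / norm, pz / norm) if norm > 0 else (ux, uy, uz)
        return PhotonInteraction(
            "compton", (x, y, z), e - e_sc, d_el, e_sc, d_sc, 0.0
        )
    # Rayleigh: elastic, Thomson-like angular shape, zero energy deposit
    while True:
        cos_t = 1.0 - 2.0 * rng.random()
        if rng.random() <= 0.5 * (1.0 + cos_t * cos_t):
            break
    phi = 2.0 * math.pi * rng.random()
    d = _deflect(ux, uy, uz, cos_t, phi)
    return PhotonInteraction("rayleigh", (x, y, z), 0.0, None, e, d, 0.0)


@dataclass
class PhotonTransportConfig:
    box_nm: tuple[float, float, float, float, float, float] | None = None
    track_secondaries_at: Callable[[float, float, float], bool] | None = None
    electron_config: TransportConfig = field(default_factory=TransportConfig)
    min_energy_ev: float = 2.0e3  # photons below this are absorbed locally


@dataclass
class PhotonHistory:
    initial_energy_ev: float
    energy_deposited_ev: float = 0.0
    energy_escaped_ev: float = 0.0
    n_interactions: int = 0
    n_compton: int = 0
    n_photoelectric: int = 0
    n_rayleigh: int = 0
    primary_uncollided: bool = True

    @property
    def closure_residual(self) -> float:
        total = self.energy_deposited_ev + self.energy_escaped_ev
        return abs(total - self.initial_energy_ev) / max(self.initial_energy_ev, 1.0)


def transport_photon(
    state: ParticleState,
    model: PhotonModel,
    config: PhotonTransportConfig,
    tables: ElectronTables,
    rng,
    scorer=None,
) -> PhotonHistory:
    """Follow a photon through exponential free flights until absorption,
    degradation below the model floor, or exit from the world box."""
    hist = PhotonHistory(initial_energy_ev=state.kinetic_energy_ev)
    e = state.kinetic_energy_ev
    x, y, z = state.position_nm
    ux, uy, uz = state.direction
    box = config.box_nm
    track_at = config.track_secondaries_at

    def inside(px, py, pz) -> bool:
        if box is None:
            return True
        return (
            box[0] <= px <= box[1]
            and box[2] <= py <= box[3]
            and box[4] <= pz <= box[5]
        )

    def handle_electron(w_ev: float, direction, px, py, pz) -> None:
        if w_ev <= 0:
            return
        if track_at is not None and not track_at(px, py, pz):
            hist.energy_deposited_ev += w_ev
            if scorer is not None:
                scorer.add_deposit(px, py, pz, w_ev, -1)
            return
        el = ParticleState(
            "electron", (px, py, pz), direction, w_ev, generation=1
        )
        tr = transport_electron(el, config.electron_config, tables, rng, scorer=scorer)
        hist.energy_deposited_ev += tr.energy_deposited_ev
        hist.energy_escaped_ev += tr.energy_escaped_ev

    while True:
        mu = model.mu_total(e)
        if mu <= 0.0:
            hist.energy_escaped_ev += e
            return hist
        path = -math.log(1.0 - rng.random()) / mu
        x += path * ux
        y += path * uy
        z += path * uz
        if not inside(x, y, z):
            hist.energy_escaped_ev += e
            return hist
        st = ParticleState("photon", (x, y, z), (ux, uy, uz), e)
        act = photon_interact(model, st, rng)
        hist.n_interactions += 1
        hist.primary_uncollided = False
        if act.kind == "rayleigh":
            hist.n_rayleigh += 1
            ux, uy, uz = act.scattered_direction
            continue
        if act.local_deposit_ev > 0:
            hist.energy_deposited_ev += act.local_deposit_ev
            if scorer is not None:
                scorer.add_deposit(x, y, z, act.local_deposit_ev, -1)
        if act.kind == "photoelectric":
            hist.n_photoelectric += 1
            handle_electron(act.electron_energy_ev, act.electron_direction, x, y, z)
            return hist
        # Compton
        hist.n_compton += 1
        handle_electron(act.electron_energy_ev, act.electron_direction, x, y, z)
        e = act.scattered_energy_ev
        ux, uy, uz = act.scattered_direction
        if e < config.min_energy_ev:
            # below the channel-model floor: assume local photoabsorption
            hist.energy_deposited_ev += e
            if scorer is not None:
                scorer.add_deposit(x, y, z, e, -1)
            return hist
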