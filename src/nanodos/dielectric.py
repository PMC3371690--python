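"""Semiempirical dielectric response of liquid water.

The energy-loss function (ELF) ``Im[-1/eps(q, E)]`` is represented as a sum of
Drude oscillator channels — five discrete electronic excitations and five
ionization shells — extended to finite momentum transfer ``q`` by a quadratic
(impulse) dispersion of each transition energy,

    E_k(q) = E_k + alpha_k * q^2 / (2 m_e),

so that the crest of the surface (the Bethe ridge) tends to the free-electron
locus ``E = q^2 / 2 m_e`` at large ``q``.  The doubly differential inverse
mean free path for inelastic scattering of an electron of energy ``T`` is

    d2(Lambda) / dq dE = Im[-1/eps(q, E)] / (pi a0 q T)

inside the kinematically allowed band ``q_-(T,E) <= q <= q_+(T,E)`` and zero
outside.  Channel parameters live in a versioned plain-text fixture
(``data/drude_channels.tsv``); they are a semiempirical reconstruction
constrained by the 8.23 eV lowest excitation threshold, the ~21 eV optical
ELF peak of liquid water, the f-sum rule and a mean excitation energy close
to the Bragg-additivity value for water.

Collective (plasmon-like) excitations and autoionization are deliberately not
part of this model; see the package methods note.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .constants import (
    BOHR_RADIUS_NM,
    RYDBERG_EV,
    E2_EV_NM,
    WATER_DENSITY_G_CM3,
    WATER_ELECTRON_DENSITY_NM3,
    plasma_energy_ev,
)

__all__ = [
    "DrudeChannel",
    "ELFModel",
    "InelasticKinematics",
    "CrossSectionTable",
    "optical_elf",
    "bethe_surface",
    "differential_inverse_mfp",
    "channel_inverse_mfp",
    "collision_stopping_power",
    "sample_energy_momentum",
    "mean_excitation_energy",
    "bethe_stopping_electron",
    "load_default_model",
]

EXCITATION = "excitation"
IONIZATION = "ionization"


@dataclass(frozen=True)
class DrudeChannel:
    """One Drude oscillator channel of the water ELF.

    ``kind`` is either ``"excitation"`` (discrete electronic excitation; the
    energy transferred in a collision is the transition energy itself) or
    ``"ionization"`` (an ionization shell with binding energy ``B_k``; the
    secondary electron carries ``E - B_k``).
    """

    kind: str
    label: str
    transition_energy_ev: float
    oscillator_strength: float
    damping_width_ev: float
    binding_energy_ev: float | None = None
    dispersion_coefficient: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in (EXCITATION, IONIZATION):
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if self.transition_energy_ev <= 0:
            raise ValueError("transition energy must be positive")
        if self.oscillator_strength <= 0:
            raise ValueError("oscillator strength must be positive")
        if self.damping_width_ev <= 0:
            raise ValueError("damping width must be positive")
        if self.kind == IONIZATION:
            if self.binding_energy_ev is None or self.binding_energy_ev <= 0:
                raise ValueError("ionization shells need a positive binding energy")
            if self.binding_energy_ev > self.transition_energy_ev:
                raise ValueError(
                    "binding energy may not exceed the channel transition energy"
                )

    @property
    def threshold_ev(self) -> float:
        """Minimum energy transfer the channel can absorb.

        The Drude lineshape itself extends below threshold; for cross-section
        integrals each channel is truncated here (transition energy for
        excitations, binding energy for ionization shells) so that inverse
        mean free paths vanish identically below threshold.
        """
        if self.kind == EXCITATION:
            return self.transition_energy_ev
        return float(self.binding_energy_ev)  # type: ignore[arg-type]


@dataclass(frozen=True)
class ELFModel:
    """Drude-channel model of Im[-1/eps(q,E)] for liquid water.

    ``mass_density_g_cm3`` rescales both the electron density (hence the
    plasma energy entering every channel strength) and all derived inverse
    mean free paths; the shape parameters are those of unit-density water.
    """

    channels: tuple[DrudeChannel, ...]
    mass_density_g_cm3: float = WATER_DENSITY_G_CM3
    electron_density_nm3: float = WATER_ELECTRON_DENSITY_NM3

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("model needs at least one channel")
        if self.mass_density_g_cm3 <= 0 or self.electron_density_nm3 <= 0:
            raise ValueError("densities must be positive")

    @property
    def plasma_energy_ev(self) -> float:
        return plasma_energy_ev(self.electron_density_nm3)

    @property
    def threshold_ev(self) -> float:
        """Lowest channel threshold; no energy loss is possible below it."""
        return min(ch.threshold_ev for ch in self.channels)

    def excitation_channels(self) -> tuple[DrudeChannel, ...]:
        return tuple(c for c in self.channels if c.kind == EXCITATION)

    def ionization_channels(self) -> tuple[DrudeChannel, ...]:
        return tuple(c for c in self.channels if c.kind == IONIZATION)

    def rescaled(self, mass_density_g_cm3: float) -> "ELFModel":
        """Same medium at a different mass density."""
        factor = mass_density_g_cm3 / self.mass_density_g_cm3
        return ELFModel(
            channels=self.channels,
            mass_density_g_cm3=mass_density_g_cm3,
            electron_density_nm3=self.electron_density_nm3 * factor,
        )

    def with_channels(self, channels: Iterable[DrudeChannel]) -> "ELFModel":
        return ELFModel(
            channels=tuple(channels),
            mass_density_g_cm3=self.mass_density_g_cm3,
            electron_density_nm3=self.electron_density_nm3,
        )


def _parse_fixture(text: str) -> list[DrudeChannel]:
    channels: list[DrudeChannel] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        kind, label, ek, fk, gk, bk, disp = line.split()
        channels.append(
            DrudeChannel(
                kind=kind,
                label=label,
                transition_energy_ev=float(ek),
                oscillator_strength=float(fk),
                damping_width_ev=float(gk),
                binding_energy_ev=None if bk == "-" else float(bk),
                dispersion_coefficient=float(disp),
            )
        )
    return channels


def load_default_model() -> ELFModel:
    """Load the packaged liquid-water channel fixture."""
    text = (
        resources.files("nanodos.data").joinpath("drude_channels.tsv").read_text()
    )
    return ELFModel(channels=tuple(_parse_fixture(text)))


# ---------------------------------------------------------------------------
# ELF evaluation
# ---------------------------------------------------------------------------

def _drude_term(
    energy_ev: np.ndarray,
    q_au: np.ndarray,
    channel: DrudeChannel,
    ep2: float,
) -> np.ndarray:
    """Drude loss-function term of one channel at (q, E), dimensionless."""
    ek = channel.transition_energy_ev + channel.dispersion_coefficient * RYDBERG_EV * (
        q_au * q_au
    )
    gam = channel.damping_width_ev
    e = energy_ev
    denom = (ek * ek - e * e) ** 2 + (gam * e) ** 2
    return channel.oscillator_strength * ep2 * gam * e / denom


def bethe_surface(model: ELFModel, q_au, energy_ev) -> np.ndarray | float:
    """Im[-1/eps(q,E)] on the energy/momentum-transfer plane (the Bethe ridge).

    Reduces exactly to the optical ELF at ``q = 0``; the crest tends to the
    free-electron locus ``E = q^2 Ry`` at large ``q``.
    """
    q = np.asarray(q_au, dtype=float)
    e = np.asarray(energy_ev, dtype=float)
    if np.any(q < 0) or np.any(e < 0):
        raise ValueError("momentum and energy transfer must be non-negative")
    ep2 = model.plasma_energy_ev**2
    out = np.zeros(np.broadcast(q, e).shape)
    for ch in model.channels:
        out += _drude_term(e, q, ch, ep2)
    if out.ndim == 0:
        return float(out)
    return out


def optical_elf(model: ELFModel, energy_ev) -> np.ndarray | float:
    """Optical-limit (q -> 0) energy-loss function Im[-1/eps(0,E)]."""
    return bethe_surface(model, 0.0, energy_ev)


def _channel_elf(
    channel: DrudeChannel,
    q_au: np.ndarray,
    energy_ev: np.ndarray,
    ep2: float,
    truncated: bool = True,
) -> np.ndarray:
    term = _drude_term(np.asarray(energy_ev, float), np.asarray(q_au, float), channel, ep2)
    if truncated:
        term = np.where(np.asarray(energy_ev) >= channel.threshold_ev, term, 0.0)
    return term


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InelasticKinematics:
    """Energy and momentum transfer for an inelastic collision.

    Nonrelativistic free-electron kinematics: with ``T`` the projectile
    energy and ``E`` the energy transfer, the allowed momentum transfer
    (atomic units) lies between

        q_± = sqrt(T/Ry) ± sqrt((T - E)/Ry).
    """

    projectile_energy_ev: float
    energy_transfer_ev: float
    momentum_transfer_au: float

    def __post_init__(self) -> None:
        t, e, q = (
            self.projectile_energy_ev,
            self.energy_transfer_ev,
            self.momentum_transfer_au,
        )
        if t <= 0:
            raise ValueError("projectile energy must be positive")
        if not 0 < e <= t:
            raise ValueError("energy transfer must satisfy 0 < E <= T")
        if q < 0:
            raise ValueError("momentum transfer must be non-negative")

    @property
    def q_minus_au(self) -> float:
        return kinematic_q_bounds(self.projectile_energy_ev, self.energy_transfer_ev)[0]

    @property
    def q_plus_au(self) -> float:
        return kinematic_q_bounds(self.projectile_energy_ev, self.energy_transfer_ev)[1]

    @property
    def allowed(self) -> bool:
        lo, hi = kinematic_q_bounds(self.projectile_energy_ev, self.energy_transfer_ev)
        return lo <= self.momentum_transfer_au <= hi


def kinematic_q_bounds(t_ev, e_ev):
    """(q_-, q_+) in atomic units for projectile energy T and transfer E."""
    t = np.asarray(t_ev, dtype=float)
    e = np.asarray(e_ev, dtype=float)
    root_t = np.sqrt(t / RYDBERG_EV)
    root_rem = np.sqrt(np.clip(t - e, 0.0, None) / RYDBERG_EV)
    return root_t - root_rem, root_t + root_rem


def differential_inverse_mfp(model: ELFModel, kin: InelasticKinematics) -> float:
    """d2(Lambda)/dq dE in nm^-1 eV^-1 a.u.^-1 at the given kinematic point.

    Zero outside the kinematically allowed momentum band.  The on-axis point
    ``q = 0`` is an integrable singularity of the 1/q weighting and is
    rejected.
    """
    if kin.momentum_transfer_au == 0.0:
        raise ValueError("q = 0 is singular; evaluate at q > 0")
    if not kin.allowed:
        return 0.0
    elf = bethe_surface(model, kin.momentum_transfer_au, kin.energy_transfer_ev)
    return float(
        elf
        / (
            math.pi
            * BOHR_RADIUS_NM
            * kin.momentum_transfer_au
            * kin.projectile_energy_ev
        )
    )


# ---------------------------------------------------------------------------
# Channel integrals
# ---------------------------------------------------------------------------

def _energy_grid(lo: float, hi: float, points_per_decade: int = 128) -> np.ndarray:
    if hi <= lo:
        return np.array([])
    n = max(24, int(points_per_decade * math.log10(hi / lo)) + 1)
    return np.geomspace(lo, hi, n)


def _q_integral_of_elf_over_q(
    channel: DrudeChannel, e_ev: np.ndarray, q_lo: np.ndarray, q_hi: np.ndarray,
    ep2: float, n_q: int = 96,
) -> np.ndarray:
    """inner(E) = ∫_{q_lo}^{q_hi} ELF_channel(q, E) / q dq, vectorised over E.

    The quadrature grid is log-spaced with extra linear nodes packed around
    the Bethe-ridge crossing q_r(E) (where the dispersed transition energy
    equals E): at large E the ridge is far narrower than any feasible global
    log grid, and without the refinement the tail of dLambda/dE is off by
    factors.
    """
    lo = np.maximum(q_lo, 1.0e-12)
    ratio = np.maximum(q_hi / lo, 1.0 + 1.0e-12)
    t = np.linspace(0.0, 1.0, n_q)[:, None]
    q = lo[None, :] * ratio[None, :] ** t  # (n_q, n_E)
    alpha = channel.dispersion_coefficient
    if alpha > 0:
        over = np.clip(e_ev - channel.transition_energy_ev, 0.0, None)
        q_r = np.sqrt(over / (alpha * RYDBERG_EV))
        dq = channel.damping_width_ev / (
            4.0 * alpha * RYDBERG_EV * np.maximum(q_r, 1.0e-6)
        )
        span = np.linspace(-8.0, 8.0, 64)[:, None]
        ridge = np.clip(q_r[None, :] + span * dq[None, :], lo[None, :], q_hi[None, :])
        q = np.sort(np.concatenate([q, ridge], axis=0), axis=0)
    integrand = _channel_elf(channel, q, e_ev[None, :], ep2) / q
    return np.trapezoid(integrand, x=q, axis=0)


def _channel_dlambda_de(
    model: ELFModel, channel: DrudeChannel, t_ev: float, e_ev: np.ndarray
) -> np.ndarray:
    """d(Lambda_k)/dE (nm^-1 eV^-1) at projectile energy T on a grid of E."""
    ep2 = model.plasma_energy_ev**2
    q_lo, q_hi = kinematic_q_bounds(t_ev, e_ev)
    inner = _q_integral_of_elf_over_q(channel, e_ev, q_lo, q_hi, ep2)
    return inner / (math.pi * BOHR_RADIUS_NM * t_ev)


def channel_inverse_mfp(model: ELFModel, t_ev: float, channel: DrudeChannel) -> float:
    """Inverse mean free path Lambda_k(T) of one channel, nm^-1.

    Integral of the doubly differential inverse mean free path over the
    kinematically allowed (E, q) region with the channel truncated at its
    threshold.  Exactly zero for T at or below threshold.
    """
    if t_ev <= 0:
        raise ValueError("projectile energy must be positive")
    if channel not in model.channels:
        raise ValueError("channel does not belong to this model")
    thr = channel.threshold_ev
    if t_ev <= thr:
        return 0.0
    e = _energy_grid(thr, t_ev)
    dlde = _channel_dlambda_de(model, channel, t_ev, e)
    return float(np.trapezoid(dlde, x=e))


def collision_stopping_power(model: ELFModel, t_ev: float) -> float:
    """Electronic stopping power -dT/ds (eV/nm): first moment ∫ E dLambda/dE."""
    thr = model.threshold_ev
    if t_ev <= thr:
        warnings.warn("projectile energy at or below threshold: stopping power is 0")
        return 0.0
    total = 0.0
    for ch in model.channels:
        if t_ev <= ch.threshold_ev:
            continue
        e = _energy_grid(ch.threshold_ev, t_ev)
        dlde = _channel_dlambda_de(model, ch, t_ev, e)
        total += float(np.trapezoid(e * dlde, x=e))
    return total


def mean_excitation_energy(model: ELFModel) -> float:
    """Mean excitation energy I from the model's own f-sum weighted log-moment,

        ln I = ∫ E * ELF(0,E) ln E dE / ∫ E * ELF(0,E) dE.
    """
    e = np.geomspace(1.0e-2, 5.0e4, 4096)
    elf = np.asarray(optical_elf(model, e))
    w = e * elf
    return float(math.exp(np.trapezoid(w * np.log(e), x=e) / np.trapezoid(w, x=e)))


def f_sum_integral(model: ELFModel, e_max_ev: float = 5.0e4) -> float:
    """∫ E * ELF(0,E) dE up to ``e_max_ev`` (eV^2)."""
    e = np.geomspace(1.0e-2, e_max_ev, 4096)
    elf = np.asarray(optical_elf(model, e))
    return float(np.trapezoid(e * elf, x=e))


def bethe_stopping_electron(electron_density_nm3: float, t_ev: float, i_ev: float) -> float:
    """Nonrelativistic Bethe collision stopping power of an electron, eV/nm.

    First-Born form without exchange (maximum energy transfer T):
    S = (2 pi e^4 n_e / T) ln(2 T / I).
    """
    if t_ev <= i_ev / 2.0:
        return 0.0
    return (
        2.0 * math.pi * E2_EV_NM**2 * electron_density_nm3 / t_ev
    ) * math.log(2.0 * t_ev / i_ev)


# ---------------------------------------------------------------------------
# Tabulated cross sections and samplers
# ---------------------------------------------------------------------------

class CrossSectionTable:
    """Per-channel inverse mean free paths and (E, q) samplers on a log grid.

    The table stores, per channel, Lambda_k(T) on a log-spaced energy grid and
    the cumulative structures needed to draw energy and momentum transfers by
    inverse-CDF interpolation.  The total inelastic inverse mean free path is
    by construction the exact sum of the channel values.
    """

    Q_GRID_LO = 5.0e-4
    Q_GRID_HI = 150.0

    def __init__(
        self,
        model: ELFModel,
        t_min_ev: float | None = None,
        t_max_ev: float = 3.0e4,
        points_per_decade: int = 32,
        n_quantiles: int = 64,
    ) -> None:
        self.model = model
        thr = model.threshold_ev
        t_min = thr * 1.001 if t_min_ev is None else t_min_ev
        n_t = max(16, int(points_per_decade * math.log10(t_max_ev / t_min)) + 1)
        self.t_grid = np.geomspace(t_min, t_max_ev, n_t)
        self.channels = model.channels
        ep2 = model.plasma_energy_ev**2
        self._ep2 = ep2

        # per-channel E grid and cumulative q-integral G[iE, jq]
        nq = max(64, int(64 * math.log10(self.Q_GRID_HI / self.Q_GRID_LO)) + 1)
        self.q_grid = np.geomspace(self.Q_GRID_LO, self.Q_GRID_HI, nq)
        self._log_q0 = math.log(self.q_grid[0])
        self._dlogq = math.log(self.q_grid[1] / self.q_grid[0])
        self.e_grids: list[np.ndarray] = []
        self.g_cum: list[np.ndarray] = []
        for ch in self.channels:
            e = _energy_grid(ch.threshold_ev, t_max_ev, points_per_decade=96)
            elf_over_q = _channel_elf(
                ch, self.q_grid[None, :], e[:, None], ep2
            ) / self.q_grid[None, :]
            g = np.concatenate(
                [
                    np.zeros((e.size, 1)),
                    np.cumsum(
                        0.5
                        * (elf_over_q[:, 1:] + elf_over_q[:, :-1])
                        * np.diff(self.q_grid)[None, :],
                        axis=1,
                    ),
                ],
                axis=1,
            )
            self.e_grids.append(e)
            self.g_cum.append(g)

        # Lambda_k on the T grid
        self.lambda_k = np.zeros((len(self.channels), n_t))
        for k, ch in enumerate(self.channels):
            for i, t in enumerate(self.t_grid):
                self.lambda_k[k, i] = self._lambda_channel(k, t)
        self.lambda_total = self.lambda_k.sum(axis=0)

        # energy-transfer quantile tables Q[k, iT, m] for fast sampling
        self.n_quantiles = n_quantiles
        self.quantile_levels = np.linspace(0.0, 1.0, n_quantiles + 1)
        self.e_quantiles = np.zeros((len(self.channels), n_t, n_quantiles + 1))
        for k in range(len(self.channels)):
            for i, t in enumerate(self.t_grid):
                if self.lambda_k[k, i] <= 0:
                    continue
                e, pdf = self._dlambda_de_grid(k, t)
                cdf = np.concatenate(
                    [[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(e))]
                )
                if cdf[-1] <= 0:
                    continue
                cdf /= cdf[-1]
                cdf, idx = np.unique(cdf, return_index=True)
                self.e_quantiles[k, i] = np.interp(
                    self.quantile_levels, cdf, e[idx]
                )

    # -- internal helpers ---------------------------------------------------

    def _g_interp_row(self, k: int, i_e: int, q: np.ndarray) -> np.ndarray:
        """Interpolate the cumulative q-integral of channel k at E-row i_e."""
        g = self.g_cum[k][i_e]
        logq = np.log(np.clip(q, self.q_grid[0], self.q_grid[-1]))
        x = (logq - self._log_q0) / self._dlogq
        j = np.clip(x.astype(int), 0, self.q_grid.size - 2)
        w = x - j
        return g[j] * (1.0 - w) + g[j + 1] * w

    def _g_interp(self, k: int, rows: np.ndarray, q: np.ndarray) -> np.ndarray:
        """Vectorised cumulative q-integral lookup at (E-row, q) pairs."""
        g = self.g_cum[k]
        logq = np.log(np.clip(q, self.q_grid[0], self.q_grid[-1]))
        x = (logq - self._log_q0) / self._dlogq
        j = np.clip(x.astype(int), 0, self.q_grid.size - 2)
        w = x - j
        return g[rows, j] * (1.0 - w) + g[rows, j + 1] * w

    def _g_interp_bilinear(self, k: int, e_ev: np.ndarray, q: np.ndarray) -> np.ndarray:
        """Cumulative q-integral interpolated in log E and log q."""
        e_full = self.e_grids[k]
        g = self.g_cum[k]
        loge = np.log(np.clip(e_ev, e_full[0], e_full[-1]))
        dlog = math.log(e_full[1] / e_full[0])
        xe = (loge - math.log(e_full[0])) / dlog
        ie = np.clip(xe.astype(int), 0, e_full.size - 2)
        we = np.clip(xe - ie, 0.0, 1.0)
        logq = np.log(np.clip(q, self.q_grid[0], self.q_grid[-1]))
        xq = (logq - self._log_q0) / self._dlogq
        jq = np.clip(xq.astype(int), 0, self.q_grid.size - 2)
        wq = xq - jq
        g00 = g[ie, jq]
        g01 = g[ie, jq + 1]
        g10 = g[ie + 1, jq]
        g11 = g[ie + 1, jq + 1]
        return (
            (g00 * (1 - wq) + g01 * wq) * (1 - we)
            + (g10 * (1 - wq) + g11 * wq) * we
        )

    def _dlambda_de_grid(self, k: int, t_ev: float):
        """(E grid restricted to <= T, dLambda/dE on it) for channel k."""
        ch = self.channels[k]
        e_full = self.e_grids[k]
        mask = e_full < t_ev
        e = np.concatenate([e_full[mask], [t_ev]])
        if e.size < 2:
            e = np.array([ch.threshold_ev, t_ev])
        pdf = _channel_dlambda_de(self.model, ch, t_ev, e)
        return e, np.clip(pdf, 0.0, None)

    def _lambda_channel(self, k: int, t_ev: float) -> float:
        if t_ev <= self.channels[k].threshold_ev:
            return 0.0
        e, pdf = self._dlambda_de_grid(k, t_ev)
        return float(np.trapezoid(pdf, x=e))

    # -- public API ---------------------------------------------------------

    def channel_imfp(self, t_ev: float) -> np.ndarray:
        """Lambda_k(T) for every channel by log-interpolation, nm^-1."""
        t = float(np.clip(t_ev, self.t_grid[0], self.t_grid[-1]))
        return np.array(
            [
                np.interp(t, self.t_grid, self.lambda_k[k])
                for k in range(len(self.channels))
            ]
        )

    def total_imfp(self, t_ev: float) -> float:
        if t_ev <= self.model.threshold_ev:
            return 0.0
        t = float(np.clip(t_ev, self.t_grid[0], self.t_grid[-1]))
        return float(np.interp(t, self.t_grid, self.lambda_total))

    def sample_energy_transfer(self, t_ev: float, k: int, rng, size: int):
        """Vectorised inverse-CDF draw of energy transfers for channel k.

        Builds the exact-T marginal d(Lambda_k)/dE on the channel grid and
        inverts its cumulative by linear interpolation.
        """
        if self._lambda_channel(k, t_ev) <= 0:
            raise ValueError("channel closed at this projectile energy")
        e, pdf = self._dlambda_de_grid(k, t_ev)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(e))])
        cdf /= cdf[-1]
        cdf, idx = np.unique(cdf, return_index=True)
        u = rng.random(size)
        return np.interp(u, cdf, e[idx])

    def sample_momentum_transfer(self, t_ev: float, k: int, e_ev: np.ndarray, rng):
        """Conditional draw of q given (T, E) from ELF(q,E)/q on [q_-, q_+]."""
        e_ev = np.asarray(e_ev, dtype=float)
        e_full = self.e_grids[k]
        q_lo, q_hi = kinematic_q_bounds(t_ev, e_ev)
        rows = np.clip(np.searchsorted(e_full, e_ev), 0, e_full.size - 1)
        u = rng.random(e_ev.size)
        g_lo = self._g_interp(k, rows, q_lo)
        g_hi = self._g_interp(k, rows, q_hi)
        targets = g_lo + u * (g_hi - g_lo)
        out = np.empty_like(e_ev)
        gcum = self.g_cum[k]
        for n in range(e_ev.size):
            g = gcum[rows[n]]
            j = int(np.clip(np.searchsorted(g, targets[n]) - 1, 0, g.size - 2))
            den = g[j + 1] - g[j]
            w = 0.0 if den <= 0 else (targets[n] - g[j]) / den
            q = self.q_grid[j] * (self.q_grid[j + 1] / self.q_grid[j]) ** w
            out[n] = min(max(q, q_lo[n]), q_hi[n])
        return out


def sample_energy_momentum(
    table: CrossSectionTable,
    t_ev: float,
    channel: DrudeChannel,
    rng: np.random.Generator,
    size: int = 1,
):
    """Draw (E, q) pairs for one open channel at projectile energy T.

    Energy transfers are drawn from the exact-T marginal d(Lambda_k)/dE by
    inverse-CDF interpolation; momentum transfers from the conditional
    ELF(q,E)/q density restricted to the kinematically allowed band.
    Identical generators yield identical sequences.
    """
    k = table.channels.index(channel)
    e = table.sample_energy_transfer(t_ev, k, rng, size)
    q = table.sample_momentum_transfer(t_ev, k, e, rng)
    return e, q
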