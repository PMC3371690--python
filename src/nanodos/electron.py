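"""Event-by-event electron transport in liquid water (and scaled media).

Every interaction of every electron is simulated as a discrete event:
exponential free flight against the total inverse mean free path, channel
selection proportional to the channel inverse mean free paths (elastic
included), energy/momentum-transfer sampling from the dielectric model,
angular deflection, secondary generation, and termination at a low-energy
cutoff (default 8.23 eV, the excitation threshold) where the remaining
energy is deposited on the spot.

Secondaries are transported from an explicit LIFO stack, so recursion depth
is unbounded and the event ordering is deterministic for a fixed random
stream.  Electrons above ``condensed_above_ev`` (default 10 keV, the
validity ceiling of the nonrelativistic event-by-event model) are first
slowed to that energy along a straight line with a condensed-history step
using the relativistic Bethe stopping power, then handed to the discrete
loop — the same hybrid "standard EM down to 10 keV, track structure below"
split used for the beam studies.

Two scoring hooks keep memory bounded on large runs: a ``scorer`` receives
per-event callbacks, and ``record_events`` controls whether a full event
list is kept on the returned :class:`Track`.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .constants import (
    ELECTRON_REST_EV,
    E2_EV_NM,
    R_E_NM,
    RYDBERG_EV,
    WATER_ELECTRON_DENSITY_NM3,
    beta_squared,
)
from .dielectric import (
    CrossSectionTable,
    DrudeChannel,
    EXCITATION,
    IONIZATION,
    mean_excitation_energy,
)
from .elastic import ElasticModel, sample_cos_theta

__all__ = [
    "ParticleState",
    "InteractionEvent",
    "Track",
    "TransportConfig",
    "ElectronTables",
    "transport_electron",
    "apply_inelastic",
    "sample_flight_and_channel",
    "local_cascade",
    "electron_stopping_high_ev_nm",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ParticleState:
    """Kinematic state of a particle being transported."""

    species: str
    position_nm: tuple[float, float, float]
    direction: tuple[float, float, float]
    kinetic_energy_ev: float
    generation: int = 0
    particle_id: int = 0
    parent_id: int = -1

    def __post_init__(self) -> None:
        ux, uy, uz = self.direction
        norm = math.sqrt(ux * ux + uy * uy + uz * uz)
        if abs(norm - 1.0) > 1.0e-9:
            if norm == 0:
                raise ValueError("direction must be a non-zero vector")
            self.direction = (ux / norm, uy / norm, uz / norm)
        if self.kinetic_energy_ev < 0:
            raise ValueError("kinetic energy must be non-negative")


@dataclass(frozen=True)
class InteractionEvent:
    """One discrete interaction vertex."""

    particle_id: int
    parent_id: int
    position_nm: tuple[float, float, float]
    event_type: str  # ionization|excitation|elastic|local-deposit|...
    channel: str
    energy_transfer_ev: float
    local_deposit_ev: float
    secondary_id: int | None = None


@dataclass
class Track:
    """Full history of one primary and all of its secondaries."""

    primary_energy_ev: float
    events: list[InteractionEvent] = field(default_factory=list)
    energy_deposited_ev: float = 0.0
    energy_escaped_ev: float = 0.0
    n_ionizations: int = 0
    n_events: int = 0
    n_secondaries: int = 0
    radius_of_gyration_nm: float = 0.0
    max_displacement_nm: float = 0.0

    @property
    def closure_residual(self) -> float:
        """Relative energy-balance residual; ~1e-16..1e-12 for a valid track."""
        total = self.energy_deposited_ev + self.energy_escaped_ev
        ref = max(self.primary_energy_ev, 1.0)
        return abs(total - self.primary_energy_ev) / ref


@dataclass
class TransportConfig:
    """Knobs of the electron transport loop.

    ``box_nm`` is an axis-aligned world box (xlo, xhi, ylo, yhi, zlo, zhi);
    particles leaving it carry their remaining energy away.  ``cutoff_ev``
    is the tracking cutoff: below it the remaining energy is deposited at
    the current position (default 8.23 eV, configurable down to a few eV).
    ``local_cascade_below_ev`` collapses secondaries below that energy to a
    point cascade (no spatial stepping) — useful when the scoring raster is
    far coarser than their range.  ``material_lookup`` maps a position to
    (inelastic scale, elastic scale) relative to unit-density water.
    """

    cutoff_ev: float = 8.23
    box_nm: tuple[float, float, float, float, float, float] | None = None
    max_secondaries: int = 10_000_000
    include_elastic: bool = True
    condensed_above_ev: float = 10_000.0
    local_cascade_below_ev: float = 0.0
    record_events: bool = True
    material_lookup: Callable[[float, float, float], tuple[float, float]] | None = None
    #: Electrons below the lowest ionization binding energy can produce no
    #: further ionizations; their remaining excitation budget is deposited
    #: at the current position instead of simulating the (model-artifact)
    #: tens-of-micrometre diffusion the truncated near-threshold excitation
    #: cross sections would imply.  Set to 0 to walk them explicitly.
    subionization_floor_ev: float | None = None  # None -> lowest ionization B_k
    #: When the elastic IMFP exceeds this multiple of the inelastic IMFP the
    #: walk between inelastic events is strongly diffusive; the individual
    #: elastic collisions are then grouped into one isotropised displacement
    #: of random-walk length sqrt(s * mfp_el).  Energy-loss statistics are
    #: untouched; only sub-nm elastic detail is condensed.
    elastic_grouping_ratio: float = 20.0

    def __post_init__(self) -> None:
        if self.cutoff_ev < 0:
            raise ValueError("cutoff must be non-negative")


class SecondaryStackOverflow(RuntimeError):
    """Raised when a track spawns more secondaries than the configured cap."""


# ---------------------------------------------------------------------------
# Fast sampling tables
# ---------------------------------------------------------------------------

class ElectronTables:
    """Flattened per-event sampling tables for the transport inner loop.

    Derived once from a :class:`CrossSectionTable` and an
    :class:`ElasticModel`; all lookups are O(1) or a short bisect on plain
    Python lists, which keeps the per-event cost at the microsecond scale.
    """

    def __init__(self, xs: CrossSectionTable, elastic: ElasticModel | None = None,
                 e_row_stride: int = 4) -> None:
        self.xs = xs
        self.elastic = elastic or ElasticModel()
        self.model = xs.model
        self.mean_excitation_ev = mean_excitation_energy(xs.model)

        t = xs.t_grid
        self.n_t = t.size
        self.log_t0 = math.log(t[0])
        self.dlog_t = math.log(t[1] / t[0])
        self.t_min = float(t[0])
        self.t_max = float(t[-1])

        chans = xs.channels
        self.channels = chans
        self.n_channels = len(chans)
        self.kind_ion = [c.kind == IONIZATION for c in chans]
        self.e_k = [c.transition_energy_ev for c in chans]
        self.b_k = [c.binding_energy_ev or 0.0 for c in chans]
        self.labels = [c.label for c in chans]
        self.threshold_ev = xs.model.threshold_ev

        self.lam_in = [float(v) for v in xs.lambda_total]
        self.lam_el = [self.elastic.imfp(float(tv)) for tv in t]

        self.lowest_ionization_ev = min(
            (c.binding_energy_ev for c in chans if c.kind == IONIZATION),
            default=float("inf"),
        )

        # cumulative inelastic channel fractions, flat [i * K + k]; channels
        # walked in order of decreasing average strength for an early exit
        K = self.n_channels
        order = sorted(range(K), key=lambda k: -float(xs.lambda_k[k].sum()))
        self.channel_order = order
        self.cumfrac = [0.0] * (self.n_t * K)
        lam_k = xs.lambda_k
        for i in range(self.n_t):
            tot = xs.lambda_total[i]
            acc = 0.0
            for j, k in enumerate(order):
                acc += lam_k[k, i]
                self.cumfrac[i * K + j] = acc / tot if tot > 0 else 1.0

        # energy-transfer quantiles, flat per channel [i * (M+1) + m]
        self.n_q = xs.n_quantiles
        M1 = self.n_q + 1
        self.e_quant = [
            [float(v) for v in xs.e_quantiles[k].reshape(-1)] for k in range(K)
        ]
        self._m1 = M1

        # decimated conditional-q tables per channel
        self.q_grid = xs.q_grid[::2]
        self.log_q0 = math.log(self.q_grid[0])
        self.dlog_q = math.log(self.q_grid[1] / self.q_grid[0])
        self.nq_cols = self.q_grid.size
        self.q_vals = [float(v) for v in self.q_grid]
        self.g_flat: list[list[float]] = []
        self.e_row_log0: list[float] = []
        self.e_row_dlog: list[float] = []
        self.e_row_count: list[int] = []
        for k in range(K):
            e_rows = xs.e_grids[k][::e_row_stride]
            g = xs.g_cum[k][::e_row_stride, ::2]
            self.g_flat.append([float(v) for v in g.reshape(-1)])
            self.e_row_log0.append(math.log(e_rows[0]))
            self.e_row_dlog.append(math.log(e_rows[1] / e_rows[0]))
            self.e_row_count.append(e_rows.size)

    # -- scalar lookups -----------------------------------------------------

    def _t_index(self, t_ev: float) -> tuple[int, float]:
        x = (math.log(t_ev) - self.log_t0) / self.dlog_t
        if x <= 0.0:
            return 0, 0.0
        if x >= self.n_t - 1:
            return self.n_t - 2, 1.0
        i = int(x)
        return i, x - i

    def inelastic_imfp(self, t_ev: float) -> float:
        if t_ev <= self.threshold_ev:
            return 0.0
        i, w = self._t_index(t_ev)
        return self.lam_in[i] * (1.0 - w) + self.lam_in[i + 1] * w

    def elastic_imfp(self, t_ev: float) -> float:
        i, w = self._t_index(t_ev)
        return self.lam_el[i] * (1.0 - w) + self.lam_el[i + 1] * w

    def pick_channel(self, t_ev: float, u: float) -> int:
        """Inelastic channel index with probability Lambda_k / Lambda_inel."""
        i, w = self._t_index(t_ev)
        K = self.n_channels
        base0 = i * K
        base1 = base0 + K
        cum = self.cumfrac
        order = self.channel_order
        for j in range(K):
            c = cum[base0 + j] * (1.0 - w) + cum[base1 + j] * w
            if u <= c:
                return order[j]
        return order[K - 1]

    def sample_energy_transfer(self, t_ev: float, k: int, u: float) -> float:
        """Quantile-table draw of the energy transfer for channel k."""
        i, w = self._t_index(t_ev)
        M1 = self._m1
        pos = u * self.n_q
        m = int(pos)
        if m >= self.n_q:
            m = self.n_q - 1
        w2 = pos - m
        row = self.e_quant[k]
        a0 = row[i * M1 + m]
        a1 = row[i * M1 + m + 1]
        b0 = row[(i + 1) * M1 + m]
        b1 = row[(i + 1) * M1 + m + 1]
        if a1 <= 0.0:  # channel closed at lower grid node; use upper row only
            e = b0 + (b1 - b0) * w2
        else:
            e = (a0 + (a1 - a0) * w2) * (1.0 - w) + (b0 + (b1 - b0) * w2) * w
        thr = self.b_k[k] if self.kind_ion[k] else self.e_k[k]
        hi = t_ev * (1.0 - 1.0e-9)
        if e < thr:
            e = thr
        if e > hi:
            e = hi
        return e

    def sample_q(self, t_ev: float, k: int, e_ev: float, u: float) -> float:
        """Conditional momentum-transfer draw from ELF(q,E)/q on [q_-, q_+]."""
        sq_t = math.sqrt(t_ev / RYDBERG_EV)
        sq_r = math.sqrt(max(t_ev - e_ev, 0.0) / RYDBERG_EV)
        q_lo = sq_t - sq_r
        q_hi = sq_t + sq_r
        row = (math.log(e_ev) - self.e_row_log0[k]) / self.e_row_dlog[k]
        irow = int(row + 0.5)
        if irow < 0:
            irow = 0
        elif irow >= self.e_row_count[k]:
            irow = self.e_row_count[k] - 1
        g = self.g_flat[k]
        off = irow * self.nq_cols

        def g_at(q: float) -> float:
            x = (math.log(min(max(q, self.q_vals[0]), self.q_vals[-1])) - self.log_q0) / self.dlog_q
            j = int(x)
            if j >= self.nq_cols - 1:
                j = self.nq_cols - 2
            wq = x - j
            return g[off + j] * (1.0 - wq) + g[off + j + 1] * wq

        glo = g_at(q_lo)
        ghi = g_at(q_hi)
        target = glo + u * (ghi - glo)
        j = bisect_right(g, target, off, off + self.nq_cols) - 1 - off
        if j < 0:
            j = 0
        elif j >= self.nq_cols - 1:
            j = self.nq_cols - 2
        den = g[off + j + 1] - g[off + j]
        wq = 0.0 if den <= 0.0 else (target - g[off + j]) / den
        q = self.q_vals[j] * (self.q_vals[j + 1] / self.q_vals[j]) ** wq
        if q < q_lo:
            q = q_lo
        elif q > q_hi:
            q = q_hi
        return q


# ---------------------------------------------------------------------------
# Kinematic helpers
# ---------------------------------------------------------------------------

def _deflect(ux: float, uy: float, uz: float, cos_t: float, phi: float):
    """Rotate a unit vector by polar angle arccos(cos_t) and azimuth phi."""
    sin_t = math.sqrt(max(1.0 - cos_t * cos_t, 0.0))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999999:
        sign = 1.0 if uz > 0 else -1.0
        return sin_t * cp, sign * sin_t * sp, sign * cos_t
    rho = math.sqrt(ux * ux + uy * uy)
    vx = sin_t * (cp * uz * ux - sp * uy) / rho + cos_t * ux
    vy = sin_t * (cp * uz * uy + sp * ux) / rho + cos_t * uy
    vz = -sin_t * cp * rho + cos_t * uz
    return vx, vy, vz


def binary_collision_cosines(t_ev: float, e_ev: float, q_au: float):
    """(primary, secondary) polar cosines from (E, q) momentum bookkeeping.

    The primary is deflected according to the momentum-transfer triangle and
    the secondary is ejected along the transferred momentum (binary-encounter
    picture); both cosines are clamped to [-1, 1].
    """
    p = math.sqrt(t_ev / RYDBERG_EV)
    p2 = p * p
    pr2 = max(t_ev - e_ev, 0.0) / RYDBERG_EV
    pr = math.sqrt(pr2)
    q2 = q_au * q_au
    if pr > 0.0 and p > 0.0:
        cos_p = (p2 + pr2 - q2) / (2.0 * p * pr)
    else:
        cos_p = 1.0
    cos_s = (p2 - pr2 + q2) / (2.0 * p * q_au) if q_au > 0.0 else 1.0
    return max(-1.0, min(1.0, cos_p)), max(-1.0, min(1.0, cos_s))


def electron_stopping_high_ev_nm(
    t_ev: float, i_ev: float, electron_density_nm3: float = WATER_ELECTRON_DENSITY_NM3
) -> float:
    """Relativistic Bethe collision stopping power for electrons (eV/nm).

    Used only for the condensed-history step above the event-by-event
    ceiling; includes the Moller closure term F(tau).
    """
    tau = t_ev / ELECTRON_REST_EV
    b2 = beta_squared(t_ev, ELECTRON_REST_EV)
    pref = 2.0 * math.pi * R_E_NM**2 * ELECTRON_REST_EV * electron_density_nm3 / b2
    ratio = i_ev / ELECTRON_REST_EV
    f_tau = 1.0 - b2 + (tau * tau / 8.0 - (2.0 * tau + 1.0) * math.log(2.0)) / (
        (tau + 1.0) ** 2
    )
    return pref * (math.log(tau * tau * (tau + 2.0) / (2.0 * ratio * ratio)) + f_tau)


# ---------------------------------------------------------------------------
# Single-collision operations
# ---------------------------------------------------------------------------

def sample_flight_and_channel(
    state: ParticleState, tables: ElectronTables, rng,
    include_elastic: bool = True,
) -> tuple[float, str]:
    """(free-flight path in nm, channel label) for the next interaction.

    Path ~ Exp(Lambda_tot); channel chosen with probability
    Lambda_k / Lambda_tot, elastic included in the total.
    """
    t = state.kinetic_energy_ev
    lam_in = tables.inelastic_imfp(t)
    lam_el = tables.elastic_imfp(t) if include_elastic else 0.0
    lam = lam_in + lam_el
    if lam <= 0.0:
        raise ValueError("all channels closed at this energy")
    path = -math.log(1.0 - rng.random()) / lam
    if rng.random() * lam < lam_el:
        return path, "elastic"
    k = tables.pick_channel(t, rng.random())
    return path, tables.labels[k]


def apply_inelastic(
    state: ParticleState,
    channel: DrudeChannel,
    sample: tuple[float, float],
    rng,
) -> tuple[ParticleState, InteractionEvent, ParticleState | None]:
    """Apply one sampled inelastic collision to a particle state.

    Excitation: the primary loses the channel transition energy, deposited
    locally, with no deflection.  Ionization: the primary loses the sampled
    transfer E and is deflected by the momentum-transfer angle; a secondary
    electron with kinetic energy E - B_k is ejected along the transferred
    momentum with uniform azimuth; the binding energy B_k is deposited
    locally.
    """
    e_ev, q_au = sample
    t = state.kinetic_energy_ev
    x, y, z = state.position_nm
    if channel.kind == EXCITATION:
        loss = channel.transition_energy_ev
        if loss > t:
            loss = t
        new = ParticleState(
            species=state.species,
            position_nm=state.position_nm,
            direction=state.direction,
            kinetic_energy_ev=t - loss,
            generation=state.generation,
            particle_id=state.particle_id,
            parent_id=state.parent_id,
        )
        ev = InteractionEvent(
            state.particle_id, state.parent_id, (x, y, z),
            "excitation", channel.label, loss, loss,
        )
        return new, ev, None

    w_sec = e_ev - float(channel.binding_energy_ev)
    if w_sec < -1.0e-9 or e_ev > t * (1.0 + 1.0e-12):
        raise ValueError("inconsistent ionization kinematics: E < B or E > T")
    w_sec = max(w_sec, 0.0)
    cos_p, cos_s = binary_collision_cosines(t, e_ev, q_au)
    phi = 2.0 * math.pi * rng.random()
    ux, uy, uz = state.direction
    d_primary = _deflect(ux, uy, uz, cos_p, phi)
    d_secondary = _deflect(ux, uy, uz, cos_s, phi + math.pi)
    sec_id = state.particle_id + 1  # caller reassigns unique ids during transport
    new = ParticleState(
        species=state.species,
        position_nm=state.position_nm,
        direction=d_primary,
        kinetic_energy_ev=t - e_ev,
        generation=state.generation,
        particle_id=state.particle_id,
        parent_id=state.parent_id,
    )
    secondary = ParticleState(
        species="electron",
        position_nm=state.position_nm,
        direction=d_secondary,
        kinetic_energy_ev=w_sec,
        generation=state.generation + 1,
        particle_id=sec_id,
        parent_id=state.particle_id,
    )
    ev = InteractionEvent(
        state.particle_id, state.parent_id, (x, y, z),
        "ionization", channel.label, e_ev,
        float(channel.binding_energy_ev), secondary_id=sec_id,
    )
    return new, ev, secondary


# ---------------------------------------------------------------------------
# Full transport
# ---------------------------------------------------------------------------

def local_cascade(
    t_ev: float, tables: ElectronTables, rng, cutoff_ev: float,
) -> tuple[int, float]:
    """Energy-space collision cascade with positions frozen.

    Follows the same channel statistics as the spatial loop but deposits
    everything at one point; returns (ionization count, deposited energy).
    Used for secondaries whose range is far below the scoring resolution.
    """
    n_ion = 0
    deposited = 0.0
    lowest_ion = tables.lowest_ionization_ev
    floor = cutoff_ev if cutoff_ev > tables.threshold_ev else tables.threshold_ev
    stack = [t_ev]
    while stack:
        t = stack.pop()
        while True:
            if t < floor:
                deposited += t
                break
            if t < lowest_ion:
                # only excitation channels are open: no further ionizations,
                # everything ends up deposited at this point anyway
                deposited += t
                break
            k = tables.pick_channel(t, rng.random())
            if tables.kind_ion[k]:
                e_loss = tables.sample_energy_transfer(t, k, rng.random())
                w = e_loss - tables.b_k[k]
                if w < 0.0:
                    w = 0.0
                n_ion += 1
                deposited += e_loss - w
                if w >= cutoff_ev:
                    stack.append(w)
                else:
                    deposited += w
                t -= e_loss
            else:
                loss = min(tables.e_k[k], t)
                deposited += loss
                t -= loss
    return n_ion, deposited


def transport_electron(
    state: ParticleState,
    config: TransportConfig,
    tables: ElectronTables,
    rng,
    scorer=None,
) -> Track:
    """Transport an electron and all its secondaries; return the Track.

    ``rng`` needs ``random()`` (python ``random.Random`` is fine and fast).
    The returned track satisfies exact energy closure: initial energy equals
    deposited plus escaped energy to floating-point accuracy.
    """
    track = Track(primary_energy_ev=state.kinetic_energy_ev)
    events = track.events
    record = config.record_events
    box = config.box_nm
    cutoff = config.cutoff_ev
    matlook = config.material_lookup
    cascade_below = config.local_cascade_below_ev
    condensed_above = config.condensed_above_ev
    i_ev = tables.mean_excitation_ev
    floor = config.subionization_floor_ev
    if floor is None:
        floor = tables.lowest_ionization_ev
    if floor < cutoff:
        floor = cutoff

    x0, y0, z0 = state.position_nm
    sum_w = 0.0
    sum_x = sum_y = sum_z = 0.0
    sum_r2 = 0.0
    max_disp2 = 0.0

    next_id = state.particle_id + 1
    # stack entries: (T, x, y, z, ux, uy, uz, generation, pid, parent)
    stack = [
        (
            state.kinetic_energy_ev,
            x0, y0, z0,
            *state.direction,
            state.generation,
            state.particle_id,
            state.parent_id,
        )
    ]

    def inside(x: float, y: float, z: float) -> bool:
        if box is None:
            return True
        return (
            box[0] <= x <= box[1]
            and box[2] <= y <= box[3]
            and box[4] <= z <= box[5]
        )

    while stack:
        t, x, y, z, ux, uy, uz, gen, pid, parent = stack.pop()

        # point cascade for sub-resolution secondaries
        if gen > 0 and t < cascade_below:
            n_ion, dep = local_cascade(t, tables, rng, cutoff)
            track.energy_deposited_ev += dep
            track.n_ionizations += n_ion
            track.n_events += n_ion
            if scorer is not None:
                scorer.add_deposit(x, y, z, dep, pid)
                for _ in range(n_ion):
                    scorer.add_ionization(x, y, z, pid, gen)
            if record:
                events.append(
                    InteractionEvent(pid, parent, (x, y, z), "local-deposit",
                                     "cascade", 0.0, dep)
                )
            continue

        # condensed-history slowing above the event-by-event ceiling
        while t > condensed_above:
            s_in = 1.0
            if matlook is not None:
                s_in, _ = matlook(x, y, z)
            if s_in <= 0.0:
                step = 500.0
                de = 0.0
            else:
                sp = electron_stopping_high_ev_nm(t, i_ev) * s_in
                de = min(0.05 * t, t - condensed_above)
                step = de / sp
                if step > 2000.0:
                    step = 2000.0
                    de = step * sp
            x += step * ux
            y += step * uy
            z += step * uz
            if not inside(x, y, z):
                track.energy_escaped_ev += t
                t = -1.0
                break
            if de > 0.0:
                t -= de
                track.energy_deposited_ev += de
                if scorer is not None:
                    scorer.add_deposit(x, y, z, de, pid)
                if record:
                    events.append(
                        InteractionEvent(pid, parent, (x, y, z), "local-deposit",
                                         "csda-step", 0.0, de)
                    )
        if t < 0.0:
            continue

        # discrete event loop
        while True:
            if t < floor or tables.inelastic_imfp(t) <= 0.0:
                track.energy_deposited_ev += t
                track.n_events += 1
                if scorer is not None and t > 0.0:
                    scorer.add_deposit(x, y, z, t, pid)
                if record:
                    events.append(
                        InteractionEvent(pid, parent, (x, y, z), "local-deposit",
                                         "cutoff", 0.0, t)
                    )
                w = max(t, 1.0e-12)
                dx, dy, dz = x - x0, y - y0, z - z0
                r2 = dx * dx + dy * dy + dz * dz
                sum_w += w
                sum_x += w * x
                sum_y += w * y
                sum_z += w * z
                sum_r2 += w * r2
                if r2 > max_disp2:
                    max_disp2 = r2
                break

            s_in = s_el = 1.0
            if matlook is not None:
                s_in, s_el = matlook(x, y, z)
            lam_in = tables.inelastic_imfp(t) * s_in
            lam_el = (tables.elastic_imfp(t) * s_el) if config.include_elastic else 0.0
            lam = lam_in + lam_el
            if lam <= 0.0:
                # vacuum: fly to the world boundary
                if box is None:
                    track.energy_escaped_ev += t
                    break
                step = 1.0e5
                x += step * ux
                y += step * uy
                z += step * uz
                if not inside(x, y, z):
                    track.energy_escaped_ev += t
                    break
                continue

            if lam_el > config.elastic_grouping_ratio * lam_in:
                # grouped-elastic diffusive step straight to the next
                # inelastic event: direction isotropised, displacement is the
                # random-walk rms over the exponential inelastic path
                path = -math.log(1.0 - rng.random()) / lam_in
                disp = math.sqrt(path / lam_el)
                if disp > path:
                    disp = path
                cos_t = 1.0 - 2.0 * rng.random()
                sin_t = math.sqrt(max(1.0 - cos_t * cos_t, 0.0))
                phi = 2.0 * math.pi * rng.random()
                ux = sin_t * math.cos(phi)
                uy = sin_t * math.sin(phi)
                uz = cos_t
                x += disp * ux
                y += disp * uy
                z += disp * uz
                if not inside(x, y, z):
                    track.energy_escaped_ev += t
                    break
                lam_el = 0.0
                lam = lam_in
            else:
                path = -math.log(1.0 - rng.random()) / lam
                x += path * ux
                y += path * uy
                z += path * uz
                if not inside(x, y, z):
                    track.energy_escaped_ev += t
                    break

            if lam_el > 0.0 and rng.random() * lam < lam_el:
                cos_t = sample_cos_theta(t, rng.random())
                phi = 2.0 * math.pi * rng.random()
                ux, uy, uz = _deflect(ux, uy, uz, cos_t, phi)
                track.n_events += 1
                if record:
                    events.append(
                        InteractionEvent(pid, parent, (x, y, z), "elastic",
                                         "elastic", 0.0, 0.0)
                    )
                continue

            k = tables.pick_channel(t, rng.random())
            if not tables.kind_ion[k]:
                loss = tables.e_k[k]
                if loss > t:
                    loss = t
                t -= loss
                track.energy_deposited_ev += loss
                track.n_events += 1
                if scorer is not None:
                    scorer.add_deposit(x, y, z, loss, pid)
                if record:
                    events.append(
                        InteractionEvent(pid, parent, (x, y, z), "excitation",
                                         tables.labels[k], loss, loss)
                    )
                continue

            e_loss = tables.sample_energy_transfer(t, k, rng.random())
            q = tables.sample_q(t, k, e_loss, rng.random())
            b_k = tables.b_k[k]
            w_sec = e_loss - b_k
            if w_sec < 0.0:
                w_sec = 0.0
                b_k = e_loss
            cos_p, cos_s = binary_collision_cosines(t, e_loss, q)
            phi = 2.0 * math.pi * rng.random()
            sec_dir = _deflect(ux, uy, uz, cos_s, phi + math.pi)
            ux, uy, uz = _deflect(ux, uy, uz, cos_p, phi)
            t -= e_loss
            track.energy_deposited_ev += b_k
            track.n_ionizations += 1
            track.n_events += 1
            track.n_secondaries += 1
            if track.n_secondaries > config.max_secondaries:
                raise SecondaryStackOverflow(
                    f"more than {config.max_secondaries} secondaries in one track"
                )
            sid = next_id
            next_id += 1
            if scorer is not None:
                scorer.add_deposit(x, y, z, b_k, pid)
                scorer.add_ionization(x, y, z, pid, gen)
            if record:
                events.append(
                    InteractionEvent(pid, parent, (x, y, z), "ionization",
                                     tables.labels[k], e_loss, b_k, secondary_id=sid)
                )
            stack.append((w_sec, x, y, z, *sec_dir, gen + 1, sid, pid))

    if sum_w > 0.0:
        cx, cy, cz = sum_x / sum_w, sum_y / sum_w, sum_z / sum_w
        # radius of gyration about the deposit centroid
        track.radius_of_gyration_nm = math.sqrt(
            max(
                sum_r2 / sum_w
                - ((cx - x0) ** 2 + (cy - y0) ** 2 + (cz - z0) ** 2),
                0.0,
            )
        )
    track.max_displacement_nm = math.sqrt(max_disp2)
    return track
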