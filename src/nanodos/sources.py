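"""Primary particle sources: pencil and focused-disc beams."""

from __future__ import annotations

import math
from typing import Iterator

from .electron import ParticleState

__all__ = ["pencil_beam_source", "disc_beam_source", "SUPPORTED_SPECIES"]

SUPPORTED_SPECIES = ("electron", "proton", "alpha", "photon")


def pencil_beam_source(
    species: str,
    energy_ev: float,
    n: int,
    start_nm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> Iterator[ParticleState]:
    """Zero-width monoenergetic beam along +x starting at the phantom face."""
    if species not in SUPPORTED_SPECIES:
        raise ValueError(f"unsupported species {species!r}")
    if energy_ev <= 0:
        raise ValueError("beam energy must be positive")
    for i in range(n):
        yield ParticleState(
            species=species,
            position_nm=start_nm,
            direction=(1.0, 0.0, 0.0),
            kinetic_energy_ev=energy_ev,
            generation=0,
            particle_id=0,
            parent_id=-1,
        )


def disc_beam_source(
    species: str,
    energy_ev: float,
    n: int,
    rng,
    radius_nm: float,
    center_yz_nm: tuple[float, float] = (0.0, 0.0),
    x_start_nm: float = 0.0,
) -> Iterator[ParticleState]:
    """Uniform (top-hat) disc beam of parallel rays along +x.

    Models a focused microbeam: all rays are parallel, entry points are
    uniform over a disc of the given radius in the y-z plane.
    """
    if species not in SUPPORTED_SPECIES:
        raise ValueError(f"unsupported species {species!r}")
    if energy_ev <= 0 or radius_nm < 0:
        raise ValueError("energy must be positive and radius non-negative")
    cy, cz = center_yz_nm
    for i in range(n):
        r = radius_nm * math.sqrt(rng.random())
        phi = 2.0 * math.pi * rng.random()
        yield ParticleState(
            species=species,
            position_nm=(x_start_nm, cy + r * math.cos(phi), cz + r * math.sin(phi)),
            direction=(1.0, 0.0, 0.0),
            kinetic_energy_ev=energy_ev,
            generation=0,
            particle_id=0,
            parent_id=-1,
        )
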