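"""Synthetic voxelized cell phantom.

A stand-in for a real segmented-cell raster: an ellipsoidal cell containing
an ellipsoidal nucleus and a set of dense spherical organelles placed at
random (non-overlapping, inside the cytoplasm).  Materials follow measured
cell compositions: cytoplasm (O 58, C 20, H 9, N 8.5, P 4.5 % by mass) and
nuclear material (O 74.5, H 11, C 9, N 3, P 2.5 %) at 1 g/cm^3, with the
organelles carrying the nuclear composition at 10 g/cm^3.  Outside the cell
is empty space.

The phantom exposes both the voxel raster (used by transport and scoring)
and the continuous geometry (used for volume bookkeeping and invariant
checks), plus a plain-text writer/reader with bit-exact round-trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .materials import CYTOPLASM, NUCLEUS, ORGANELLE, VACUUM, Material

__all__ = [
    "CellGeometry",
    "CellPhantom",
    "build_cell_phantom",
    "write_phantom",
    "read_phantom",
]

# material id codes in the raster
ID_VACUUM = 0
ID_CYTOPLASM = 1
ID_NUCLEUS = 2
ID_ORGANELLE = 3


@dataclass(frozen=True)
class CellGeometry:
    """Geometry parameters; lengths in micrometres (semi-axes and radii)."""

    cell_semiaxes_um: tuple[float, float, float] = (12.5, 12.5, 5.5)
    nucleus_semiaxes_um: tuple[float, float, float] = (5.0, 5.0, 2.5)
    n_organelles: int = 20
    organelle_radius_um: float = 0.5
    voxel_size_um: float = 0.25
    margin_um: float = 1.0
    organelle_centers_um: tuple[tuple[float, float, float], ...] | None = None

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.cell_semiaxes_um):
            raise ValueError("cell semi-axes must be positive")
        if any(
            n >= c for n, c in zip(self.nucleus_semiaxes_um, self.cell_semiaxes_um)
        ):
            raise ValueError("nucleus must fit strictly inside the cell")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel size must be positive")
        if self.n_organelles < 0 or self.organelle_radius_um < 0:
            raise ValueError("organelle parameters must be non-negative")


@dataclass
class CellPhantom:
    geometry: CellGeometry
    materials: tuple[Material, ...]  # indexed by material id
    material_ids: np.ndarray  # (nx, ny, nz) uint8
    origin_um: tuple[float, float, float]
    organelle_centers_um: list[tuple[float, float, float]]

    @property
    def voxel_size_um(self) -> float:
        return self.geometry.voxel_size_um

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.material_ids.shape

    @property
    def bounds_nm(self) -> tuple[float, float, float, float, float, float]:
        (x0, y0, z0) = self.origin_um
        nx, ny, nz = self.shape
        v = self.voxel_size_um
        return (
            x0 * 1e3, (x0 + nx * v) * 1e3,
            y0 * 1e3, (y0 + ny * v) * 1e3,
            z0 * 1e3, (z0 + nz * v) * 1e3,
        )

    def voxel_index(self, x_nm: float, y_nm: float, z_nm: float):
        v = self.voxel_size_um * 1e3
        x0, y0, z0 = (c * 1e3 for c in self.origin_um)
        ix = int((x_nm - x0) / v)
        iy = int((y_nm - y0) / v)
        iz = int((z_nm - z0) / v)
        nx, ny, nz = self.shape
        if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
            return ix, iy, iz
        return None

    def region_id_at(self, x_nm: float, y_nm: float, z_nm: float) -> int:
        idx = self.voxel_index(x_nm, y_nm, z_nm)
        if idx is None:
            return ID_VACUUM
        return int(self.material_ids[idx])

    # -- continuous geometry (for bookkeeping oracles) ----------------------

    def continuous_region(self, x_um: float, y_um: float, z_um: float) -> int:
        g = self.geometry
        for c in self.organelle_centers_um:
            dx, dy, dz = x_um - c[0], y_um - c[1], z_um - c[2]
            if dx * dx + dy * dy + dz * dz <= g.organelle_radius_um**2:
                return ID_ORGANELLE
        an, bn, cn = g.nucleus_semiaxes_um
        if (x_um / an) ** 2 + (y_um / bn) ** 2 + (z_um / cn) ** 2 <= 1.0:
            return ID_NUCLEUS
        a, b, cc = g.cell_semiaxes_um
        if (x_um / a) ** 2 + (y_um / b) ** 2 + (z_um / cc) ** 2 <= 1.0:
            return ID_CYTOPLASM
        return ID_VACUUM

    def analytic_organelle_volume_um3(self) -> float:
        return len(self.organelle_centers_um) * (4.0 / 3.0) * math.pi * (
            self.geometry.organelle_radius_um**3
        )

    # -- masses -------------------------------------------------------------

    def region_mass_kg(self, ids: tuple[int, ...]) -> float:
        v_cm3 = (self.voxel_size_um * 1.0e-4) ** 3
        mass_g = 0.0
        for i in ids:
            n = int((self.material_ids == i).sum())
            mass_g += n * v_cm3 * self.materials[i].density_g_cm3
        return mass_g * 1.0e-3

    def cell_mass_kg(self) -> float:
        return self.region_mass_kg((ID_CYTOPLASM, ID_NUCLEUS, ID_ORGANELLE))

    # -- transport helpers --------------------------------------------------

    def scale_tables(self, bethe_log_arg_ev: float | None = None):
        """(inelastic, elastic) scale factors per material id."""
        inel = [m.inelastic_scale(bethe_log_arg_ev) for m in self.materials]
        el = [m.elastic_scale() for m in self.materials]
        return inel, el

    def material_lookup(self, bethe_log_arg_ev: float | None = None):
        """Fast (x, y, z in nm) -> (inelastic scale, elastic scale) closure."""
        inel, el = self.scale_tables(bethe_log_arg_ev)
        nx, ny, nz = self.shape
        flat = self.material_ids.reshape(-1).tolist()
        v = self.voxel_size_um * 1e3
        x0, y0, z0 = (c * 1e3 for c in self.origin_um)
        pairs = [(inel[i], el[i]) for i in range(len(self.materials))]

        def lookup(x: float, y: float, z: float):
            ix = int((x - x0) / v)
            iy = int((y - y0) / v)
            iz = int((z - z0) / v)
            if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                return pairs[flat[(ix * ny + iy) * nz + iz]]
            return pairs[ID_VACUUM]

        return lookup


def _inside_ellipsoid(p, semi, shrink=0.0) -> bool:
    return sum(
        (c / max(s - shrink, 1e-9)) ** 2 for c, s in zip(p, semi)
    ) <= 1.0


def build_cell_phantom(
    geometry: CellGeometry, rng, max_attempts: int = 20_000
) -> CellPhantom:
    """Construct the voxel raster; deterministic given the rng state.

    Organelles are placed by rejection sampling: fully inside the cell,
    clear of the nucleus, mutually non-overlapping.  Raises after
    ``max_attempts`` failed draws (infeasible packing).
    """
    g = geometry
    r = g.organelle_radius_um
    centers: list[tuple[float, float, float]] = []
    if g.organelle_centers_um is not None:
        centers = list(g.organelle_centers_um)
        if len(centers) != g.n_organelles:
            raise ValueError("explicit centers must match n_organelles")
    else:
        a, b, c = g.cell_semiaxes_um
        attempts = 0
        while len(centers) < g.n_organelles:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError("organelle packing infeasible")
            p = (
                (2.0 * rng.random() - 1.0) * a,
                (2.0 * rng.random() - 1.0) * b,
                (2.0 * rng.random() - 1.0) * c,
            )
            if not _inside_ellipsoid(p, g.cell_semiaxes_um, shrink=r):
                continue
            # clear of the nucleus (conservative: grow nucleus by r)
            an, bn, cn = g.nucleus_semiaxes_um
            if sum(
                (pc / (s + r)) ** 2 for pc, s in zip(p, (an, bn, cn))
            ) <= 1.0:
                continue
            if any(
                (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 + (p[2] - q[2]) ** 2
                < (2 * r) ** 2
                for q in centers
            ):
                continue
            centers.append(p)

    # voxel raster
    half = [s + g.margin_um for s in g.cell_semiaxes_um]
    v = g.voxel_size_um
    n = [int(math.ceil(2 * h / v)) for h in half]
    origin = tuple(-(ni * v) / 2.0 for ni in n)
    xs = origin[0] + (np.arange(n[0]) + 0.5) * v
    ys = origin[1] + (np.arange(n[1]) + 0.5) * v
    zs = origin[2] + (np.arange(n[2]) + 0.5) * v
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")

    a, b, c = g.cell_semiaxes_um
    an, bn, cn = g.nucleus_semiaxes_um
    ids = np.full(n, ID_VACUUM, dtype=np.uint8)
    in_cell = (gx / a) ** 2 + (gy / b) ** 2 + (gz / c) ** 2 <= 1.0
    ids[in_cell] = ID_CYTOPLASM
    in_nuc = (gx / an) ** 2 + (gy / bn) ** 2 + (gz / cn) ** 2 <= 1.0
    ids[in_nuc] = ID_NUCLEUS
    for p in centers:
        d2 = (gx - p[0]) ** 2 + (gy - p[1]) ** 2 + (gz - p[2]) ** 2
        ids[(d2 <= r * r) & in_cell & ~in_nuc] = ID_ORGANELLE

    return CellPhantom(
        geometry=g,
        materials=(VACUUM, CYTOPLASM, NUCLEUS, ORGANELLE),
        material_ids=ids,
        origin_um=origin,
        organelle_centers_um=centers,
    )


# ---------------------------------------------------------------------------
# Plain-text phantom file
# ---------------------------------------------------------------------------

def write_phantom(phantom: CellPhantom, path) -> None:
    g = phantom.geometry
    nx, ny, nz = phantom.shape
    with open(path, "w") as fh:
        fh.write("# nanodos cell phantom v1\n")
        fh.write(f"voxel_size_um {g.voxel_size_um!r}\n")
        fh.write(f"shape {nx} {ny} {nz}\n")
        fh.write(
            "origin_um " + " ".join(repr(c) for c in phantom.origin_um) + "\n"
        )
        fh.write(
            "cell_semiaxes_um "
            + " ".join(repr(c) for c in g.cell_semiaxes_um) + "\n"
        )
        fh.write(
            "nucleus_semiaxes_um "
            + " ".join(repr(c) for c in g.nucleus_semiaxes_um) + "\n"
        )
        fh.write(f"organelle_radius_um {g.organelle_radius_um!r}\n")
        fh.write(f"n_organelles {len(phantom.organelle_centers_um)}\n")
        for p in phantom.organelle_centers_um:
            fh.write("organelle " + " ".join(repr(c) for c in p) + "\n")
        for i, m in enumerate(phantom.materials):
            frac = ",".join(f"{k}:{v!r}" for k, v in sorted(m.mass_fractions.items()))
            fh.write(f"material {i} {m.name} {m.density_g_cm3!r} {frac or '-'}\n")
        fh.write("ids\n")
        flat = phantom.material_ids.reshape(-1)
        for i in range(0, flat.size, 80):
            fh.write("".join(str(int(x)) for x in flat[i : i + 80]) + "\n")


def read_phantom(path) -> CellPhantom:
    from .materials import material_from_composition

    meta: dict[str, list[str]] = {}
    organelles: list[tuple[float, float, float]] = []
    materials: dict[int, Material] = {}
    digits: list[str] = []
    with open(path) as fh:
        in_ids = False
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if in_ids:
                digits.append(line)
                continue
            if line == "ids":
                in_ids = True
                continue
            key, *rest = line.split()
            if key == "organelle":
                organelles.append(tuple(float(v) for v in rest))
            elif key == "material":
                idx = int(rest[0])
                name, dens, frac = rest[1], float(rest[2]), rest[3]
                if frac == "-":
                    materials[idx] = Material(name=name, mass_fractions={},
                                              density_g_cm3=dens)
                else:
                    fr = {
                        kv.split(":")[0]: float(kv.split(":")[1])
                        for kv in frac.split(",")
                    }
                    m = material_from_composition(fr, dens, name)
                    materials[idx] = m
            else:
                meta[key] = rest
    shape = tuple(int(v) for v in meta["shape"])
    flat = np.frombuffer("".join(digits).encode(), dtype=np.uint8) - ord("0")
    ids = flat.reshape(shape).astype(np.uint8)
    geometry = CellGeometry(
        cell_semiaxes_um=tuple(float(v) for v in meta["cell_semiaxes_um"]),
        nucleus_semiaxes_um=tuple(float(v) for v in meta["nucleus_semiaxes_um"]),
        n_organelles=int(meta["n_organelles"][0]),
        organelle_radius_um=float(meta["organelle_radius_um"][0]),
        voxel_size_um=float(meta["voxel_size_um"][0]),
        organelle_centers_um=tuple(organelles),
    )
    return CellPhantom(
        geometry=geometry,
        materials=tuple(materials[i] for i in sorted(materials)),
        material_ids=ids,
        origin_um=tuple(float(v) for v in meta["origin_um"]),
        organelle_centers_um=organelles,
    )
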