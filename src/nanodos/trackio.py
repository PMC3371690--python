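"""Plain-text track files, raster writers and run manifests.

Track files are tabular text: a ``#``-prefixed header block carrying the
run configuration and seed, a sha256 checksum of the data body, a column
header, and one interaction event per row.  Floats are written with
``repr`` so a write/read round-trip is bit-exact and two runs with the same
seed produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .electron import InteractionEvent

__all__ = [
    "write_track_file",
    "read_track_file",
    "TrackFileError",
    "write_cluster_map",
    "write_distribution",
    "write_projection",
    "RunManifest",
    "file_sha256",
]

_COLUMNS = (
    "particle_id parent_id x_nm y_nm z_nm event_type channel "
    "energy_transfer_ev local_deposit_ev secondary_id"
)


class TrackFileError(ValueError):
    """Malformed track file (bad structure or checksum mismatch)."""


def _event_row(ev: InteractionEvent) -> str:
    x, y, z = ev.position_nm
    sec = "-" if ev.secondary_id is None else str(ev.secondary_id)
    return (
        f"{ev.particle_id}\t{ev.parent_id}\t{x!r}\t{y!r}\t{z!r}\t"
        f"{ev.event_type}\t{ev.channel}\t{ev.energy_transfer_ev!r}\t"
        f"{ev.local_deposit_ev!r}\t{sec}"
    )


def write_track_file(events, path, header: dict | None = None) -> str:
    """Write events to a track file; returns the body checksum."""
    rows = [_event_row(ev) for ev in events]
    body = "\n".join(rows)
    digest = hashlib.sha256(body.encode()).hexdigest()
    with open(path, "w") as fh:
        fh.write("# nanodos track file v1\n")
        for k, v in sorted((header or {}).items()):
            fh.write(f"# {k} = {v}\n")
        fh.write(f"# sha256 = {digest}\n")
        fh.write(f"# columns: {_COLUMNS}\n")
        if body:
            fh.write(body + "\n")
    return digest


def read_track_file(path):
    """Read a track file back into (header dict, list of events).

    Verifies the body checksum; a tampered file raises
    :class:`TrackFileError` with the offending line reported for parse
    errors.
    """
    header: dict[str, str] = {}
    rows: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" in stripped:
                    k, v = stripped.split("=", 1)
                    header[k.strip()] = v.strip()
                continue
            rows.append(line)
    body = "\n".join(rows)
    digest = hashlib.sha256(body.encode()).hexdigest()
    expected = header.get("sha256")
    if expected is not None and digest != expected:
        raise TrackFileError(
            f"checksum mismatch in {path}: file is corrupt or was modified"
        )
    events = []
    for i, line in enumerate(rows):
        parts = line.split("\t")
        if len(parts) != 10:
            raise TrackFileError(f"malformed event row at data line {i + 1}")
        try:
            events.append(
                InteractionEvent(
                    particle_id=int(parts[0]),
                    parent_id=int(parts[1]),
                    position_nm=(float(parts[2]), float(parts[3]), float(parts[4])),
                    event_type=parts[5],
                    channel=parts[6],
                    energy_transfer_ev=float(parts[7]),
                    local_deposit_ev=float(parts[8]),
                    secondary_id=None if parts[9] == "-" else int(parts[9]),
                )
            )
        except ValueError as exc:
            raise TrackFileError(
                f"bad value at data line {i + 1}: {exc}"
            ) from exc
    return header, events


def write_cluster_map(cmap, path, header: dict | None = None) -> None:
    """Cluster map as (y_index, z_index, count) rows for occupied voxels."""
    with open(path, "w") as fh:
        fh.write("# nanodos cluster map v1\n")
        meta = dict(cmap.metadata)
        meta.update(header or {})
        meta["depth_mm"] = cmap.grid.depth_mm
        meta["voxel_size_nm"] = cmap.grid.voxel_size_nm
        meta["slab_thickness_nm"] = cmap.grid.slab_thickness_nm
        meta["transverse_extent_nm"] = cmap.grid.transverse_extent_nm
        meta["total_ionizations"] = cmap.total
        for k, v in sorted(meta.items()):
            fh.write(f"# {k} = {v}\n")
        fh.write("# columns: y_index z_index count\n")
        ys, zs = np.nonzero(cmap.counts)
        for y, z in zip(ys, zs):
            fh.write(f"{y}\t{z}\t{int(cmap.counts[y, z])}\n")


def write_distribution(dist, path, header: dict | None = None) -> None:
    """Cluster-size distribution as (nu, frequency) rows."""
    with open(path, "w") as fh:
        fh.write("# nanodos cluster-size distribution v1\n")
        for k, v in sorted((header or {}).items()):
            fh.write(f"# {k} = {v}\n")
        fh.write(f"# n_voxels = {dist.n_voxels}\n")
        fh.write("# columns: nu frequency\n")
        for nu, f in enumerate(dist.frequencies):
            fh.write(f"{nu}\t{int(f)}\n")


def write_projection(array: np.ndarray, path, header: dict | None = None) -> None:
    """2-D raster as tab-separated rows."""
    with open(path, "w") as fh:
        fh.write("# nanodos 2d projection v1\n")
        for k, v in sorted((header or {}).items()):
            fh.write(f"# {k} = {v}\n")
        fh.write(f"# shape = {array.shape[0]} {array.shape[1]}\n")
        for row in array:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record emitted alongside every run's outputs."""

    config: dict
    fixture_versions: dict = field(default_factory=dict)
    code_version: str = "nanodos 0.1.0"
    runtimes_s: dict = field(default_factory=dict)
    output_checksums: dict = field(default_factory=dict)

    def add_output(self, path) -> None:
        self.output_checksums[Path(path).name] = file_sha256(path)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "fixture_versions": self.fixture_versions,
                    "code_version": self.code_version,
                    "runtimes_s": self.runtimes_s,
                    "output_checksums": self.output_checksums,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")

    def verify(self, out_dir) -> bool:
        """Do the recorded checksums still match the files on disk?"""
        return all(
            file_sha256(Path(out_dir) / name) == digest
            for name, digest in self.output_checksums.items()
        )


def fixture_versions() -> dict:
    """First header line of each packaged fixture table."""
    from importlib import resources

    out = {}
    for name in ("drude_channels.tsv", "elastic_imfp.tsv", "photon_xs.tsv"):
        text = resources.files("nanodos.data").joinpath(name).read_text()
        first = text.splitlines()[0].lstrip("# ").strip()
        out[name] = first
    return out
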