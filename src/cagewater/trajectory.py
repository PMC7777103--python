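"""Trajectory and topology data model, file I/O, and spatial region assignment.

Coordinates are Å, times ps, velocities Å/ps. XYZ and extended-XYZ files are
parsed natively (the extended-XYZ comment line carries ``Lattice=...``,
``Time=...`` and a ``Properties=`` column spec that may include velocities);
multi-MODEL PDB files are read through MDAnalysis for positions only.

Space around the host is partitioned into three regions:

* ``cage``      — water oxygen within ``cage_radius`` of the cage center,
* ``hydration`` — otherwise within ``hydration_cutoff`` of any cage atom,
* ``bulk``      — everything else.

The default cage radius of 4.0 Å gives a spherical interior of ≈268 Å³,
matching the ~270 Å³ cavity of the Ga4L6 tetrahedral host; the default
hydration cutoff is 4.1 Å.
"""

from __future__ import annotations

import re
import shlex
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "Frame",
    "Trajectory",
    "Topology",
    "CageDefinition",
    "TrajectoryParseError",
    "read_trajectory",
    "write_trajectory",
    "read_topology",
    "assign_regions",
    "count_region_waters",
    "minimum_image",
    "pair_distances",
    "water_oxygen_positions",
]

REGIONS = ("cage", "hydration", "bulk")


class TrajectoryParseError(ValueError):
    """Raised when a trajectory file cannot be parsed."""


@dataclass
class Frame:
    """One snapshot: atom species, positions, optional velocities and box."""

    index: int
    time: float
    positions: np.ndarray
    species: list[str]
    velocities: np.ndarray | None = None
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if len(self.species) != len(self.positions):
            raise ValueError("species count must equal positions count")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions shape")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be 3 strictly positive edge lengths")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)


@dataclass
class Trajectory:
    """Ordered, uniformly spaced frames plus an optional topology."""

    frames: list[Frame]
    timestep: float | None = None
    topology: "Topology | None" = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a trajectory needs at least one frame")
        times = np.array([f.time for f in self.frames])
        if len(times) > 1:
            dts = np.diff(times)
            if np.any(dts <= 0):
                raise ValueError("frame times must be strictly increasing")
            if np.max(np.abs(dts - dts[0])) > 1e-9:
                raise ValueError("frames must be uniformly spaced in time")
            if self.timestep is None:
                self.timestep = float(dts[0])

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def duration(self) -> float:
        return self.frames[-1].time - self.frames[0].time

    def positions_array(self) -> np.ndarray:
        """All positions as an (n_frames, n_atoms, 3) array."""
        n0 = self.frames[0].n_atoms
        if any(f.n_atoms != n0 for f in self.frames):
            raise ValueError("atom count varies across frames")
        return np.stack([f.positions for f in self.frames])

    def velocities_array(self) -> np.ndarray:
        if any(f.velocities is None for f in self.frames):
            raise ValueError("trajectory has no velocities")
        return np.stack([f.velocities for f in self.frames])


@dataclass
class Topology:
    """Atom bookkeeping: water triplets, host, guest, charges.

    ``water_triplets`` lists (O, H, H) index triplets; ``lone_oxygens`` holds
    oxygen-only point waters used by synthetic occupancy ensembles. The two
    sets together define the waters of the system. ``point_waters=True``
    declares that *every* atom of each frame is a water oxygen (used by
    occupancy ensembles whose molecule count varies from frame to frame).
    """

    water_triplets: list[tuple[int, int, int]] = field(default_factory=list)
    cage_atoms: list[int] = field(default_factory=list)
    guest_atoms: list[int] = field(default_factory=list)
    counterion_atoms: list[int] = field(default_factory=list)
    lone_oxygens: list[int] = field(default_factory=list)
    charges: np.ndarray | None = None
    point_waters: bool = False

    def __post_init__(self) -> None:
        water_atoms = {i for t in self.water_triplets for i in t}
        water_atoms |= set(self.lone_oxygens)
        groups = [water_atoms, set(self.cage_atoms), set(self.guest_atoms),
                  set(self.counterion_atoms)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("atom index sets must be disjoint")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)

    @property
    def water_oxygens(self) -> np.ndarray:
        """Indices of all water oxygen atoms (triplet O's plus lone oxygens)."""
        if self.point_waters:
            raise ValueError(
                "point-water topology: oxygen indices are frame-dependent; "
                "use water_oxygen_positions(frame, topo)")
        idx = [t[0] for t in self.water_triplets] + list(self.lone_oxygens)
        return np.asarray(idx, dtype=int)

    @property
    def n_waters(self) -> int:
        return len(self.water_triplets) + len(self.lone_oxygens)

    def validate_species(self, frame: Frame) -> None:
        """Check that every triplet is (O, H, H) in the given frame."""
        for o, h1, h2 in self.water_triplets:
            if frame.species[o] != "O" or frame.species[h1] != "H" or frame.species[h2] != "H":
                raise ValueError(f"water triplet ({o},{h1},{h2}) is not (O,H,H)")


@dataclass
class CageDefinition:
    """Geometric definition of the host interior and hydration shell."""

    cage_radius: float = 4.0
    hydration_cutoff: float = 4.1
    center: np.ndarray | None = None
    vertex_atoms: list[int] | None = None

    def __post_init__(self) -> None:
        if self.cage_radius <= 0 or self.hydration_cutoff <= 0:
            raise ValueError("cage_radius and hydration_cutoff must be positive")
        if self.center is not None:
            self.center = np.asarray(self.center, dtype=float)

    def resolve_center(self, frame: Frame | None = None) -> np.ndarray:
        if self.center is not None:
            return self.center
        if self.vertex_atoms and frame is not None:
            return frame.positions[self.vertex_atoms].mean(axis=0)
        raise ValueError(
            "cage center unresolvable: give an explicit center or vertex atoms"
        )

    @property
    def volume(self) -> float:
        from .units import sphere_volume

        return sphere_volume(self.cage_radius)


# ---------------------------------------------------------------------------
# geometry helpers

def minimum_image(dx: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention.

    With ``box=None`` boundaries are open and ``dx`` is returned unchanged.
    """
    if box is None:
        return dx
    return dx - box * np.round(dx / box)


def pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """(len(a), len(b)) distance matrix with optional periodic wrapping."""
    dx = a[:, None, :] - b[None, :, :]
    dx = minimum_image(dx, box)
    return np.linalg.norm(dx, axis=-1)


# ---------------------------------------------------------------------------
# XYZ / extended-XYZ I/O

_PROPS_RE = re.compile(r"Properties=(\S+)", re.IGNORECASE)


def _parse_comment(comment: str) -> dict:
    """Parse key=value tokens of an extended-XYZ comment line."""
    out: dict = {}
    try:
        tokens = shlex.split(comment)
    except ValueError:
        return out
    for tok in tokens:
        if "=" not in tok:
            continue
        key, val = tok.split("=", 1)
        out[key.lower()] = val
    return out


def _parse_properties(spec: str) -> list[tuple[str, str, int]]:
    parts = spec.split(":")
    if len(parts) % 3:
        raise TrajectoryParseError(f"malformed Properties spec: {spec!r}")
    return [(parts[i], parts[i + 1], int(parts[i + 2]))
            for i in range(0, len(parts), 3)]


def _read_xyz_frames(path: Path) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    idx = 0
    default_dt = 1.0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise TrajectoryParseError(
                f"{path}: line {i + 1}: expected atom count, got {lines[i]!r}"
            )
        if i + 1 + n >= len(lines) + 1:
            raise TrajectoryParseError(f"{path}: truncated frame at line {i + 1}")
        comment = lines[i + 1].rstrip("\n")
        meta = _parse_comment(comment)
        box = None
        if "lattice" in meta:
            lat = np.fromstring(meta["lattice"], sep=" ")
            if lat.size == 9:
                box = lat.reshape(3, 3).diagonal().copy()
        time = float(meta["time"]) if "time" in meta else idx * default_dt
        columns = None
        if "properties" in meta:
            columns = _parse_properties(meta["properties"])
        species, pos, vel = [], [], []
        has_vel = False
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise TrajectoryParseError(
                    f"{path}: line {i + 3 + j}: malformed atom line"
                )
            if columns:
                col = 0
                row: dict[str, list[str]] = {}
                for name, _kind, width in columns:
                    row[name.lower()] = parts[col:col + width]
                    col += width
                species.append(row.get("species", [parts[0]])[0])
                pos.append([float(x) for x in row["pos"]])
                for vkey in ("vel", "velo", "velocities"):
                    if vkey in row:
                        vel.append([float(x) for x in row[vkey]])
                        has_vel = True
                        break
            else:
                species.append(parts[0])
                pos.append([float(x) for x in parts[1:4]])
        frames.append(Frame(
            index=idx, time=time, positions=np.array(pos), species=species,
            velocities=np.array(vel) if has_vel else None, box=box,
        ))
        idx += 1
        i += 2 + n
    if not frames:
        raise TrajectoryParseError(f"{path}: no frames found")
    return frames


def _read_pdb_frames(path: Path) -> list[Frame]:
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    species = [el if (el := getattr(a, "element", "") or "") else a.name[0]
               for a in u.atoms]
    frames = []
    for k, ts in enumerate(u.trajectory):
        box = None
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            box = np.asarray(ts.dimensions[:3], dtype=float)
        frames.append(Frame(index=k, time=float(k), positions=ts.positions.copy(),
                            species=list(species), box=box))
    return frames


def read_trajectory(path: str | Path, format: str | None = None,
                    timestep: float | None = None,
                    topology: Topology | None = None) -> Trajectory:
    """Read a trajectory from XYZ, extended-XYZ or multi-MODEL PDB.

    The format is inferred from the suffix when not given. Atom order is
    preserved exactly as in the file.
    """
    path = Path(path)
    if format is None:
        format = {".xyz": "xyz", ".extxyz": "extxyz", ".pdb": "pdb"}.get(
            path.suffix.lower(), "xyz")
    if format in ("xyz", "extxyz"):
        frames = _read_xyz_frames(path)
        if format == "xyz" and len({f.n_atoms for f in frames}) > 1:
            raise TrajectoryParseError(
                f"{path}: inconsistent atom count across frames")
    elif format == "pdb":
        frames = _read_pdb_frames(path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    if timestep is not None and len(frames) > 1:
        for k, f in enumerate(frames):
            f.time = k * timestep
    return Trajectory(frames=frames, timestep=timestep, topology=topology)


def write_trajectory(traj: Trajectory | Iterable[Frame], path: str | Path) -> None:
    """Write frames as extended-XYZ (velocity columns included when present)."""
    frames = traj.frames if isinstance(traj, Trajectory) else list(traj)
    with open(path, "w") as fh:
        for f in frames:
            has_vel = f.velocities is not None
            props = "species:S:1:pos:R:3" + (":vel:R:3" if has_vel else "")
            comment = f"Properties={props} Time={f.time:.6f}"
            if f.box is not None:
                b = f.box
                comment = (f'Lattice="{b[0]:.6f} 0.0 0.0 0.0 {b[1]:.6f} 0.0 '
                           f'0.0 0.0 {b[2]:.6f}" ') + comment
            fh.write(f"{f.n_atoms}\n{comment}\n")
            for a in range(f.n_atoms):
                x, y, z = f.positions[a]
                line = f"{f.species[a]} {x:.8f} {y:.8f} {z:.8f}"
                if has_vel:
                    vx, vy, vz = f.velocities[a]
                    line += f" {vx:.8f} {vy:.8f} {vz:.8f}"
                fh.write(line + "\n")


def read_topology(path: str | Path) -> Topology:
    """Read a topology config (YAML/JSON, 0-based index lists)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return Topology(
        water_triplets=[tuple(t) for t in data.get("water_triplets", [])],
        cage_atoms=list(data.get("cage_atoms", [])),
        guest_atoms=list(data.get("guest_atoms", [])),
        counterion_atoms=list(data.get("counterion_atoms", [])),
        lone_oxygens=list(data.get("lone_oxygens", [])),
        charges=data.get("charges"),
    )


def water_oxygen_positions(frame: Frame, topo: Topology) -> np.ndarray:
    """Positions of the water oxygens of a frame under either topology mode."""
    if topo.point_waters:
        return frame.positions
    return frame.positions[topo.water_oxygens]


# ---------------------------------------------------------------------------
# region assignment

def assign_regions(frame: Frame, topo: Topology, cage: CageDefinition) -> np.ndarray:
    """Label each water as 'cage', 'hydration' or 'bulk'.

    A water is *cage* iff its oxygen lies within ``cage_radius`` of the cage
    center; otherwise *hydration* iff the oxygen is within
    ``hydration_cutoff`` of any cage atom; otherwise *bulk*. The labels
    partition the water set.
    """
    center = cage.resolve_center(frame)
    opos = water_oxygen_positions(frame, topo)
    if len(opos) == 0:
        return np.array([], dtype=object)
    d_center = np.linalg.norm(minimum_image(opos - center, frame.box), axis=1)
    labels = np.full(len(opos), "bulk", dtype=object)
    inside = d_center <= cage.cage_radius
    labels[inside] = "cage"
    if topo.cage_atoms:
        cpos = frame.positions[topo.cage_atoms]
        dmin = pair_distances(opos, cpos, frame.box).min(axis=1)
        labels[~inside & (dmin <= cage.hydration_cutoff)] = "hydration"
    return labels


def count_region_waters(traj: Trajectory, topo: Topology, cage: CageDefinition,
                        region: str, block_length: int = 10) -> dict:
    """Per-frame count of waters in a region, with block-averaged stderr.

    Returns ``{"counts", "mean", "stderr"}``; the standard error comes from
    block averaging over blocks of ``block_length`` frames (correlated MD
    frames make the naive stderr optimistic).
    """
    if region not in REGIONS:
        raise ValueError(f"region must be one of {REGIONS}")
    counts = np.array([
        int(np.sum(assign_regions(f, topo, cage) == region)) for f in traj
    ])
    mean = float(counts.mean())
    nblocks = max(1, len(counts) // max(1, block_length))
    if nblocks > 1:
        blocks = np.array_split(counts[: nblocks * block_length], nblocks)
        bm = np.array([b.mean() for b in blocks])
        stderr = float(bm.std(ddof=1) / np.sqrt(nblocks))
    else:
        stderr = 0.0 if np.all(counts == counts[0]) else float(
            counts.std(ddof=1) / np.sqrt(len(counts)))
    return {"counts": counts, "mean": mean, "stderr": stderr}
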