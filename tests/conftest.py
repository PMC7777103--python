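"""Shared fixtures: small constructed frames and synthetic ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from cagewater.trajectory import CageDefinition, Frame, Topology, Trajectory


def make_water(o, direction, spread_deg=104.52, oh=0.9572):
    """O at ``o`` with two H's; the H-bisector points along ``direction``."""
    o = np.asarray(o, dtype=float)
    axis = np.asarray(direction, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    perp = np.cross(axis, ref)
    perp /= np.linalg.norm(perp)
    half = np.deg2rad(spread_deg) / 2.0
    h1 = o + oh * (np.cos(half) * axis + np.sin(half) * perp)
    h2 = o + oh * (np.cos(half) * axis - np.sin(half) * perp)
    return o, h1, h2


def frame_from_waters(waters, extra_species=(), extra_positions=(), time=0.0,
                      box=None):
    """Build a Frame + Topology from a list of (O, H1, H2) coordinate triples."""
    pos, species, triplets = [], [], []
    for o, h1, h2 in waters:
        base = len(pos)
        pos += [o, h1, h2]
        species += ["O", "H", "H"]
        triplets.append((base, base + 1, base + 2))
    for sp, p in zip(extra_species, extra_positions):
        species.append(sp)
        pos.append(np.asarray(p, dtype=float))
    frame = Frame(index=0, time=time, positions=np.array(pos),
                  species=species, box=box)
    topo = Topology(water_triplets=triplets,
                    cage_atoms=list(range(len(pos) - len(extra_species),
                                          len(pos))))
    return frame, topo


def random_water_frame(n_waters, box=12.0, seed=0):
    """n random waters with random orientations in an open box."""
    rng = np.random.default_rng(seed)
    waters = []
    for _ in range(n_waters):
        o = rng.uniform(0, box, 3)
        d = rng.normal(size=3)
        waters.append(make_water(o, d))
    return frame_from_waters(waters)


@pytest.fixture(scope="session")
def droplet():
    """Langevin droplet: 9 confined + 3 exchanging + 15 exterior waters."""
    from cagewater.synth import make_confined_droplet

    cage = CageDefinition(cage_radius=4.0, center=np.zeros(3))
    traj, topo = make_confined_droplet(
        n_inside=9, cage=cage, n_outside=15, n_exchange=3,
        dynamics="langevin", n_frames=300, dt=0.05, seed=11)
    return traj, topo, cage


@pytest.fixture(scope="session")
def poisson_bulk():
    from cagewater.synth import make_bulk_ensemble

    return make_bulk_ensemble(density=0.0334, box=12.0, n_frames=6000,
                              occupancy_model="poisson", seed=7)
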