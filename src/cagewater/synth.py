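"""Synthetic-data generators with analytically known ground truth.

Every statistical structure the downstream analyses assume can be emulated
here: bulk-density point-water ensembles with Poisson or tunable-variance
Gaussian occupancy statistics, a wall-confined droplet with Langevin
dynamics, two-state Markov hydrogen-bond indicator chains, rotational
Brownian dipoles, harmonic velocity signals, and noisy three-oscillator
absorbance spectra. All generators are fully determined by their seed.

These ensembles provide known ground truth for validating the analysis
machinery; they make no attempt to reproduce real water's pair correlations
or energetics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .trajectory import CageDefinition, Frame, Topology, Trajectory
from .units import BULK_WATER_DENSITY, C_CM_PER_PS, KB_KCAL_MOL_K, sphere_volume

__all__ = [
    "GeneratorSpec",
    "generate",
    "make_tetrahedral_lattice",
    "make_fcc_lattice",
    "make_ideal_gas",
    "make_bulk_ensemble",
    "make_confined_droplet",
    "make_hb_markov",
    "make_rotational_diffusion",
    "make_harmonic_velocities",
    "make_oscillator_spectrum",
    "velocities_to_trajectory",
]

# kcal/mol expressed in g/mol·Å²/ps² (for Langevin thermal velocities)
_KCAL_TO_G_A2_PS2 = 418.4
_WATER_MASS = 18.015  # g/mol

# rigid water geometry used when dressing oxygens with hydrogens
_OH_BOND = 0.9572  # Å
_HOH_ANGLE = np.deg2rad(104.52)


@dataclass
class GeneratorSpec:
    """Declarative description of a synthetic dataset (kind + parameters + seed)."""

    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    _KINDS = (
        "tetrahedral_lattice", "fcc_lattice", "ideal_gas",
        "gaussian_occupancy_ensemble", "confined_droplet", "hb_markov",
        "rotational_diffusion", "harmonic_velocities", "oscillator_spectrum",
    )

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}")


def generate(spec: GeneratorSpec):
    """Dispatch a GeneratorSpec to its generator function."""
    p = dict(spec.parameters)
    if spec.kind == "tetrahedral_lattice":
        return make_tetrahedral_lattice(**p)
    if spec.kind == "fcc_lattice":
        return make_fcc_lattice(seed=spec.seed, **p)
    if spec.kind == "ideal_gas":
        return make_ideal_gas(seed=spec.seed, **p)
    if spec.kind == "gaussian_occupancy_ensemble":
        return make_bulk_ensemble(seed=spec.seed, occupancy_model="gaussian", **p)
    if spec.kind == "confined_droplet":
        return make_confined_droplet(seed=spec.seed, **p)
    if spec.kind == "hb_markov":
        return make_hb_markov(seed=spec.seed, **p)
    if spec.kind == "rotational_diffusion":
        return make_rotational_diffusion(seed=spec.seed, **p)
    if spec.kind == "harmonic_velocities":
        return make_harmonic_velocities(seed=spec.seed, **p)
    if spec.kind == "oscillator_spectrum":
        return make_oscillator_spectrum(seed=spec.seed, **p)
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# lattices

def make_tetrahedral_lattice(n_cells: int = 1, spacing: float = 2.75) -> Frame:
    """Diamond-cubic oxygen lattice; every site sees 4 neighbors at cos ψ = −1/3.

    ``spacing`` is the nearest-neighbor O–O distance (2.75 Å ≈ ice). The
    frame carries a periodic box, so *all* sites are interior sites and the
    tetrahedral order parameter q equals 1 exactly on every one of them.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    a = 4.0 * spacing / np.sqrt(3.0)
    fcc = np.array([[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
    basis = np.vstack([fcc, fcc + 0.25])
    cells = np.array([[i, j, k] for i in range(n_cells)
                      for j in range(n_cells) for k in range(n_cells)])
    pos = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3) * a
    box = np.full(3, n_cells * a)
    return Frame(index=0, time=0.0, positions=pos,
                 species=["O"] * len(pos), box=box)


def make_fcc_lattice(n_cells: int = 3, a: float | None = None,
                     density: float = BULK_WATER_DENSITY,
                     broadening: float = 0.0, seed: int = 0) -> Frame:
    """Face-centered-cubic oxygen lattice, optionally thermally broadened.

    If ``a`` is omitted it is set so the lattice density matches ``density``
    (4 atoms per cell). ``broadening`` is an isotropic Gaussian displacement
    sd in Å mimicking thermal motion.
    """
    if a is None:
        a = (4.0 / density) ** (1.0 / 3.0)
    fcc = np.array([[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
    cells = np.array([[i, j, k] for i in range(n_cells)
                      for j in range(n_cells) for k in range(n_cells)])
    pos = (cells[:, None, :] + fcc[None, :, :]).reshape(-1, 3) * a
    if broadening > 0:
        rng = np.random.default_rng(seed)
        pos = pos + rng.normal(scale=broadening, size=pos.shape)
    box = np.full(3, n_cells * a)
    return Frame(index=0, time=0.0, positions=pos,
                 species=["O"] * len(pos), box=box)


# ---------------------------------------------------------------------------
# occupancy ensembles

def make_ideal_gas(density: float = BULK_WATER_DENSITY, box: float = 14.0,
                   n_frames: int = 100, seed: int = 0) -> Trajectory:
    """Uncorrelated uniform point waters (Poisson occupancy in any sub-volume)."""
    return make_bulk_ensemble(density=density, box=box, n_frames=n_frames,
                              occupancy_model="poisson", seed=seed)


def make_bulk_ensemble(density: float = BULK_WATER_DENSITY, box: float = 14.0,
                       n_frames: int = 1000, occupancy_model: str = "poisson",
                       variance_ratio: float = 1.0,
                       probe_radius: float | None = None,
                       probe_center: np.ndarray | None = None,
                       seed: int = 0) -> Trajectory:
    """Point-water frames with prescribed probe-sphere occupancy statistics.

    ``poisson``: the per-frame molecule count is Poisson(ρ·V_box) with
    uniform positions, so the occupancy of *any* sub-volume v is exactly
    Poisson(ρv). ``gaussian``: the occupancy of the declared probe sphere is
    drawn first from a discretized Gaussian with mean ρv and variance
    ``variance_ratio``·ρv (clipped at 0), positions are then distributed
    uniformly inside/outside the sphere. The Gaussian model emulates
    occupancy statistics only, not pair structure.

    Frames hold oxygen-only point waters; the attached topology sets
    ``point_waters=True`` since the molecule count varies across frames.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if occupancy_model not in ("poisson", "gaussian"):
        raise ValueError("occupancy_model must be 'poisson' or 'gaussian'")
    if variance_ratio <= 0:
        raise ValueError("variance_ratio must be positive")
    rng = np.random.default_rng(seed)
    box_vec = np.full(3, float(box))
    v_box = float(box) ** 3
    frames: list[Frame] = []

    if occupancy_model == "poisson":
        counts = rng.poisson(density * v_box, size=n_frames)
        for k in range(n_frames):
            pos = rng.uniform(0.0, box, size=(int(counts[k]), 3))
            frames.append(Frame(index=k, time=float(k),
                                positions=pos, species=["O"] * int(counts[k]),
                                box=box_vec.copy()))
    else:
        if probe_radius is None:
            raise ValueError("gaussian occupancy model needs a probe_radius")
        center = (np.full(3, box / 2.0) if probe_center is None
                  else np.asarray(probe_center, dtype=float))
        v_probe = sphere_volume(probe_radius)
        if v_probe >= v_box:
            raise ValueError("probe sphere does not fit inside the box")
        mean = density * v_probe
        n_in = np.clip(np.rint(rng.normal(mean, np.sqrt(variance_ratio * mean),
                                          size=n_frames)), 0, None).astype(int)
        n_out = rng.poisson(density * (v_box - v_probe), size=n_frames)
        for k in range(n_frames):
            inside = _uniform_in_sphere(rng, int(n_in[k]), probe_radius) + center
            outside = _uniform_outside_sphere(rng, int(n_out[k]), box,
                                              center, probe_radius)
            pos = np.vstack([inside, outside])
            frames.append(Frame(index=k, time=float(k), positions=pos,
                                species=["O"] * len(pos), box=box_vec.copy()))
    topo = Topology(point_waters=True)
    return Trajectory(frames=frames, timestep=1.0, topology=topo)


def _uniform_in_sphere(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    if n == 0:
        return np.empty((0, 3))
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = radius * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return u * r


def _uniform_outside_sphere(rng: np.random.Generator, n: int, box: float,
                            center: np.ndarray, radius: float) -> np.ndarray:
    out = np.empty((0, 3))
    while len(out) < n:
        cand = rng.uniform(0.0, box, size=(max(16, 2 * (n - len(out))), 3))
        keep = np.linalg.norm(cand - center, axis=1) > radius
        out = np.vstack([out, cand[keep]])
    return out[:n]


# ---------------------------------------------------------------------------
# confined droplet

def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    u = rng.normal(size=(n, 3))
    return u / np.linalg.norm(u, axis=1, keepdims=True)


def _dress_with_hydrogens(o_pos: np.ndarray, orient: np.ndarray) -> np.ndarray:
    """Place two H's per oxygen from a rigid geometry and a per-molecule axis."""
    n = len(o_pos)
    # build an orthonormal frame around each orientation axis
    axis = orient
    ref = np.where(np.abs(axis[:, [0]]) < 0.9,
                   np.tile([1.0, 0.0, 0.0], (n, 1)),
                   np.tile([0.0, 1.0, 0.0], (n, 1)))
    perp = np.cross(axis, ref)
    perp /= np.linalg.norm(perp, axis=1, keepdims=True)
    half = _HOH_ANGLE / 2.0
    h1 = o_pos + _OH_BOND * (np.cos(half) * axis + np.sin(half) * perp)
    h2 = o_pos + _OH_BOND * (np.cos(half) * axis - np.sin(half) * perp)
    return np.stack([h1, h2], axis=1)


def make_confined_droplet(n_inside: int = 9, cage: CageDefinition | None = None,
                          n_outside: int = 20, n_exchange: int = 0,
                          dynamics: str = "static", n_frames: int = 100,
                          dt: float = 0.05, temperature: float = 300.0,
                          friction: float = 2.0, outer_radius: float = 12.0,
                          seed: int = 0) -> tuple[Trajectory, Topology]:
    """Droplet of wall-confined waters inside a cage plus free exterior waters.

    ``n_inside`` waters are held inside the cage sphere by a reflecting wall
    (long residence, "arrested"); ``n_exchange`` waters start inside but feel
    no wall and exchange with the exterior; ``n_outside`` waters move freely
    in the shell between the cage and ``outer_radius``. Four vertex atoms
    (species Ga) are placed on a tetrahedron just outside the cage sphere so
    region assignment has host atoms to measure against.

    ``dynamics='static'`` repeats the initial configuration; ``'langevin'``
    integrates overdamped-free Langevin motion (BAOAB-style velocity
    Ornstein–Uhlenbeck plus drift) with hard reflecting walls. Hydrogens ride
    rigidly on their oxygen with a fixed per-molecule orientation.
    """
    if cage is None:
        cage = CageDefinition()
    if n_inside < 0:
        raise ValueError("n_inside must be >= 0")
    n_max = int(np.ceil(2.0 * BULK_WATER_DENSITY * cage.volume))
    if n_inside + n_exchange > n_max:
        raise ValueError(
            f"cage overfilled: {n_inside + n_exchange} waters exceed packing "
            f"feasibility (~{n_max}) for radius {cage.cage_radius} Å")
    if dynamics not in ("static", "langevin"):
        raise ValueError("dynamics must be 'static' or 'langevin'")
    rng = np.random.default_rng(seed)
    center = np.zeros(3) if cage.center is None else np.asarray(cage.center, float)

    wall_in = cage.cage_radius - 0.15  # keep O strictly within the cage sphere
    shell_lo = cage.cage_radius + 1.5
    o0_in = center + _uniform_in_sphere(rng, n_inside + n_exchange, wall_in * 0.9)
    u = _random_unit(rng, n_outside)
    r = (rng.uniform(shell_lo**3, outer_radius**3, size=(n_outside, 1))) ** (1 / 3)
    o0_out = center + u * r
    o_pos0 = np.vstack([o0_in, o0_out])
    n_w = len(o_pos0)
    orient = _random_unit(rng, n_w)

    # vertex atoms of the host tetrahedron
    tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
    tet /= np.linalg.norm(tet, axis=1, keepdims=True)
    vert = center + tet * (cage.cage_radius + 1.0)

    kT = KB_KCAL_MOL_K * temperature * _KCAL_TO_G_A2_PS2  # g/mol Å²/ps²
    sigma_v = np.sqrt(kT / _WATER_MASS)
    c1 = np.exp(-friction * dt)
    c2 = sigma_v * np.sqrt(1.0 - c1 * c1)

    confined = np.zeros(n_w, bool)
    confined[:n_inside] = True
    exterior = np.zeros(n_w, bool)
    exterior[n_inside + n_exchange:] = True

    o = o_pos0.copy()
    v = rng.normal(scale=sigma_v, size=(n_w, 3))
    frames: list[Frame] = []
    for k in range(n_frames):
        if dynamics == "langevin" and k > 0:
            v = c1 * v + c2 * rng.normal(size=(n_w, 3))
            o = o + v * dt
            o, v = _reflect_sphere(o, v, center, wall_in, confined, inside=True)
            o, v = _reflect_sphere(o, v, center, outer_radius, ~confined,
                                   inside=True)
            o, v = _reflect_sphere(o, v, center, shell_lo, exterior,
                                   inside=False)
        h = _dress_with_hydrogens(o, orient)
        pos = np.vstack([vert] + [np.vstack([o[i], h[i]]) for i in range(n_w)])
        vel = np.vstack([np.zeros((4, 3))] +
                        [np.tile(v[i], (3, 1)) for i in range(n_w)])
        species = ["Ga"] * 4 + ["O", "H", "H"] * n_w
        frames.append(Frame(index=k, time=k * dt, positions=pos,
                            species=species, velocities=vel))
    triplets = [(4 + 3 * i, 5 + 3 * i, 6 + 3 * i) for i in range(n_w)]
    topo = Topology(water_triplets=triplets, cage_atoms=[0, 1, 2, 3])
    return Trajectory(frames=frames, timestep=dt, topology=topo), topo


def _reflect_sphere(pos, vel, center, radius, mask, inside: bool):
    """Reflect masked particles at a spherical wall (inside=True keeps them in)."""
    d = pos - center
    r = np.linalg.norm(d, axis=1)
    bad = mask & ((r > radius) if inside else (r < radius))
    if np.any(bad):
        n_hat = d[bad] / r[bad, None]
        # fold the radial excursion back across the wall
        pos = pos.copy()
        vel = vel.copy()
        pos[bad] = center + n_hat * (2 * radius - r[bad])[:, None]
        v_rad = np.sum(vel[bad] * n_hat, axis=1, keepdims=True)
        vel[bad] = vel[bad] - 2.0 * v_rad * n_hat
    return pos, vel


# ---------------------------------------------------------------------------
# stochastic time series

def make_hb_markov(n_bonds: int = 100, k_break: float = 0.5,
                   k_form: float = 0.5, duration: float = 50.0,
                   dt: float = 0.01, seed: int = 0) -> tuple[np.ndarray, float]:
    """Stationary two-state Markov HB indicator chains h(t) ∈ {0, 1}.

    Uses the exact discrete skeleton of the continuous-time two-state chain,
    so the intermittent correlator is exactly
    C(t) = p + (1−p)·exp(−(k_break+k_form)·t) with p = k_form/(k_form+k_break).
    Returns (h of shape (n_bonds, n_steps), dt).
    """
    if k_break < 0 or k_form < 0 or k_break + k_form <= 0:
        raise ValueError("rates must be non-negative with positive sum")
    k = k_break + k_form
    if dt >= 1.0 / k:
        warnings.warn("dt >= 1/(k_break+k_form): discretization too coarse",
                      stacklevel=2)
    p = k_form / k
    decay = 1.0 - np.exp(-k * dt)
    p_01 = p * decay          # 0 -> 1
    p_10 = (1.0 - p) * decay  # 1 -> 0
    n_steps = int(round(duration / dt)) + 1
    rng = np.random.default_rng(seed)
    h = np.empty((n_bonds, n_steps), dtype=np.int8)
    h[:, 0] = rng.uniform(size=n_bonds) < p
    u = rng.uniform(size=(n_bonds, n_steps - 1))
    for t in range(1, n_steps):
        prev = h[:, t - 1]
        flip = np.where(prev == 1, u[:, t - 1] < p_10, u[:, t - 1] < p_01)
        h[:, t] = np.where(flip, 1 - prev, prev)
    return h, dt


def make_rotational_diffusion(n_molecules: int = 200, D_r: float = 1.0 / 12.0,
                              duration: float = 20.0, dt: float = 0.01,
                              seed: int = 0) -> tuple[np.ndarray, float]:
    """Isotropic rotational Brownian motion of unit dipoles.

    The rank-ℓ orientational correlator decays as exp(−ℓ(ℓ+1)·D_r·t); for
    ℓ = 2 the relaxation time is 1/(6·D_r). Returns (unit vectors of shape
    (n_molecules, n_steps, 3), dt).
    """
    if D_r <= 0:
        raise ValueError("D_r must be positive")
    n_steps = int(round(duration / dt)) + 1
    rng = np.random.default_rng(seed)
    u = _random_unit(rng, n_molecules)
    out = np.empty((n_molecules, n_steps, 3))
    out[:, 0] = u
    step = np.sqrt(2.0 * D_r * dt)
    for t in range(1, n_steps):
        xi = rng.normal(size=(n_molecules, 3))
        xi -= np.sum(xi * u, axis=1, keepdims=True) * u  # tangent-plane noise
        u = u + step * xi
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        out[:, t] = u
    return out, dt


def make_harmonic_velocities(frequencies, duration: float = 20.0,
                             dt: float = 0.002, amplitudes=None,
                             n_atoms: int = 1,
                             seed: int = 0) -> tuple[np.ndarray, float]:
    """Superposed random-phase cosine velocities at given wavenumbers (cm⁻¹).

    Returns (velocities of shape (n_steps, n_atoms, 3), dt). Raises if any
    requested wavenumber is above the Nyquist limit 1/(2·c·dt).
    """
    frequencies = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if amplitudes is None:
        amplitudes = np.ones_like(frequencies)
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    nyquist = 1.0 / (2.0 * C_CM_PER_PS * dt)
    for nu in frequencies:
        if nu >= nyquist:
            raise ValueError(
                f"frequency {nu} cm^-1 aliases: Nyquist limit is "
                f"{nyquist:.1f} cm^-1 for dt={dt} ps")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt)) + 1
    t = np.arange(n_steps) * dt
    vel = np.zeros((n_steps, n_atoms, 3))
    for nu, amp in zip(frequencies, amplitudes):
        omega = 2.0 * np.pi * nu * C_CM_PER_PS  # rad/ps
        for a in range(n_atoms):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            direction = _random_unit(rng, 1)[0]
            vel[:, a, :] += amp * np.cos(omega * t + phase)[:, None] * direction
    return vel, dt


def velocities_to_trajectory(vel: np.ndarray, dt: float,
                             species: str = "O") -> Trajectory:
    """Wrap a (n_steps, n_atoms, 3) velocity array into a Trajectory.

    Positions are the time integral of the velocities (irrelevant to spectra
    but kept consistent); useful for feeding synthetic signals to the THz
    engine.
    """
    n_steps, n_atoms, _ = vel.shape
    pos = np.cumsum(vel, axis=0) * dt
    frames = [Frame(index=k, time=k * dt, positions=pos[k],
                    species=[species] * n_atoms, velocities=vel[k])
              for k in range(n_steps)]
    return Trajectory(frames=frames, timestep=dt)


# ---------------------------------------------------------------------------
# spectra

def make_oscillator_spectrum(params=None, grid=None, noise_sd: float = 0.0,
                             seed: int = 0):
    """Evaluate the three-damped-oscillator model and add Gaussian noise.

    ``params`` is an OscillatorParams (defaults to the package's cage-water
    defaults); ``grid`` defaults to 50–450 cm⁻¹ at 2 cm⁻¹ spacing, the
    experimental THz window.
    """
    from .spectra import Spectrum, default_oscillator_params, oscillator_model

    if params is None:
        params = default_oscillator_params("cage")
    if grid is None:
        grid = np.arange(50.0, 450.0 + 1e-9, 2.0)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be monotone increasing")
    values = oscillator_model(params, grid)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(scale=noise_sd, size=grid.shape)
    return Spectrum(frequency=grid, intensity=values,
                    metadata={"source": "oscillator_model", "noise_sd": noise_sd,
                              "seed": seed})
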