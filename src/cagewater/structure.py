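"""Pair structure and order parameters for water oxygens.

Implements the oxygen–oxygen radial distribution function g_OO(r) with
region-resolved normalization, coordination numbers by integration under
g_OO(r), the Errington–Debenedetti tetrahedral order parameter

    q = 1 − (3/8) Σ_{j<k} (cos ψ_jk + 1/3)²   (4 nearest O neighbors)

(q = 1 for a perfect tetrahedral site, ensemble mean 0 for isotropically
random neighbors), and the translational order parameter

    t = (1/s_c) ∫₀^{s_c} |g(s) − 1| ds,   s = ρ^{1/3} r,  s_c = 2.843

which vanishes for an ideal gas and grows with pair-structure modulation.
An optional normalization constant maps a broadened fcc reference to t = 1
(off by default; recorded in metadata when used).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import (CageDefinition, Frame, Topology, Trajectory,
                         assign_regions, minimum_image, pair_distances,
                         water_oxygen_positions)

__all__ = [
    "RadialDistribution",
    "OrderParams",
    "radial_distribution",
    "coordination_number",
    "tetrahedral_order",
    "translational_order",
]

#: reduced-distance cutoff of the translational order integral
T_CUTOFF_REDUCED = 2.843


@dataclass
class RadialDistribution:
    r: np.ndarray            # bin centers, A
    g: np.ndarray
    density: float           # molecules/A^3 used in normalization
    region_pair: tuple[str, str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")


@dataclass
class OrderParams:
    q_values: np.ndarray
    q_mean: float
    t: float | None = None
    region: str | None = None


def _frame_oxygens(frame: Frame, topo: Topology,
                   region: str | None, cage: CageDefinition | None) -> np.ndarray:
    pos = water_oxygen_positions(frame, topo)
    if region is None:
        return pos
    if cage is None:
        raise ValueError("region selection needs a CageDefinition")
    labels = assign_regions(frame, topo, cage)
    return pos[labels == region]


def radial_distribution(traj: Trajectory, topo: Topology,
                        region_pair: tuple[str, str] | None = None,
                        r_max: float = 8.0, bin_width: float = 0.05,
                        density: float | None = None,
                        cage: CageDefinition | None = None) -> RadialDistribution:
    """Oxygen–oxygen g(r), optionally restricted to a region pair.

    The histogram of ordered O(a)→O(b) distances is normalized per frame by
    N_a · ρ_b · V_shell with ρ_b the partner-region density. When ``density``
    is not given it is estimated per frame: (N_b − δ_ab)/V_box for periodic
    frames, or N_cage/V_cage for the finite cage cluster (the local-density
    convention, recorded in metadata because it sets absolute peak heights).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centers = 0.5 * (edges[1:] + edges[:-1])
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    hist_norm = np.zeros(len(centers))
    densities_used = []
    reg_a, reg_b = region_pair if region_pair is not None else (None, None)
    same_region = reg_a == reg_b
    for frame in traj:
        if frame.box is not None and r_max > frame.box.min() / 2.0:
            raise ValueError("r_max exceeds half the smallest box edge")
        pos_a = _frame_oxygens(frame, topo, reg_a, cage)
        pos_b = pos_a if same_region else _frame_oxygens(frame, topo, reg_b, cage)
        n_a, n_b = len(pos_a), len(pos_b)
        if n_a == 0 or n_b == 0:
            continue
        d = pair_distances(pos_a, pos_b, frame.box)
        if same_region:
            np.fill_diagonal(d, np.inf)
        counts, _ = np.histogram(d.ravel(), bins=edges)
        if density is not None:
            rho = density
        elif reg_b == "cage" and cage is not None:
            rho = n_b / cage.volume
        elif frame.box is not None:
            rho = (n_b - (1 if same_region else 0)) / float(np.prod(frame.box))
        else:
            raise ValueError("density required for aperiodic, region-free g(r)")
        densities_used.append(rho)
        hist_norm += counts / (n_a * rho * shell_vol)
    if not densities_used:
        raise ValueError("no frame contributed any pair")
    g = hist_norm / len(traj.frames)
    rho_mean = float(np.mean(densities_used))
    return RadialDistribution(
        r=centers, g=g, density=rho_mean, region_pair=region_pair,
        metadata={"bin_width": bin_width, "r_max": r_max,
                  "density_convention": "given" if density is not None
                  else ("local_cage" if reg_b == "cage" else "box")})


def coordination_number(rdf: RadialDistribution, r_cut: float,
                        density: float | None = None) -> float:
    """Mean neighbor count 4πρ ∫₀^{r_cut} g(r) r² dr (trapezoidal)."""
    if r_cut < 0 or r_cut > rdf.r[-1]:
        raise ValueError("r_cut outside the g(r) grid")
    rho = rdf.density if density is None else density
    mask = rdf.r <= r_cut
    g_end = float(np.interp(r_cut, rdf.r, rdf.g))
    r = np.concatenate([[0.0], rdf.r[mask], [r_cut]])
    integrand = np.concatenate([[0.0], rdf.g[mask] * rdf.r[mask] ** 2,
                                [g_end * r_cut**2]])
    return float(4.0 * np.pi * rho * np.trapezoid(integrand, r))


def tetrahedral_order(frame: Frame, topo: Topology,
                      selection: np.ndarray | None = None,
                      region: str | None = None,
                      cage: CageDefinition | None = None) -> OrderParams:
    """Per-molecule tetrahedral order q over the 4 nearest oxygen neighbors.

    Neighbors are taken from *all* water oxygens regardless of region
    (standard convention, so cage-edge molecules may have exterior
    neighbors). Molecules with fewer than 4 available neighbors get NaN.
    """
    all_pos = water_oxygen_positions(frame, topo)
    if region is not None:
        if cage is None:
            raise ValueError("region selection needs a CageDefinition")
        sel_mask = assign_regions(frame, topo, cage) == region
        sel_idx = np.nonzero(sel_mask)[0]
    elif selection is not None:
        sel_idx = np.asarray(selection, dtype=int)
    else:
        sel_idx = np.arange(len(all_pos))
    q = np.full(len(sel_idx), np.nan)
    for k, i in enumerate(sel_idx):
        dvec = minimum_image(all_pos - all_pos[i], frame.box)
        dist = np.linalg.norm(dvec, axis=1)
        dist[i] = np.inf
        if np.sum(np.isfinite(dist)) < 4:
            continue
        nn = np.argsort(dist)[:4]
        units = dvec[nn] / dist[nn, None]
        s = 0.0
        for a in range(3):
            for b in range(a + 1, 4):
                cosang = float(np.dot(units[a], units[b]))
                s += (cosang + 1.0 / 3.0) ** 2
        q[k] = 1.0 - 3.0 / 8.0 * s
    valid = q[np.isfinite(q)]
    return OrderParams(q_values=q,
                       q_mean=float(valid.mean()) if valid.size else float("nan"),
                       region=region)


def translational_order(rdf: RadialDistribution, density: float | None = None,
                        s_cut: float = T_CUTOFF_REDUCED,
                        normalization: float | None = None) -> float:
    """Translational order t = (1/s_c) ∫₀^{s_c} |g(s) − 1| ds, s = ρ^{1/3} r.

    Exactly 0 for g ≡ 1. ``normalization`` (if given) divides the result so
    a chosen reference crystal maps to 1.
    """
    rho = rdf.density if density is None else density
    s = rho ** (1.0 / 3.0) * rdf.r
    if s[-1] < s_cut:
        raise ValueError(
            f"g(r) grid reaches s = {s[-1]:.3f} < cutoff {s_cut}; extend r_max")
    mask = s <= s_cut
    integrand = np.abs(rdf.g - 1.0)
    # constant extension below the first bin (no assumption about g(0))
    s_in = np.concatenate([[0.0], s[mask], [s_cut]])
    f_in = np.concatenate([[integrand[0]], integrand[mask],
                           [np.interp(s_cut, s, integrand)]])
    t = float(np.trapezoid(f_in, s_in) / s_cut)
    if normalization is not None:
        t /= normalization
    return t
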