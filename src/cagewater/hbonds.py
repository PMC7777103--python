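"""Hydrogen-bond detection and dynamics, orientational relaxation, residence.

The intermittent HB autocorrelation

    C_HB(t) = <h(t) h(0)> / <h(0)^2>,   h = 1 while a given HB is intact

allows a bond to break and re-form (no absorbing state), so its decay time
is the HB lifetime in the loose sense used for THz band analysis. The
orientational correlator

    C_mu2(t) = <P2[mu(t) . mu(0)]>,     P2(x) = (3x^2 - 1)/2

uses the unit water dipole (O->H-midpoint bisector). Both start at 1 by
construction.

Default geometric HB criterion: r_OO <= 3.5 A and O-H...O deviation <= 30
degrees (the standard liquid-water definition); fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .trajectory import (CageDefinition, Frame, Topology, Trajectory,
                         assign_regions, minimum_image)

__all__ = [
    "HBCriteria",
    "HBond",
    "CorrelationSeries",
    "RelaxationEstimate",
    "ResidenceRecord",
    "detect_hbonds",
    "hb_indicator_series",
    "hb_autocorrelation",
    "water_dipoles",
    "orientational_correlation",
    "orientational_correlation_from_vectors",
    "extract_relaxation_time",
    "residence_analysis",
    "hbonds_per_molecule",
]


@dataclass(frozen=True)
class HBCriteria:
    r_max: float = 3.5      # max O...O distance, A
    angle_max: float = 30.0  # max O-H...O deviation from linear, degrees


@dataclass(frozen=True)
class HBond:
    donor_O: int
    H: int
    acceptor_O: int
    r_OO: float
    angle: float


@dataclass
class CorrelationSeries:
    """Correlation values on a uniform lag grid starting at 0."""

    lags: np.ndarray
    values: np.ndarray
    relaxation_time: float | None = None
    method: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags[0] != 0.0:
            raise ValueError("lag grid must start at 0")
        if len(self.lags) > 1 and np.max(np.abs(
                np.diff(self.lags) - (self.lags[1] - self.lags[0]))) > 1e-9:
            raise ValueError("lag grid must be uniform")
        if abs(self.values[0] - 1.0) > 1e-9:
            raise ValueError("correlation must be normalized to 1 at lag 0")


@dataclass
class RelaxationEstimate:
    """Extracted relaxation time; ``ok=False`` flags failure (no fallback)."""

    time: float
    ok: bool
    method: str
    message: str = ""
    plateau: float = 0.0


@dataclass
class ResidenceRecord:
    water: int
    region: str
    intervals: list[tuple[float, float]]
    total_residence: float
    max_residence: float
    classification: str  # arrested | fast


# ---------------------------------------------------------------------------
# detection

def detect_hbonds(frame: Frame, topo: Topology,
                  criteria: HBCriteria = HBCriteria()) -> list[HBond]:
    """All water-water donor/acceptor pairs satisfying the geometric criterion.

    A bond (donor_O, H, acceptor_O) exists when r_OO <= r_max and the angle
    between the O_d->H bond vector and the O_d->O_a axis is <= angle_max.
    Each triple is listed at most once.
    """
    triplets = topo.water_triplets
    if not triplets:
        raise ValueError("topology defines no water triplets with hydrogens")
    o_idx = np.array([t[0] for t in triplets])
    opos = frame.positions[o_idx]
    box = frame.box
    d = minimum_image(opos[:, None, :] - opos[None, :, :], box)
    r = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(r, np.inf)
    bonds: list[HBond] = []
    cos_max = np.cos(np.deg2rad(criteria.angle_max))
    donors, acceptors = np.nonzero(r <= criteria.r_max)
    for di, ai in zip(donors, acceptors):
        o_d, h1, h2 = triplets[di]
        o_a = triplets[ai][0]
        oa_vec = minimum_image(frame.positions[o_a] - frame.positions[o_d], box)
        oa_unit = oa_vec / np.linalg.norm(oa_vec)
        for h in (h1, h2):
            oh = minimum_image(frame.positions[h] - frame.positions[o_d], box)
            cosang = float(np.dot(oh, oa_unit) / np.linalg.norm(oh))
            if cosang >= cos_max:
                bonds.append(HBond(donor_O=int(o_d), H=int(h), acceptor_O=int(o_a),
                                   r_OO=float(r[di, ai]),
                                   angle=float(np.degrees(np.arccos(
                                       np.clip(cosang, -1, 1))))))
    return bonds


def hb_indicator_series(traj: Trajectory, topo: Topology,
                        criteria: HBCriteria = HBCriteria()
                        ) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Indicator h(t) for every (donor_O, H, acceptor_O) triple ever bonded.

    Returns (h of shape (n_bonds, n_frames), ordered bond identity list).
    """
    per_frame = [
        {(b.donor_O, b.H, b.acceptor_O) for b in detect_hbonds(f, topo, criteria)}
        for f in traj
    ]
    identities = sorted(set().union(*per_frame))
    h = np.zeros((len(identities), len(traj.frames)), dtype=np.int8)
    index = {ident: i for i, ident in enumerate(identities)}
    for t, bonds in enumerate(per_frame):
        for ident in bonds:
            h[index[ident], t] = 1
    return h, identities


# ---------------------------------------------------------------------------
# correlators

def _acf_fft(x: np.ndarray, max_lag_steps: int) -> np.ndarray:
    """Mean over series/origins of x(t0)x(t0+lag) via FFT, lags 0..max_lag."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n_series, n_t = x.shape
    nfft = 1 << int(np.ceil(np.log2(2 * n_t)))
    f = np.fft.rfft(x, nfft, axis=1)
    raw = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, : max_lag_steps + 1]
    counts = n_t - np.arange(max_lag_steps + 1)
    return raw.sum(axis=0) / (counts * n_series)


def hb_autocorrelation(h: np.ndarray, dt: float,
                       max_lag: float | None = None,
                       continuous: bool = False) -> CorrelationSeries:
    """Intermittent HB correlator C(t) = <h(t)h(0)> / <h(0)^2>.

    ``h`` is an (n_bonds, n_steps) indicator array sampled every ``dt`` ps.
    With ``continuous=True`` a bond is considered dead after its first
    breaking event (history rewritten per origin is approximated by zeroing
    h after the first 1->0 transition), a stricter lifetime variant that is
    not the default.
    """
    h = np.atleast_2d(np.asarray(h, dtype=float))
    n_t = h.shape[1]
    if max_lag is None:
        max_lag = (n_t - 1) * dt / 2.0
    max_steps = int(round(max_lag / dt))
    if max_steps > n_t - 1:
        raise ValueError("max_lag exceeds the series duration")
    if continuous:
        h = h.copy()
        for row in h:
            ones = np.nonzero(row)[0]
            if ones.size:
                breaks = np.nonzero(np.diff(row) == -1)[0]
                if breaks.size:
                    row[breaks[0] + 1:] = 0.0
    norm = float(np.mean(h * h))
    if norm == 0.0:
        raise ValueError("no bond is ever intact: correlator undefined")
    values = _acf_fft(h, max_steps) / norm
    lags = np.arange(max_steps + 1) * dt
    values[0] = 1.0  # guard against round-off
    return CorrelationSeries(lags=lags, values=values,
                             metadata={"kind": "hb_intermittent"
                                       if not continuous else "hb_continuous"})


def water_dipoles(frame: Frame, topo: Topology) -> np.ndarray:
    """Unit dipole direction per water: O through the midpoint of the two H."""
    out = np.empty((len(topo.water_triplets), 3))
    for i, (o, h1, h2) in enumerate(topo.water_triplets):
        mid = 0.5 * (frame.positions[h1] + frame.positions[h2])
        v = mid - frame.positions[o]
        out[i] = v / np.linalg.norm(v)
    return out


def orientational_correlation_from_vectors(vectors: np.ndarray, dt: float,
                                           max_lag: float | None = None
                                           ) -> CorrelationSeries:
    """C_mu2(t) from an (n_mol, n_steps, 3) array of unit dipoles.

    Uses <(u(0).u(t))^2> = sum_ab <q_ab(0) q_ab(t)> with q_ab = u_a u_b,
    computed by FFT, then P2. Exact and O(n log n).
    """
    vectors = np.asarray(vectors, dtype=float)
    n_mol, n_t, _ = vectors.shape
    if n_t < 2:
        raise ValueError("need at least 2 frames")
    if max_lag is None:
        max_lag = (n_t - 1) * dt / 2.0
    max_steps = int(round(max_lag / dt))
    if max_steps > n_t - 1:
        raise ValueError("max_lag exceeds the series duration")
    # 9 outer-product component series per molecule
    q = np.einsum("mta,mtb->mtab", vectors, vectors).reshape(n_mol, n_t, 9)
    q = np.moveaxis(q, 1, 2).reshape(n_mol * 9, n_t)
    dot_sq = _acf_fft(q, max_steps) * 9.0  # undo the per-series averaging over components
    values = 0.5 * (3.0 * dot_sq - 1.0)
    values[0] = 1.0
    lags = np.arange(max_steps + 1) * dt
    return CorrelationSeries(lags=lags, values=values,
                             metadata={"kind": "orientational_l2"})


def orientational_correlation(traj: Trajectory, topo: Topology,
                              region_filter: str | None = None,
                              cage: CageDefinition | None = None,
                              max_lag: float | None = None) -> CorrelationSeries:
    """C_mu2(t) for waters of a trajectory, optionally restricted by region.

    Region membership is evaluated at each time origin; a water contributes
    to the origin average iff it is in ``region_filter`` then, and is not
    dropped if it later changes region.
    """
    if len(traj.frames) < 2:
        raise ValueError("need at least 2 frames")
    dt = traj.timestep
    dips = np.stack([water_dipoles(f, topo) for f in traj], axis=1)  # (n_w, n_t, 3)
    n_w, n_t, _ = dips.shape
    if max_lag is None:
        max_lag = (n_t - 1) * dt / 2.0
    max_steps = int(round(max_lag / dt))
    if region_filter is None:
        return orientational_correlation_from_vectors(dips, dt, max_lag)
    if cage is None:
        raise ValueError("region filtering needs a CageDefinition")
    member = np.stack([assign_regions(f, topo, cage) == region_filter
                       for f in traj], axis=1)  # (n_w, n_t)
    values = np.empty(max_steps + 1)
    for lag in range(max_steps + 1):
        u0 = dips[:, : n_t - lag]
        ut = dips[:, lag:]
        m = member[:, : n_t - lag]
        if not np.any(m):
            raise ValueError(f"no water ever in region {region_filter!r}")
        dots = np.sum(u0 * ut, axis=-1)
        p2 = 0.5 * (3.0 * dots**2 - 1.0)
        values[lag] = p2[m].mean()
    values = values / values[0]
    lags = np.arange(max_steps + 1) * dt
    return CorrelationSeries(lags=lags, values=values,
                             metadata={"kind": "orientational_l2",
                                       "region": region_filter})


# ---------------------------------------------------------------------------
# relaxation times

def extract_relaxation_time(series: CorrelationSeries, method: str = "one_over_e",
                            plateau: float | str | None = None
                            ) -> RelaxationEstimate:
    """Characteristic relaxation time of a correlation series.

    ``one_over_e``: linear interpolation of the first crossing of 1/e, after
    optional plateau subtraction (``plateau`` may be a number or ``"tail"``
    for the mean of the last 20% of lags). ``exp_fit``: time constant of a
    least-squares A*exp(-t/tau) + C fit. Failures are flagged in the result,
    never silently replaced.
    """
    lags, values = series.lags, series.values
    if method == "one_over_e":
        p = 0.0
        if plateau == "tail":
            p = float(values[int(0.8 * len(values)):].mean())
        elif plateau is not None:
            p = float(plateau)
        norm = (values - p) / (values[0] - p)
        target = np.exp(-1.0)
        below = np.nonzero(norm <= target)[0]
        if below.size == 0:
            return RelaxationEstimate(time=float("nan"), ok=False,
                                      method=method, plateau=p,
                                      message="no 1/e crossing in lag window")
        j = below[0]
        if j == 0:
            return RelaxationEstimate(time=0.0, ok=True, method=method, plateau=p)
        t = lags[j - 1] + (lags[j] - lags[j - 1]) * \
            (norm[j - 1] - target) / (norm[j - 1] - norm[j])
        series.relaxation_time = float(t)
        series.method = method
        return RelaxationEstimate(time=float(t), ok=True, method=method, plateau=p)
    if method == "exp_fit":
        def model(t, a, tau, c):
            return a * np.exp(-t / tau) + c

        try:
            span = lags[-1] if lags[-1] > 0 else 1.0
            popt, _ = curve_fit(model, lags, values,
                                p0=(values[0] - values[-1], span / 5.0,
                                    values[-1]),
                                maxfev=10000)
        except RuntimeError as exc:
            return RelaxationEstimate(time=float("nan"), ok=False, method=method,
                                      message=f"fit did not converge: {exc}")
        tau = float(popt[1])
        series.relaxation_time = tau
        series.method = method
        return RelaxationEstimate(time=tau, ok=True, method=method,
                                  plateau=float(popt[2]))
    raise ValueError("method must be 'one_over_e' or 'exp_fit'")


# ---------------------------------------------------------------------------
# residence analysis

def residence_analysis(traj: Trajectory, topo: Topology, cage: CageDefinition,
                       threshold: float = 10.0, tolerance_gap: float = 0.5
                       ) -> tuple[list[ResidenceRecord], int]:
    """Classify cage waters as arrested or fast from in-cage residence spans.

    Per water, maximal in-cage intervals are built after merging exits
    shorter than ``tolerance_gap`` ps; a water whose longest interval is at
    least ``threshold`` ps is *arrested*, any other water that ever visits
    the cage is *fast*. Returns (records, arrested count).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    dt = traj.timestep
    in_cage = np.stack([assign_regions(f, topo, cage) == "cage"
                        for f in traj], axis=1)  # (n_w, n_t)
    gap_steps = int(round(tolerance_gap / dt))
    records: list[ResidenceRecord] = []
    arrested = 0
    times = np.array([f.time for f in traj])
    for w in range(in_cage.shape[0]):
        series = in_cage[w].astype(int)
        if not series.any():
            continue
        # merge short exits
        padded = np.concatenate([[0], series, [0]])
        starts = np.nonzero(np.diff(padded) == 1)[0]
        ends = np.nonzero(np.diff(padded) == -1)[0]  # exclusive
        merged: list[list[int]] = []
        for s, e in zip(starts, ends):
            if merged and s - merged[-1][1] <= gap_steps:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        intervals = [(float(times[s]), float(times[e - 1])) for s, e in merged]
        durations = [b - a for a, b in intervals]
        max_res = max(durations)
        cls = "arrested" if max_res >= threshold else "fast"
        if cls == "arrested":
            arrested += 1
        records.append(ResidenceRecord(
            water=w, region="cage", intervals=intervals,
            total_residence=float(sum(durations)),
            max_residence=float(max_res), classification=cls))
    return records, arrested


def hbonds_per_molecule(traj: Trajectory, topo: Topology,
                        region_filter: str | None = None,
                        cage: CageDefinition | None = None,
                        criteria: HBCriteria = HBCriteria()) -> float:
    """Time-averaged HBs (donated + accepted) per water in a region."""
    o_to_water = {t[0]: i for i, t in enumerate(topo.water_triplets)}
    totals, n_obs = 0.0, 0
    for f in traj:
        counts = np.zeros(len(topo.water_triplets))
        for b in detect_hbonds(f, topo, criteria):
            counts[o_to_water[b.donor_O]] += 1
            counts[o_to_water[b.acceptor_O]] += 1
        if region_filter is None:
            sel = np.ones(len(counts), dtype=bool)
        else:
            if cage is None:
                raise ValueError("region filtering needs a CageDefinition")
            sel = assign_regions(f, topo, cage) == region_filter
        totals += counts[sel].sum()
        n_obs += int(sel.sum())
    if n_obs == 0:
        raise ValueError(f"region {region_filter!r} empty over all frames")
    return totals / n_obs
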