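"""HB detection vs brute force, correlators vs closed forms, residence."""

import numpy as np
import pytest

from cagewater.hbonds import (CorrelationSeries, HBCriteria, detect_hbonds,
                              extract_relaxation_time, hb_autocorrelation,
                              hbonds_per_molecule, orientational_correlation,
                              orientational_correlation_from_vectors,
                              residence_analysis, water_dipoles)
from cagewater.synth import (make_confined_droplet, make_hb_markov,
                             make_rotational_diffusion)
from cagewater.trajectory import CageDefinition, Frame, Trajectory

from conftest import frame_from_waters, make_water, random_water_frame


def brute_force_hbonds(frame, topo, r_max=3.5, angle_max=30.0):
    """Independent all-pairs scan with explicit loops (oracle)."""
    found = set()
    trip = topo.water_triplets
    for d in range(len(trip)):
        for a in range(len(trip)):
            if d == a:
                continue
            o_d, h1, h2 = trip[d]
            o_a = trip[a][0]
            r = np.linalg.norm(frame.positions[o_a] - frame.positions[o_d])
            if r > r_max:
                continue
            for h in (h1, h2):
                oh = frame.positions[h] - frame.positions[o_d]
                oo = frame.positions[o_a] - frame.positions[o_d]
                cosang = np.dot(oh, oo) / (np.linalg.norm(oh) * np.linalg.norm(oo))
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if ang <= angle_max:
                    found.add((o_d, h, o_a))
    return found


class TestDetection:
    def test_linear_dimer_single_bond(self):
        donor = make_water([0, 0, 0], [1, 0, 0])
        # rotate donor so one O-H points exactly at the acceptor
        o = np.zeros(3)
        h1 = np.array([0.9572, 0.0, 0.0])          # points at acceptor
        h2 = o + 0.9572 * np.array([np.cos(np.deg2rad(104.52)),
                                    np.sin(np.deg2rad(104.52)), 0.0])
        acceptor = make_water([2.8, 0, 0], [1, 0.3, 0])
        frame, topo = frame_from_waters([(o, h1, h2), acceptor])
        bonds = detect_hbonds(frame, topo)
        assert len([b for b in bonds if b.donor_O == 0]) == 1
        b = [b for b in bonds if b.donor_O == 0][0]
        assert b.r_OO == pytest.approx(2.8)
        assert b.angle == pytest.approx(0.0, abs=1e-9)

    def test_distant_pair_no_bond(self):
        frame, topo = frame_from_waters([
            make_water([0, 0, 0], [1, 0, 0]),
            make_water([5.0, 0, 0], [-1, 0, 0])])
        assert detect_hbonds(frame, topo) == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, seed):
        frame, topo = random_water_frame(20, box=8.0, seed=seed)
        ours = {(b.donor_O, b.H, b.acceptor_O)
                for b in detect_hbonds(frame, topo)}
        assert ours == brute_force_hbonds(frame, topo)

    def test_missing_waters_errors(self):
        from cagewater.trajectory import Topology
        frame, _ = random_water_frame(2, seed=0)
        with pytest.raises(ValueError, match="water triplets"):
            detect_hbonds(frame, Topology())


class TestHBAutocorrelation:
    def test_always_intact_is_one(self):
        h = np.ones((5, 200))
        series = hb_autocorrelation(h, dt=0.1, max_lag=5.0)
        np.testing.assert_allclose(series.values, 1.0, atol=1e-12)

    def test_never_intact_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            hb_autocorrelation(np.zeros((3, 100)), dt=0.1, max_lag=2.0)

    def test_markov_matches_closed_form(self):
        kb, kf, duration = 0.5, 0.5, 100.0
        h, dt = make_hb_markov(n_bonds=1000, k_break=kb, k_form=kf,
                               duration=duration, dt=0.02, seed=13)
        series = hb_autocorrelation(h, dt, max_lag=10.0)
        p = kf / (kb + kf)
        closed = p + (1 - p) * np.exp(-(kb + kf) * series.lags)
        # standard error from block scatter over bond groups
        groups = np.array_split(np.arange(h.shape[0]), 10)
        per_group = np.stack([
            hb_autocorrelation(h[g], dt, max_lag=10.0).values for g in groups])
        se = per_group.std(axis=0, ddof=1) / np.sqrt(len(groups))
        # the finite observation window biases the sample ACF downward by
        # O(2 p(1-p) tau / T); include that analytic term in the bound
        bias = 2.0 * p * (1 - p) / ((kb + kf) * duration)
        dev = np.abs(series.values - closed)[1:]
        assert np.all(dev <= 3 * se[1:] + bias)

    def test_lifetime_near_one_ps_in_bulk_regime(self):
        # total relaxation rate 1/ps mimics the bulk HB lifetime scale
        h, dt = make_hb_markov(n_bonds=300, k_break=0.5, k_form=0.5,
                               duration=50.0, dt=0.01, seed=2)
        series = hb_autocorrelation(h, dt, max_lag=25.0)
        tau = extract_relaxation_time(series, "one_over_e", plateau="tail")
        assert tau.ok
        assert tau.time == pytest.approx(1.0, rel=0.10)


class TestOrientational:
    def test_frozen_dipoles_constant(self):
        vecs = np.tile(np.array([0.0, 0.0, 1.0]), (4, 50, 1))
        series = orientational_correlation_from_vectors(vecs, dt=0.1)
        np.testing.assert_allclose(series.values, 1.0, atol=1e-12)

    def test_rotational_diffusion_closed_form(self):
        D = 0.1
        vecs, dt = make_rotational_diffusion(n_molecules=400, D_r=D,
                                             duration=20.0, dt=0.01, seed=8)
        series = orientational_correlation_from_vectors(vecs, dt, max_lag=5.0)
        closed = np.exp(-6.0 * D * series.lags)
        assert np.max(np.abs(series.values - closed)) < 0.05

    def test_uncorrelated_orientations_decay_to_zero(self):
        rng = np.random.default_rng(0)
        vecs = rng.normal(size=(200, 60, 3))
        vecs /= np.linalg.norm(vecs, axis=-1, keepdims=True)
        series = orientational_correlation_from_vectors(vecs, dt=1.0,
                                                        max_lag=20.0)
        assert np.max(np.abs(series.values[1:])) < 0.05

    def test_bounded_by_one(self):
        vecs, dt = make_rotational_diffusion(n_molecules=50, D_r=0.2,
                                             duration=10.0, dt=0.01, seed=1)
        series = orientational_correlation_from_vectors(vecs, dt)
        assert series.values[0] == 1.0
        assert np.all(np.abs(series.values) <= 1.0 + 1e-9)

    def test_region_filtered_correlator(self, droplet):
        traj, topo, cage = droplet
        series = orientational_correlation(traj, topo, region_filter="cage",
                                           cage=cage, max_lag=3.0)
        assert series.values[0] == pytest.approx(1.0)
        assert len(series.lags) == int(round(3.0 / traj.timestep)) + 1

    def test_too_few_frames(self):
        f = Frame(index=0, time=0.0, positions=np.zeros((3, 3)) + np.eye(3),
                  species=["O", "H", "H"])
        from cagewater.trajectory import Topology
        with pytest.raises(ValueError, match="2 frames"):
            orientational_correlation(Trajectory(frames=[f]),
                                      Topology(water_triplets=[(0, 1, 2)]))


class TestRelaxationExtraction:
    def test_exact_exponential_both_methods(self):
        lags = np.arange(0, 10, 0.05)
        series = CorrelationSeries(lags=lags, values=np.exp(-lags / 2.0))
        t1 = extract_relaxation_time(series, "one_over_e")
        t2 = extract_relaxation_time(series, "exp_fit")
        assert t1.time == pytest.approx(2.0, abs=1e-3)
        assert t2.time == pytest.approx(2.0, abs=1e-6)

    def test_plateau_exponential_exp_fit(self):
        lags = np.arange(0, 20, 0.05)
        series = CorrelationSeries(lags=lags,
                                   values=0.5 + 0.5 * np.exp(-lags))
        t = extract_relaxation_time(series, "exp_fit")
        assert t.time == pytest.approx(1.0, abs=1e-6)
        assert t.plateau == pytest.approx(0.5, abs=1e-6)

    def test_known_tau_ratio_recovered(self):
        taus = {}
        for name, d_r, seed in (("slow", 0.05, 3), ("fast", 0.125, 4)):
            vecs, dt = make_rotational_diffusion(n_molecules=300, D_r=d_r,
                                                 duration=40.0, dt=0.01,
                                                 seed=seed)
            c2 = orientational_correlation_from_vectors(vecs, dt, max_lag=20.0)
            taus[name] = extract_relaxation_time(c2, "one_over_e").time
        assert taus["slow"] / taus["fast"] == pytest.approx(2.5, rel=0.10)

    def test_no_crossing_flagged(self):
        lags = np.arange(0, 5, 0.1)
        series = CorrelationSeries(lags=lags,
                                   values=1.0 - 0.1 * lags / lags[-1])
        result = extract_relaxation_time(series, "one_over_e")
        assert not result.ok
        assert np.isnan(result.time)


class TestResidence:
    def _traj_with_pattern(self, pattern, dt=1.0):
        """One water whose O sits inside (0,0,0) or outside (20,0,0)."""
        frames = []
        for k, inside in enumerate(pattern):
            o = np.zeros(3) if inside else np.array([20.0, 0, 0])
            w = make_water(o, [0, 0, 1])
            frame, topo = frame_from_waters([w], time=k * dt)
            frame.index = k
            frame.time = k * dt
            frames.append(frame)
        return Trajectory(frames=frames), topo

    def test_permanent_resident_is_arrested(self):
        traj, topo = self._traj_with_pattern([True] * 30)
        cage = CageDefinition(cage_radius=4.0, center=np.zeros(3))
        records, arrested = residence_analysis(traj, topo, cage,
                                               threshold=10.0,
                                               tolerance_gap=0.5)
        assert arrested == 1
        assert records[0].classification == "arrested"

    def test_single_frame_visit_is_fast(self):
        traj, topo = self._traj_with_pattern(
            [False] * 10 + [True] + [False] * 10)
        cage = CageDefinition(cage_radius=4.0, center=np.zeros(3))
        records, arrested = residence_analysis(traj, topo, cage,
                                               threshold=10.0,
                                               tolerance_gap=0.5)
        assert arrested == 0
        assert records[0].classification == "fast"

    def test_short_exit_is_merged(self):
        pattern = [True] * 10 + [False] + [True] * 10
        traj, topo = self._traj_with_pattern(pattern)
        cage = CageDefinition(cage_radius=4.0, center=np.zeros(3))
        records, arrested = residence_analysis(traj, topo, cage,
                                               threshold=15.0,
                                               tolerance_gap=2.0)
        assert arrested == 1

    def test_droplet_arrested_count(self, droplet):
        traj, topo, cage = droplet
        _, arrested = residence_analysis(traj, topo, cage, threshold=5.0,
                                         tolerance_gap=0.5)
        assert arrested == 9

    def test_threshold_validation(self, droplet):
        traj, topo, cage = droplet
        with pytest.raises(ValueError):
            residence_analysis(traj, topo, cage, threshold=0.0)


class TestHBsPerMolecule:
    def test_isolated_water_zero(self):
        frame, topo = frame_from_waters([make_water([0, 0, 0], [0, 0, 1])])
        traj = Trajectory(frames=[frame])
        assert hbonds_per_molecule(traj, topo) == 0.0

    def test_perfect_four_coordination(self):
        # central water donating to 2 neighbors and accepting from 2 others,
        # all at ideal tetrahedral directions
        d = 2.8
        dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                        float)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        center_o = np.zeros(3)
        # donate along dirs[0], dirs[1]
        c_h1 = center_o + 0.9572 * dirs[0]
        c_h2 = center_o + 0.9572 * dirs[1]
        waters = [(center_o, c_h1, c_h2)]
        for k in (0, 1):  # acceptors
            waters.append(make_water(d * dirs[k], dirs[k]))
        for k in (2, 3):  # donors pointing one H back at the center
            o = d * dirs[k]
            h1 = o - 0.9572 * dirs[k]
            h2 = o + 0.9572 * np.array([0.0, 0.0, 1.0])
            waters.append((o, h1, h2))
        frame, topo = frame_from_waters(waters)
        traj = Trajectory(frames=[frame])
        bonds = [b for b in
                 __import__("cagewater.hbonds", fromlist=["detect_hbonds"])
                 .detect_hbonds(frame, topo) if 0 in (b.donor_O, b.acceptor_O)]
        assert len(bonds) == 4

    def test_droplet_undercoordinated_vs_lattice(self, droplet):
        traj, topo, cage = droplet
        per_mol = hbonds_per_molecule(
            Trajectory(frames=traj.frames[:20]), topo,
            region_filter="cage", cage=cage)
        assert per_mol < 4.0  # far below a fully bonded network

    def test_empty_region_flagged(self, droplet):
        traj, topo, cage = droplet
        tiny = CageDefinition(cage_radius=0.01, hydration_cutoff=0.01,
                              center=np.array([500.0, 0, 0]))
        with pytest.raises(ValueError, match="empty"):
            hbonds_per_molecule(Trajectory(frames=traj.frames[:3]), topo,
                                region_filter="cage", cage=tiny)
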