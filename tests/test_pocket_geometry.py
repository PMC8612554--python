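import numpy as np
import pytest

from aptamd import synthetic_data as syn
from aptamd.model_io import ReferenceSite, Segment, Topology, Trajectory
from aptamd.pocket_geometry import (
    CVTrace,
    DistanceDefinition,
    cv_density_map,
    cv_trace,
    distance_series,
    grid_density,
    pocket_frame,
    site_occupancy,
    theta_angle,
)
from conftest import random_rotation


class TestDistanceSeries:
    def test_static_pair(self, toy):
        traj = toy.reference_trajectory()
        d = DistanceDefinition("d_15-30", (15, "C1'"), (30, "C1'"))
        s = distance_series(traj, d)
        assert s.mean == pytest.approx(toy.spec.door_back_width, abs=1e-9)
        assert s.sd == 0.0

    def test_construction_parameter_exact(self):
        toy = syn.build_toy_complex(syn.ToyPocketSpec(door_back_width=11.2))
        s = distance_series(
            toy.reference_trajectory(), DistanceDefinition("d_15-30", (15, "C1'"), (30, "C1'"))
        )
        assert np.allclose(s.values, 11.2)

    def test_unresolvable_atom_named(self, toy):
        with pytest.raises(KeyError, match="99"):
            distance_series(
                toy.reference_trajectory(),
                DistanceDefinition("bad", (99, "C1'"), (30, "C1'")),
            )

    def test_noise_sd_matches_monte_carlo(self, toy, rng):
        """SD of a noisy distance agrees with a direct Monte-Carlo estimate."""
        sd = 0.5
        n = 4000
        a0 = np.array([0.0, 0.0, 0.0])
        b0 = np.array([7.8, 0.0, 0.0])
        # package path: noisy trajectory of two atoms
        from aptamd.model_io import AtomRecord

        top = Topology(
            [
                AtomRecord(1, "X1", "LIG", 1, Segment.LIGAND, "C"),
                AtomRecord(2, "X2", "LIG", 2, Segment.LIGAND, "C"),
            ]
        )
        coords = np.stack([a0, b0])[None] + rng.normal(scale=sd, size=(n, 2, 3))
        s = distance_series(
            Trajectory(top, coords), DistanceDefinition("d", (1, "X1"), (2, "X2"))
        )
        # independent Monte-Carlo oracle with its own draws
        da = a0 + rng.normal(scale=sd, size=(n, 3))
        db = b0 + rng.normal(scale=sd, size=(n, 3))
        oracle_sd = np.std(np.linalg.norm(da - db, axis=1), ddof=1)
        assert s.sd == pytest.approx(oracle_sd, rel=0.05)

    def test_histogram_unit_area(self, toy):
        traj, _ = syn.simulate_bound_trajectory(toy, n_frames=200, seed=5)
        s = distance_series(traj, DistanceDefinition("d_5-11", (5, "C1'"), (11, "C1'")))
        edges, dens = s.histogram()
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0, abs=1e-9)


class TestPocketFrame:
    def test_front_back_orientation(self, toy):
        pf = pocket_frame(toy.reference, toy.topology, toy.pocket_spec)
        top = toy.topology
        front_mid = toy.reference[top.atom_indices([(5, "C1'"), (11, "C1'")])].mean(axis=0)
        back_mid = toy.reference[top.atom_indices([(15, "C1'"), (30, "C1'")])].mean(axis=0)
        assert (front_mid - pf.plane_origin) @ pf.normal > 0
        assert (back_mid - pf.plane_origin) @ pf.normal < 0

    def test_rigid_rotation_leaves_cv_unchanged(self, toy, rng):
        trace0 = cv_trace(toy.reference_trajectory(), toy.ligand_residue, toy.pocket_spec)
        for _ in range(5):
            R = random_rotation(rng)
            t = rng.normal(scale=20, size=3)
            moved = Trajectory(toy.topology, toy.reference[None] @ R.T + t)
            trace1 = cv_trace(moved, toy.ligand_residue, toy.pocket_spec)
            assert trace1.r[0] == pytest.approx(trace0.r[0], abs=1e-9)
            assert trace1.z[0] == pytest.approx(trace0.z[0], abs=1e-9)

    def test_colinear_plane_atoms_error(self, toy):
        coords = toy.reference.copy()
        top = toy.topology
        idx = top.atom_indices(toy.pocket_spec.plane_atoms)
        coords[idx] = np.outer(np.arange(3.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="colinear"):
            pocket_frame(coords, top, toy.pocket_spec)


class TestCVTrace:
    def test_metadynamics_embedding_roundtrip(self, toy):
        """2D toy (x, z) positions embedded in 3D and re-measured round-trip."""
        res = syn.simulate_wt_metadynamics(n_steps=2000, seed=9)
        pos = res.positions[::100]
        traj = syn.embed_trace(toy, pos)
        trace = cv_trace(traj, toy.ligand_residue, toy.pocket_spec)
        np.testing.assert_allclose(trace.r, np.linalg.norm(pos, axis=1), atol=1e-6)
        np.testing.assert_allclose(trace.z, pos[:, 1], atol=1e-6)

    def test_r_nonnegative_contract(self):
        with pytest.raises(ValueError, match="non-negative"):
            CVTrace(r=np.array([-1.0]), z=np.array([0.0]), times=np.array([0.0]))


def _base(center, normal_axis, topology_atoms, coords, res_idx, rng):
    from aptamd.model_io import AtomRecord

    ang = 2 * np.pi * np.arange(4) / 4
    ring = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(4)])
    if normal_axis == "x":
        ring = ring[:, [2, 0, 1]]
    elif normal_axis == "rand":
        ring = ring @ random_rotation(rng).T
    sel = []
    for i, xyz in enumerate(ring, start=1):
        serial = len(topology_atoms) + 1
        topology_atoms.append(
            AtomRecord(serial, f"B{i}", "A", res_idx, Segment.RNA, "C")
        )
        coords.append(np.asarray(center) + xyz)
        sel.append((res_idx, f"B{i}"))
    return sel


class TestTheta:
    def _build(self, axes1, axes2, rng):
        atoms, coords = [], []
        g1 = [
            _base((5 * k, 0, 0), ax, atoms, coords, 10 + k, rng)
            for k, ax in enumerate(axes1)
        ]
        g2 = [
            _base((5 * k, 8, 0), ax, atoms, coords, 20 + k, rng)
            for k, ax in enumerate(axes2)
        ]
        return Topology(atoms), np.array(coords), g1, g2

    def test_coplanar_zero(self, rng):
        top, coords, g1, g2 = self._build(["z"] * 3, ["z"] * 2, rng)
        assert theta_angle(coords, top, g1, g2) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_ninety(self, rng):
        top, coords, g1, g2 = self._build(["z"] * 3, ["x"] * 2, rng)
        assert theta_angle(coords, top, g1, g2) == pytest.approx(90.0, abs=1e-9)

    def test_matches_direct_pairwise_average(self, rng):
        from aptamd.stacking_hbonds import fit_plane

        top, coords, g1, g2 = self._build(["rand"] * 3, ["rand"] * 2, rng)
        theta = theta_angle(coords, top, g1, g2)
        # brute-force oracle: average acute angle over all 3x2 normal pairs
        def normal(sel):
            return fit_plane(coords[top.atom_indices(sel)]).normal

        angles = [
            np.degrees(np.arccos(np.clip(abs(normal(b1) @ normal(b2)), 0, 1)))
            for b1 in g1
            for b2 in g2
        ]
        assert theta == pytest.approx(np.mean(angles), abs=1e-9)


class TestCVDensityMap:
    def test_identical_frames_single_bin(self):
        x = np.full(100, 3.0)
        y = np.full(100, 27.5)
        hist, xe, ye, peak = cv_density_map(x, y, bins=10)
        assert (hist > 0).sum() == 1
        assert hist.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mixture_peak_near_heavier_mean(self, rng):
        n = 20000
        comp = rng.random(n) < 0.7
        x = np.where(comp, rng.normal(13.5, 0.4, n), rng.normal(16.0, 0.4, n))
        y = np.where(comp, rng.normal(27.5, 2.0, n), rng.normal(80.0, 2.0, n))
        hist, xe, ye, peak = cv_density_map(x, y, bins=40)
        assert abs(peak[0] - 13.5) <= (xe[1] - xe[0])
        assert abs(peak[1] - 27.5) <= (ye[1] - ye[0])

    def test_unit_mass(self, rng):
        hist, *_ = cv_density_map(rng.normal(size=500), rng.normal(size=500), bins=12)
        assert hist.sum() == pytest.approx(1.0, abs=1e-12)


class TestGridDensity:
    def _ion_traj(self, positions):
        from aptamd.model_io import AtomRecord

        top = Topology([AtomRecord(1, "MG", "MG", 101, Segment.ION, "MG")])
        return Trajectory(top, np.asarray(positions)[:, None, :])

    def test_static_ion_single_voxel(self):
        traj = self._ion_traj(np.tile([1.0, 2.0, 3.0], (50, 1)))
        dens = grid_density(traj, np.array([0]), spacing=0.5)
        assert (dens.counts > 0).sum() == 1
        assert dens.counts.max() == 50

    def test_conservation_with_overflow(self, rng):
        traj = self._ion_traj(rng.normal(scale=5.0, size=(200, 3)))
        dens = grid_density(
            traj, np.array([0]), spacing=0.5,
            origin=np.array([-2.0, -2.0, -2.0]), shape=(8, 8, 8),
        )
        assert dens.counts.sum() + dens.overflow == 200

    def test_smoothing_conserves_mass_lowers_peak(self, rng):
        traj = self._ion_traj(np.tile([0.0, 0.0, 0.0], (100, 1)))
        raw = grid_density(traj, np.array([0]), spacing=0.5)
        smooth = grid_density(traj, np.array([0]), spacing=0.5, smoothing_sd=1.0)
        assert smooth.counts.sum() == pytest.approx(raw.counts.sum(), abs=1e-9)
        assert smooth.counts.max() < raw.counts.max()


class TestSiteOccupancy:
    SITES = [ReferenceSite("M2", (10.0, 5.0, 0.0)), ReferenceSite("M3", (-8.0, 2.0, 4.0))]

    def test_full_occupancy(self):
        traj, _ = syn.simulate_ion_occupancy(
            self.SITES[:1], {"M2": 1.0}, n_frames=200, seed=0, noise_sd=0.3
        )
        occ = site_occupancy(traj, np.array([0]), self.SITES[:1], radius=2.0)
        assert occ.occupancy[0] == 1.0

    def test_distant_site_zero(self):
        traj, _ = syn.simulate_ion_occupancy(
            self.SITES[:1], {"M2": 1.0}, n_frames=100, seed=0
        )
        far = [ReferenceSite("far", (50.0, 50.0, 50.0))]
        occ = site_occupancy(traj, np.array([0]), far)
        assert occ.occupancy[0] == 0.0

    def test_recovery_and_peak_position(self):
        from scipy import stats

        p = 0.8
        traj, log = syn.simulate_ion_occupancy(
            self.SITES, {"M2": p, "M3": 0.1}, n_frames=5000, seed=2
        )
        occ = site_occupancy(traj, np.array([0]), self.SITES, radius=2.0, spacing=0.5)
        lo = stats.binom.ppf(0.005, 5000, p) / 5000
        hi = stats.binom.ppf(0.995, 5000, p) / 5000
        assert lo <= occ.occupancy[0] <= hi
        assert occ.nearest_peak_distance[0] < 0.5
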