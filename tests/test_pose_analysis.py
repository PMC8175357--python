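"""Contacts, RMSD clustering, energies, hot spots and rescoring."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from rigidbd.constants import COULOMB_KCAL
from rigidbd.io_formats import Structure, Trajectory
from rigidbd.pose_analysis import (
    body_frame_coords,
    cluster_poses,
    contact_frames,
    frame_coordinates,
    hotspot_density,
    interaction_energy,
    membrane_depth_profile,
    phospho_rescore,
    score_clusters,
    tilt_angle,
)
from conftest import random_body, single_atom

IDENT = np.array([1.0, 0.0, 0.0, 0.0])


def _traj(positions, quats=None, stride=0.2):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if quats is None:
        quats = np.tile(IDENT, (n, 1))
    return Trajectory(times=np.arange(n) * stride, positions=positions,
                      quaternions=np.asarray(quats))


class TestContacts:
    def test_distance_threshold(self):
        a = Structure([single_atom(position=(0, 0, 0))])
        near = _traj([[2.9, 0, 0], [3.1, 0, 0]])
        got = contact_frames(near, a, a, cutoff=3.0)
        np.testing.assert_array_equal(got, [0])

    def test_matches_brute_force_oracle(self, rng):
        mobile = random_body(40, seed=41, spread=6.0)
        stationary = random_body(60, seed=42, spread=8.0)
        positions = rng.uniform(-20, 20, (50, 3))
        quats = rng.standard_normal((50, 4))
        quats /= np.linalg.norm(quats, axis=1, keepdims=True)
        traj = _traj(positions, quats)
        got = set(contact_frames(traj, mobile, stationary, cutoff=3.0).tolist())
        body = body_frame_coords(mobile)
        expected = set()
        for i in range(len(traj)):
            world = frame_coordinates(traj, mobile, i)
            d = np.linalg.norm(world[:, None, :] - stationary.positions[None],
                               axis=2)
            if d.min() <= 3.0:
                expected.add(i)
        assert got == expected


class TestClustering:
    def test_identical_frames_single_cluster(self):
        coords = np.zeros((8, 5, 3))
        clusters = cluster_poses(coords, rmsd_cutoff=10.0)
        assert len(clusters) == 1
        assert clusters[0].population == 1.0
        assert clusters[0].member_frames.size == 8

    def test_two_separated_blobs(self, rng):
        base = rng.standard_normal((4, 3))
        frames = []
        labels = []
        for c, center in enumerate([np.zeros(3), np.array([40.0, 0, 0])]):
            for _ in range(10):
                frames.append(base + center + 0.5 * rng.standard_normal(3))
                labels.append(c)
        clusters = cluster_poses(np.array(frames), rmsd_cutoff=10.0)
        assert len(clusters) == 2
        for cl in clusters:
            assert len({labels[i] for i in cl.member_frames}) == 1

    def test_five_blobs_recover_generative_labels(self, rng):
        """Five pose blobs separated by >> the 10 A cutoff are recovered
        exactly (adjusted Rand index 1)."""
        base = rng.standard_normal((6, 3)) * 2.0
        centers = [np.array([50.0 * np.cos(a), 50.0 * np.sin(a), 0.0])
                   for a in np.linspace(0, 2 * np.pi, 5, endpoint=False)]
        frames, labels = [], []
        for c, center in enumerate(centers):
            for _ in range(12):
                frames.append(base + center + rng.standard_normal(3))
                labels.append(c)
        order = rng.permutation(len(frames))
        clusters = cluster_poses(np.array(frames)[order], rmsd_cutoff=10.0)
        assert len(clusters) == 5
        pred = np.empty(len(frames), dtype=int)
        for ci, cl in enumerate(clusters):
            pred[cl.member_frames] = ci
        assert adjusted_rand_score(np.array(labels)[order], pred) == 1.0

    def test_permutation_only_relabels(self, rng):
        frames = np.concatenate([
            rng.standard_normal((10, 4, 3)),
            rng.standard_normal((10, 4, 3)) + 100.0,
        ])
        a = cluster_poses(frames, 10.0)
        perm = rng.permutation(20)
        b = cluster_poses(frames[perm], 10.0, frame_indices=perm)
        sets_a = {frozenset(c.member_frames.tolist()) for c in a}
        sets_b = {frozenset(np.sort(c.member_frames).tolist()) for c in b}
        assert sets_a == sets_b

    def test_empty_input(self):
        assert cluster_poses(np.zeros((0, 3, 3)), 10.0) == []


class TestInteractionEnergy:
    def test_two_unit_charges_coulomb(self):
        a = Structure([single_atom(position=(0, 0, 0), charge=1.0, eps=0.1)])
        b = Structure([single_atom(position=(10.0, 0, 0), charge=1.0, eps=0.1)])
        elec, vdw = interaction_energy(b, a, dielectric=1.0, cutoff=20.0)
        assert elec == pytest.approx(COULOMB_KCAL / 10.0, rel=1e-9)
        r_ij, eps_ij = 4.0, 0.1
        s6 = (r_ij / 10.0) ** 6
        assert vdw == pytest.approx(eps_ij * (s6 ** 2 - 2 * s6), rel=1e-9)

    def test_charge_antisymmetry(self):
        a = Structure([single_atom(charge=1.0)])
        b = Structure([single_atom(position=(10.0, 0, 0), charge=-1.0)])
        c = Structure([single_atom(position=(10.0, 0, 0), charge=1.0)])
        e_attr, _ = interaction_energy(b, a, dielectric=1.0, cutoff=20.0)
        e_rep, _ = interaction_energy(c, a, dielectric=1.0, cutoff=20.0)
        assert e_attr == pytest.approx(-e_rep)

    def test_beyond_cutoff_zero(self):
        a = Structure([single_atom(charge=1.0)])
        b = Structure([single_atom(position=(30.0, 0, 0), charge=1.0)])
        assert interaction_energy(b, a, dielectric=1.0, cutoff=12.0) == (0.0, 0.0)

    def test_clash_rejected(self):
        a = Structure([single_atom(charge=1.0)])
        b = Structure([single_atom(position=(0.05, 0, 0), charge=1.0)])
        with pytest.raises(ValueError, match="clash"):
            interaction_energy(b, a, dielectric=1.0, cutoff=12.0)

    def test_representative_selection_most_favorable(self):
        stationary = Structure([single_atom(charge=1.0)])
        mobile = Structure([single_atom(charge=-1.0)])
        # frame 1 is closer, hence lower (more favourable) energy
        traj = _traj([[8.0, 0, 0], [5.0, 0, 0], [9.0, 0, 0]])
        clusters = cluster_poses(
            np.array([[[8.0, 0, 0]], [[5.0, 0, 0]], [[9.0, 0, 0]]]), 10.0)
        scored = score_clusters(clusters, traj, mobile, stationary,
                                dielectric=1.0, cutoff=20.0)
        assert scored[0].representative == 1
        assert scored[0].rep_energy[0] == pytest.approx(-COULOMB_KCAL / 5.0)


class TestHotspotDensity:
    def _probe(self):
        return Structure([single_atom()])

    def test_point_cloud_single_peak(self):
        traj = _traj(np.tile([7.0, -3.0, 0.0], (20, 1)))
        h = hotspot_density(traj, self._probe(), [0])
        assert h.integral == pytest.approx(1.0, abs=1e-6)
        assert h.mode() == pytest.approx((7.0, -3.0), abs=0.5)

    def test_two_blob_symmetry(self, rng):
        a = np.array([20.0, 0, 0]) + rng.standard_normal((100, 3))
        b = np.array([-20.0, 0, 0]) + rng.standard_normal((100, 3))
        traj = _traj(np.concatenate([a, b]))
        h = hotspot_density(traj, self._probe(), [0], resolution=0.5)
        mass_right = h.density[h.x >= 0, :].sum()
        mass_left = h.density[h.x < 0, :].sum()
        assert mass_right == pytest.approx(mass_left, rel=0.02)
        assert np.all(h.density >= 0)

    def test_integral_independent_of_bandwidth(self, rng):
        traj = _traj(rng.standard_normal((50, 3)) * 5)
        for bw in (0.5, 2.0, 8.0):
            h = hotspot_density(traj, self._probe(), [0], bandwidth=bw)
            assert h.integral == pytest.approx(1.0, abs=1e-6)


class TestPhosphoRescore:
    def _system(self):
        stationary = Structure([
            single_atom(position=(0, 0, 0), charge=0.0, serial=1,
                        residue_id=215),
            single_atom(position=(16.0, 0, 0), charge=-1.0, serial=2,
                        residue_id=1),
        ])
        mobile = Structure([single_atom(charge=1.0)])
        traj = _traj([[8.0, 0, 0]])
        clusters = cluster_poses(np.array([[[8.0, 0, 0]]]), 10.0)
        return stationary, mobile, traj, clusters

    def test_identity_modification_ratio_one(self):
        stationary, mobile, traj, clusters = self._system()
        ratios = phospho_rescore(clusters, traj, mobile, stationary, 215,
                                 {"A0": 0.0}, dielectric=1.0, cutoff=50.0)
        assert ratios[0] == 1.0

    def test_two_charge_construction_matches_hand_ratio(self):
        # probe +1e at x=8; site at origin goes 0 -> -2e; spectator -1e at
        # x=16 is 8 A on the probe's far side
        stationary, mobile, traj, clusters = self._system()
        ratios = phospho_rescore(clusters, traj, mobile, stationary, 215,
                                 {"A0": -2.0}, dielectric=1.0, cutoff=50.0)
        e_orig = COULOMB_KCAL * (-1.0) / 8.0
        e_mod = COULOMB_KCAL * ((-2.0) / 8.0 + (-1.0) / 8.0)
        assert ratios[0] == pytest.approx(e_orig / e_mod, rel=1e-9)

    def test_site_outside_cutoff_ratio_one(self):
        stationary, mobile, traj, clusters = self._system()
        ratios = phospho_rescore(clusters, traj, mobile, stationary, 215,
                                 {"A0": -2.0}, dielectric=1.0, cutoff=6.0)
        assert ratios[0] == 1.0

    def test_unknown_residue_rejected(self):
        stationary, mobile, traj, clusters = self._system()
        with pytest.raises(ValueError, match="999"):
            phospho_rescore(clusters, traj, mobile, stationary, 999, {})


class TestGeometryObservables:
    def test_tilt_angles(self):
        s = Structure([
            single_atom(position=(0, 0, -1.0), serial=1),
            single_atom(position=(0, 0, 1.0), serial=2),
        ])
        traj_up = _traj([[0, 0, 0]])
        assert tilt_angle(traj_up, s, [0], [1])[0] == pytest.approx(0.0, abs=1e-9)
        # rotate axis into the membrane plane: 90 degrees about y
        q90 = np.array([np.cos(np.pi / 4), 0.0, np.sin(np.pi / 4), 0.0])
        traj_flat = _traj([[0, 0, 0]], quats=[q90])
        assert tilt_angle(traj_flat, s, [0], [1])[0] == pytest.approx(90.0)
        q45 = np.array([np.cos(np.pi / 8), 0.0, np.sin(np.pi / 8), 0.0])
        traj_45 = _traj([[0, 0, 0]], quats=[q45])
        assert tilt_angle(traj_45, s, [0], [1])[0] == pytest.approx(45.0)

    def test_tilt_coincident_sets_rejected(self):
        s = Structure([single_atom(serial=1), single_atom(serial=2)])
        with pytest.raises(ValueError, match="coincide"):
            tilt_angle(_traj([[0, 0, 0]]), s, [0], [1])

    def test_depth_profile_statistics(self):
        s = Structure([single_atom()])
        traj = _traj([[0, 0, -5.0], [0, 0, -15.0], [0, 0, -5.0], [0, 0, -15.0]])
        out = membrane_depth_profile(traj, s, {"R1": [0]}, phosphorus_plane_z=0.0)
        mean, sd = out["R1"]
        assert mean == pytest.approx(-10.0)
        assert sd == pytest.approx(5.0)

    def test_depth_fixed_at_plane(self):
        s = Structure([single_atom()])
        traj = _traj([[0, 0, 3.0]] * 3, stride=0.1)
        out = membrane_depth_profile(traj, s, {"R1": [0]}, phosphorus_plane_z=3.0)
        assert out["R1"] == (0.0, 0.0)

    def test_empty_selection_rejected(self):
        s = Structure([single_atom()])
        with pytest.raises(ValueError, match="empty"):
            membrane_depth_profile(_traj([[0, 0, 0]]), s, {"R1": []}, 0.0)
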