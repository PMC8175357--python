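"""Propagator, grid forces/torques, diffusion models and determinism."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rigidbd.bd_engine import (
    BDParams,
    BDState,
    DiffusionModel,
    bd_step,
    build_density_set,
    build_map_set,
    grid_force_torque,
    quat_from_rotvec,
    quat_multiply,
    quat_rotate,
    rotation_matrix,
    run_bd,
    stokes_diffusion,
    total_energy,
)
from rigidbd.constants import KB_KCAL
from rigidbd.gridmaps import DensitySet, MapSet, frame_around, make_frame
from rigidbd.io_formats import GridMap, Structure
from conftest import random_body, single_atom


def _unit_quat(rng):
    q = rng.standard_normal(4)
    return q / np.linalg.norm(q)


class TestQuaternions:
    """Cross-checked against scipy's Rotation as an independent oracle."""

    def test_rotation_matrix_matches_scipy(self, rng):
        for _ in range(20):
            q = _unit_quat(rng)
            expected = Rotation.from_quat(q, scalar_first=True).as_matrix()
            np.testing.assert_allclose(rotation_matrix(q), expected, atol=1e-12)

    def test_multiply_matches_scipy(self, rng):
        for _ in range(20):
            q1, q2 = _unit_quat(rng), _unit_quat(rng)
            got = quat_multiply(q1, q2)
            expected = (Rotation.from_quat(q1, scalar_first=True)
                        * Rotation.from_quat(q2, scalar_first=True)
                        ).as_quat(scalar_first=True)
            sign = np.sign(got[0]) * np.sign(expected[0]) or 1.0
            np.testing.assert_allclose(got, sign * expected, atol=1e-12)

    def test_from_rotvec_matches_scipy(self, rng):
        for scale in (1e-14, 1e-6, 0.1, 2.0):
            phi = scale * rng.standard_normal(3)
            got = quat_from_rotvec(phi)
            expected = Rotation.from_rotvec(phi).as_quat(scalar_first=True)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_rotate_vectors(self, rng):
        q = _unit_quat(rng)
        v = rng.standard_normal((7, 3))
        expected = Rotation.from_quat(q, scalar_first=True).apply(v)
        np.testing.assert_allclose(quat_rotate(q, v), expected, atol=1e-12)


class TestStokesDiffusion:
    def test_reference_sphere(self):
        m = stokes_diffusion(radius=20.0, viscosity=0.6913, temperature=310.0)
        assert m.d_trans == pytest.approx(16.4, rel=0.01)

    def test_radius_scaling(self):
        m1 = stokes_diffusion(20.0, 0.6913, 310.0)
        m2 = stokes_diffusion(40.0, 0.6913, 310.0)
        assert m2.d_trans == pytest.approx(m1.d_trans / 2)
        assert m2.d_rot == pytest.approx(m1.d_rot / 8)

    def test_temperature_scaling(self):
        m1 = stokes_diffusion(20.0, 0.6913, 155.0)
        m2 = stokes_diffusion(20.0, 0.6913, 310.0)
        assert m2.d_trans == pytest.approx(2 * m1.d_trans)
        assert m2.d_rot == pytest.approx(2 * m1.d_rot)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            stokes_diffusion(-1.0)


class TestGridForceTorque:
    def _uniform_z_field(self, extent=10, e_mag=1.0):
        # V = -E z  => force on +1e is +E along z
        n = 2 * extent + 1
        zs = np.arange(-extent, extent + 1.0)
        vals = np.broadcast_to(-e_mag * zs, (n, n, n)).copy()
        return GridMap(origin=(-extent, -extent, -extent), spacing=1.0, values=vals)

    def _density_from(self, structure, spacing=1.0):
        return build_density_set(structure, spacing=spacing)

    def test_single_charge_in_uniform_field(self):
        s = Structure([single_atom(charge=1.0, eps=0.0)])
        dens = self._density_from(s)
        maps = MapSet(elec_potential=self._uniform_z_field(), lj_potential={})
        dens.lj_cells = {}
        f, t = grid_force_torque(dens, maps, np.zeros(3), np.array([1.0, 0, 0, 0]))
        np.testing.assert_allclose(f, [0, 0, 1.0], atol=1e-12)
        np.testing.assert_allclose(t, 0.0, atol=1e-12)

    def test_dipole_in_uniform_field(self):
        s = Structure([
            single_atom(position=(-1.0, 0, 0), charge=-1.0, serial=1, eps=0.0),
            single_atom(position=(1.0, 0, 0), charge=1.0, serial=2, eps=0.0),
        ])
        dens = self._density_from(s)
        dens.lj_cells = {}
        maps = MapSet(elec_potential=self._uniform_z_field(), lj_potential={})
        f, t = grid_force_torque(dens, maps, np.zeros(3), np.array([1.0, 0, 0, 0]))
        np.testing.assert_allclose(f, 0.0, atol=1e-12)
        # p x E with p = (2, 0, 0) and E = (0, 0, 1): torque along -y
        np.testing.assert_allclose(t, [0, -2.0, 0], atol=1e-12)

    def test_force_is_negative_gradient_of_energy(self, rng):
        stationary = random_body(10, seed=21, spread=4.0)
        mobile = random_body(8, seed=22, spread=3.0)
        frame = frame_around(stationary, spacing=1.0, margin=25.0)
        maps = build_map_set(stationary, frame, solvent_dielectric=1.0,
                             cutoff=80.0, cap=1e5, eps_scale=1.0)
        dens = build_density_set(mobile)
        h = 1e-5
        for _ in range(20):
            pos = rng.uniform(8, 14) * _rand_dir(rng)
            q = _unit_quat(rng)
            f, _t = grid_force_torque(dens, maps, pos, q)
            for ax in range(3):
                e = np.zeros(3)
                e[ax] = h
                de = (total_energy(dens, maps, None, pos + e, q)
                      - total_energy(dens, maps, None, pos - e, q)) / (2 * h)
                assert -de == pytest.approx(f[ax], rel=2e-4, abs=1e-7)

    def test_category_mismatch_rejected(self):
        s = Structure([single_atom(charge=1.0)])
        dens = build_density_set(s)
        maps = MapSet(elec_potential=self._uniform_z_field(), lj_potential={})
        with pytest.raises(ValueError, match="no matching LJ potential map"):
            grid_force_torque(dens, maps, np.zeros(3), np.array([1.0, 0, 0, 0]))


def _rand_dir(rng):
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


class TestBDStep:
    MODEL = DiffusionModel(d_trans=100.0, d_rot=1.0, temperature=310.0)

    def test_no_force_no_noise_is_stationary(self):
        s = BDState(position=np.ones(3), quaternion=[1.0, 0, 0, 0])
        s2 = bd_step(s, np.zeros(3), np.zeros(3), self.MODEL, 0.01, noise=False)
        np.testing.assert_array_equal(s2.position, s.position)
        np.testing.assert_array_equal(s2.quaternion, [1.0, 0, 0, 0])

    def test_deterministic_drift_velocity(self):
        f = np.array([0.0, 0.0, 3.0])
        dt = 0.01
        s = BDState(position=np.zeros(3), quaternion=[1.0, 0, 0, 0])
        s2 = bd_step(s, f, np.zeros(3), self.MODEL, dt, noise=False)
        expected = self.MODEL.d_trans / (KB_KCAL * 310.0) * f * dt
        np.testing.assert_allclose(s2.position, expected, rtol=1e-12)

    def test_noise_advances_rng_deterministically(self):
        s1 = BDState(position=np.zeros(3), quaternion=[1.0, 0, 0, 0],
                     rng=np.random.default_rng(4))
        s2 = BDState(position=np.zeros(3), quaternion=[1.0, 0, 0, 0],
                     rng=np.random.default_rng(4))
        a = bd_step(s1, np.zeros(3), np.zeros(3), self.MODEL, 0.01)
        b = bd_step(s2, np.zeros(3), np.zeros(3), self.MODEL, 0.01)
        np.testing.assert_array_equal(a.position, b.position)
        np.testing.assert_array_equal(a.quaternion, b.quaternion)

    def test_large_displacement_warns(self):
        s = BDState(position=np.zeros(3), quaternion=[1.0, 0, 0, 0])
        with pytest.warns(UserWarning, match="timestep too large"):
            bd_step(s, np.array([1e5, 0, 0]), np.zeros(3), self.MODEL, 0.01,
                    noise=False, max_displacement=2.0)


class TestRunBD:
    MODEL = DiffusionModel(d_trans=100.0, d_rot=1.0, temperature=310.0)

    def test_zero_field_noise_off_is_stationary(self):
        params = BDParams(duration=0.1, timestep=1000.0, output_stride=0.01, seed=1)
        pose0 = (np.array([5.0, 5.0, 5.0]), np.array([1.0, 0, 0, 0]))
        trajs = run_bd(None, None, None, self.MODEL, params, [pose0], noise=False)
        np.testing.assert_allclose(trajs[0].positions, 5.0)
        np.testing.assert_allclose(trajs[0].quaternions[:, 0], 1.0)

    def test_same_seed_bit_identical_different_seed_not(self, tmp_path):
        from rigidbd.io_formats import write_trajectory
        params = BDParams(duration=0.2, timestep=1000.0, output_stride=0.005, seed=7)
        pose0 = [(np.zeros(3), np.array([1.0, 0, 0, 0]))] * 2
        t1 = run_bd(None, None, None, self.MODEL, params, pose0)
        t2 = run_bd(None, None, None, self.MODEL, params, pose0)
        p1, p2 = tmp_path / "a.traj", tmp_path / "b.traj"
        write_trajectory(t1[0], p1)
        write_trajectory(t2[0], p2)
        assert p1.read_bytes() == p2.read_bytes()
        params3 = BDParams(duration=0.2, timestep=1000.0, output_stride=0.005, seed=8)
        t3 = run_bd(None, None, None, self.MODEL, params3, pose0)
        assert not np.array_equal(t3[0].positions, t1[0].positions)
        # replicas are independent streams
        assert not np.array_equal(t1[0].positions[1:], t1[1].positions[1:])

    def test_free_diffusion_msd(self):
        # Einstein relation <|r(t) - r(0)|^2> = 6 D t
        params = BDParams(duration=1.0, timestep=10000.0, output_stride=1.0, seed=11)
        poses = [(np.zeros(3), np.array([1.0, 0, 0, 0]))] * 400
        trajs = run_bd(None, None, None, self.MODEL, params, poses)
        disp = np.array([t.positions[-1] - t.positions[0] for t in trajs])
        msd = np.mean(np.sum(disp ** 2, axis=1))
        assert msd == pytest.approx(6 * self.MODEL.d_trans * 1.0, rel=0.10)

    def test_overlapping_start_rejected(self):
        stationary = random_body(10, seed=31, spread=3.0)
        mobile = random_body(5, seed=32, spread=2.0)
        frame = frame_around(stationary, spacing=1.0, margin=10.0)
        maps = build_map_set(stationary, frame, cutoff=30.0, cap=30.0)
        dens = build_density_set(mobile)
        params = BDParams(duration=0.01, timestep=1000.0, output_stride=0.01, seed=1)
        with pytest.raises(ValueError, match="overlaps"):
            run_bd(dens, maps, None, self.MODEL, params,
                   [(np.zeros(3), np.array([1.0, 0, 0, 0]))])

    def test_harmonic_well_equilibrium_variance(self):
        from rigidbd.restraints import RestraintSet, ZPotential
        k = 1.0
        centers = np.arange(-8.0, 8.01, 0.25)
        pot = ZPotential(z_min=-8.0 - 0.125, bin_width=0.25,
                         values=0.5 * k * centers ** 2)
        rs = RestraintSet(anchors={"A": (np.zeros(3), pot)},
                          wall_radius=1e6, wall_stiffness=0.0)
        params = BDParams(duration=40.0, timestep=250.0, output_stride=2.5e-4,
                          seed=13)
        trajs = run_bd(None, None, rs, self.MODEL, params,
                       [(np.zeros(3), np.array([1.0, 0, 0, 0]))] * 2)
        z = np.concatenate([t.positions[4000:, 2] for t in trajs])
        assert z.var() == pytest.approx(KB_KCAL * 310.0 / k, rel=0.10)

    def test_rotational_decorrelation(self):
        # <cos theta(t)> = exp(-2 D_r t) for a freely rotating body
        model = DiffusionModel(d_trans=1.0, d_rot=1.0, temperature=310.0)
        t_end = 0.5
        params = BDParams(duration=t_end, timestep=5000.0, output_stride=t_end,
                          seed=17)
        poses = [(np.zeros(3), np.array([1.0, 0, 0, 0]))] * 600
        trajs = run_bd(None, None, None, model, params, poses)
        cos_theta = [rotation_matrix(t.quaternions[-1])[2, 2] for t in trajs]
        assert np.mean(cos_theta) == pytest.approx(np.exp(-2 * model.d_rot * t_end),
                                                   rel=0.10)
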