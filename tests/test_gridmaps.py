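"""Potential/density map construction and trilinear interpolation."""

import numpy as np
import pytest

from rigidbd.constants import COULOMB_KCAL
from rigidbd.gridmaps import (
    LJCategory,
    collapse_lj_categories,
    deposit_density,
    frame_around,
    gradient,
    interpolate,
    lj_potential_map,
    make_frame,
    screened_coulomb_map,
)
from rigidbd.io_formats import AtomRecord, GridMap, Structure
from conftest import random_body, single_atom


def _atom(element, eps, rmin_half=2.0, serial=1, pos=(0, 0, 0)):
    return AtomRecord(serial=serial, name=f"X{serial}", element=element,
                      residue_name="T", residue_id=serial, chain="A",
                      position=pos, lj_rmin_half=rmin_half, lj_epsilon=eps,
                      vdw_radius=1.5)


class TestCollapseLJ:
    def test_identical_atoms_single_category(self):
        s = Structure([_atom("C", 0.1, 2.0, i + 1) for i in range(5)])
        cats = {c.label: c for c in collapse_lj_categories(s)}
        assert cats["C,S"].rmin_mean == pytest.approx(4.0)  # Rmin = 2 x Rmin/2
        assert cats["C,S"].eps_scaled == pytest.approx(0.03)
        assert cats["C,S"].n_members == 5

    def test_mixed_on_category_mean(self):
        s = Structure([
            _atom("O", 0.12, serial=1), _atom("O", 0.20, serial=2),
            _atom("N", 0.20, serial=3),
        ])
        cats = {c.label: c for c in collapse_lj_categories(s)}
        assert cats["O,N"].eps_scaled == pytest.approx(0.052)

    def test_unit_scale_reproduces_unscaled_mean(self):
        s = Structure([_atom("H", 0.05, 1.0, 1), _atom("H", 0.15, 1.2, 2)])
        cats = {c.label: c for c in collapse_lj_categories(s, scale=1.0)}
        assert cats["H"].eps_scaled == pytest.approx(0.1)
        assert cats["H"].rmin_mean == pytest.approx(2.2)

    def test_unknown_element_names_atom(self):
        s = Structure([_atom("Fe", 0.1, serial=9)])
        with pytest.raises(ValueError, match="atom 9"):
            collapse_lj_categories(s)

    def test_empty_category_retained_with_warning(self):
        s = Structure([_atom("C", 0.1)])
        with pytest.warns(UserWarning):
            cats = {c.label: c for c in collapse_lj_categories(s)}
        assert cats["H"].n_members == 0


class TestDeposit:
    def test_atom_on_node_deposits_single_cell(self):
        s = Structure([single_atom(position=(2.0, 3.0, 1.0), charge=1.0)])
        frame = make_frame((0, 0, 0), 1.0, (6, 6, 6))
        g = deposit_density(s, "charge", frame)
        assert g.values[2, 3, 1] == pytest.approx(1.0)
        assert g.values.sum() == pytest.approx(1.0)
        assert np.count_nonzero(g.values) == 1

    def test_atom_at_cell_center_splits_eighths(self):
        s = Structure([single_atom(position=(1.5, 1.5, 1.5), charge=1.0)])
        frame = make_frame((0, 0, 0), 1.0, (4, 4, 4))
        g = deposit_density(s, "charge", frame)
        sub = g.values[1:3, 1:3, 1:3]
        np.testing.assert_allclose(sub, 0.125)
        assert g.values.sum() == pytest.approx(1.0)

    def test_charge_conservation_random_body(self):
        body = random_body(50, seed=5)
        frame = frame_around(body, spacing=1.0, margin=2.0)
        g = deposit_density(body, "charge", frame)
        assert g.values.sum() == pytest.approx(body.total_charge, abs=1e-9)

    def test_count_conservation_per_category(self):
        body = random_body(30, seed=6)
        frame = frame_around(body, spacing=1.0)
        g = deposit_density(body, "count", frame, category_indices=np.arange(12))
        assert g.values.sum() == pytest.approx(12.0, abs=1e-9)

    def test_atom_outside_grid_names_serial(self):
        s = Structure([single_atom(position=(100.0, 0, 0), serial=77)])
        frame = make_frame((0, 0, 0), 1.0, (5, 5, 5))
        with pytest.raises(ValueError, match="77"):
            deposit_density(s, "charge", frame)


class TestScreenedCoulomb:
    def test_point_charge_coulomb_value(self):
        s = Structure([single_atom(charge=1.0)])
        frame = make_frame((-12, -12, -12), 1.0, (25, 25, 25))
        g = screened_coulomb_map(s, frame, solvent_dielectric=1.0,
                                 ionic_strength=0.0, cutoff=50.0, cap=1e9)
        v = interpolate(g, (10.0, 0.0, 0.0))
        assert v == pytest.approx(33.206, abs=5e-3)

    def test_zero_charges_zero_map(self):
        s = Structure([single_atom(charge=0.0)])
        frame = make_frame((-5, -5, -5), 1.0, (11, 11, 11))
        g = screened_coulomb_map(s, frame)
        assert np.all(g.values == 0.0)

    def test_debye_screening_ratio(self):
        s = Structure([single_atom(charge=1.0)])
        frame = make_frame((-1, -1, -10), 1.0, (3, 3, 21))
        lam = 3.04 / np.sqrt(0.15)
        g0 = screened_coulomb_map(s, frame, 1.0, 0.0, cutoff=50.0, cap=1e9)
        gs = screened_coulomb_map(s, frame, 1.0, 0.15, cutoff=50.0, cap=1e9)
        r = lam
        v0 = interpolate(g0, (0.0, 0.0, r))
        vs = interpolate(gs, (0.0, 0.0, r))
        assert vs / v0 == pytest.approx(np.exp(-1.0), rel=0.01)

    def test_matches_pairwise_oracle_beyond_clamp(self):
        body = random_body(10, seed=2, spread=3.0)
        frame = make_frame((-15, -15, -15), 1.0, (31, 31, 31))
        g = screened_coulomb_map(body, frame, 1.0, 0.0, cutoff=100.0, cap=1e9)
        xs = frame.axis_coords(0)
        nodes = np.stack(np.meshgrid(xs, xs, xs, indexing="ij"), axis=-1).reshape(-1, 3)
        d = np.linalg.norm(nodes[:, None, :] - body.positions[None], axis=2)
        keep = d.min(axis=1) > 1.5
        oracle = (COULOMB_KCAL * body.charges[None, :] / d).sum(axis=1)
        got = g.values.reshape(-1)
        np.testing.assert_allclose(got[keep], oracle[keep], rtol=1e-6)

    def test_negative_ionic_strength_rejected(self):
        s = Structure([single_atom()])
        frame = make_frame((0, 0, 0), 1.0, (3, 3, 3))
        with pytest.raises(ValueError):
            screened_coulomb_map(s, frame, ionic_strength=-0.1)
        with pytest.raises(ValueError):
            screened_coulomb_map(s, frame, cutoff=0.0)


class TestLJMap:
    CAT = LJCategory(label="C,S", rmin_mean=4.0, eps_scaled=0.03, n_members=1)

    def test_minimum_at_combined_rmin(self):
        s = Structure([single_atom(rmin_half=2.0, eps=0.12)])
        r_ij = 2.0 + 2.0  # category Rmin/2 + atom Rmin/2
        frame = make_frame((-6, -6, -6), 1.0, (13, 13, 13))
        g = lj_potential_map(s, self.CAT, frame, cap=30.0, cutoff=20.0)
        eps_ij = np.sqrt(0.03 * 0.12)
        assert g.values[6 + 4, 6, 6] == pytest.approx(-eps_ij, rel=1e-9)
        assert interpolate(g, (r_ij, 0, 0)) == pytest.approx(-eps_ij, rel=1e-9)

    def test_decays_to_zero_far_away(self):
        s = Structure([single_atom(eps=0.12)])
        frame = make_frame((-40, -2, -2), 2.0, (41, 3, 3))
        g = lj_potential_map(s, self.CAT, frame, cutoff=100.0)
        assert abs(interpolate(g, (-38.0, 0, 0))) < 1e-6

    def test_pairwise_additivity(self):
        s2 = Structure([
            single_atom(position=(-5.0, 0, 0), serial=1, eps=0.12),
            single_atom(position=(5.0, 0, 0), serial=2, eps=0.12),
        ])
        s1 = Structure([single_atom(position=(-5.0, 0, 0), eps=0.12)])
        frame = make_frame((-1, -1, -1), 1.0, (3, 3, 3))
        g2 = lj_potential_map(s2, self.CAT, frame, cutoff=50.0)
        g1 = lj_potential_map(s1, self.CAT, frame, cutoff=50.0)
        # midpoint node is symmetric: two-atom value is twice one atom's
        assert g2.values[1, 1, 1] == pytest.approx(2 * g1.values[1, 1, 1], rel=1e-12)

    def test_clamped_never_nan(self):
        s = Structure([single_atom(eps=0.12)])
        frame = make_frame((-2, -2, -2), 1.0, (5, 5, 5))
        g = lj_potential_map(s, self.CAT, frame, cap=30.0)
        assert np.all(np.isfinite(g.values))
        assert g.values.max() <= 30.0


class TestInterpolation:
    def test_linear_field_reproduced_exactly(self, rng):
        zs = np.arange(9.0)
        vals = np.broadcast_to(2.0 * zs, (5, 5, 9)).copy()
        g = GridMap(origin=(0, 0, 0), spacing=1.0, values=vals)
        pts = rng.uniform(0.2, 3.8, (50, 3)) + np.array([0, 0, 2.0])
        np.testing.assert_allclose(interpolate(g, pts), 2.0 * pts[:, 2], rtol=1e-12)
        grads = gradient(g, pts)
        np.testing.assert_allclose(grads, np.tile([0, 0, 2.0], (50, 1)), atol=1e-12)

    def test_node_values_exact(self, rng):
        vals = rng.standard_normal((4, 4, 4))
        g = GridMap(origin=(1, 1, 1), spacing=0.5, values=vals)
        assert interpolate(g, (1.0 + 0.5 * 2, 1.0 + 0.5 * 3, 1.0)) == \
            pytest.approx(vals[2, 3, 0], rel=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        vals = rng.standard_normal((8, 8, 8))
        g = GridMap(origin=(0, 0, 0), spacing=1.0, values=vals)
        pts = rng.uniform(1.2, 5.8, (100, 3))
        # keep FD probes inside one cell so the interpolant is smooth there
        pts = np.floor(pts) + np.clip(pts - np.floor(pts), 0.1, 0.9)
        h = 1e-6
        ana = gradient(g, pts)
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = h
            num = (interpolate(g, pts + e) - interpolate(g, pts - e)) / (2 * h)
            np.testing.assert_allclose(ana[:, ax], num, atol=1e-6)

    def test_out_of_bounds_policies(self):
        g = GridMap(origin=(0, 0, 0), spacing=1.0, values=np.ones((3, 3, 3)),
                    out_of_bounds="zero")
        assert interpolate(g, (10.0, 0, 0)) == 0.0
        g.out_of_bounds = "error"
        with pytest.raises(ValueError, match="outside"):
            interpolate(g, (10.0, 0, 0))
        g.out_of_bounds = "clamp"
        assert interpolate(g, (10.0, 0, 0)) == pytest.approx(1.0)
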