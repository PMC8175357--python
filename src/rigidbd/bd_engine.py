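"""Overdamped rigid-body Brownian dynamics under grid-map forces.

The mobile body carries precomputed density grids in its own frame
(charge per cell, LJ particles per cell per category).  At each step
the occupied cells are rigidly transformed by the current pose, the
matching stationary potential maps are differentiated at the cell
centres, and the local forces ``-rho grad V`` and their torques about
the centre of mass are summed.  Anchoring restraints and the lateral
wall add their own force and torque contributions.

Propagation uses the first-order overdamped (Ermak-McCammon) update

    dx   = (D_t / k_B T) F dt + sqrt(2 D_t dt) xi
    dphi = (D_r / k_B T) tau dt + sqrt(2 D_r dt) xi_rot

with independent standard-normal noise per axis; the rotation vector
``dphi`` is applied as an exponential-map quaternion increment and the
quaternion renormalised every step.  With a 200 fs step and
protein-scale friction, momentum relaxation is far below the step, so
the inertialess limit is the appropriate propagator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from rigidbd.constants import KB_KCAL
from rigidbd.gridmaps import (
    DensitySet,
    MapSet,
    categorize_atoms,
    collapse_lj_categories,
    deposit_density,
    frame_around,
    gradient,
    interpolate,
    lj_potential_map,
    screened_coulomb_map,
)
from rigidbd.io_formats import GridMap, Structure, Trajectory
from rigidbd.restraints import RestraintSet, wall_energy, wall_force

__all__ = [
    "DiffusionModel",
    "BDParams",
    "BDState",
    "quat_multiply",
    "quat_rotate",
    "quat_from_rotvec",
    "rotation_matrix",
    "stokes_diffusion",
    "build_density_set",
    "build_map_set",
    "grid_force_torque",
    "restraint_force_torque",
    "total_energy",
    "bd_step",
    "run_bd",
]


# ---------------------------------------------------------------------------
# quaternions (w, x, y, z convention)


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def rotation_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def quat_rotate(q: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    """Rotate row vectors by the unit quaternion q."""
    return np.asarray(vectors) @ rotation_matrix(q).T


def quat_from_rotvec(phi: np.ndarray) -> np.ndarray:
    """Exponential map: rotation vector (axis * angle, rad) to quaternion."""
    angle = float(np.linalg.norm(phi))
    if angle < 1e-12:
        return np.array([1.0, 0.5 * phi[0], 0.5 * phi[1], 0.5 * phi[2]]) / np.sqrt(
            1.0 + 0.25 * angle * angle)
    axis = phi / angle
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


# ---------------------------------------------------------------------------
# models and state


@dataclass(frozen=True)
class DiffusionModel:
    """Isotropic translational and rotational diffusion coefficients.

    ``d_trans`` in A^2/ns, ``d_rot`` in rad^2/ns; temperature in K.
    Anisotropic diffusion tensors are deliberately reduced to scalars:
    pose discovery is insensitive to the detailed diffusive behaviour.
    """

    d_trans: float
    d_rot: float
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if self.d_trans <= 0 or self.d_rot <= 0:
            raise ValueError("diffusion coefficients must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def kt(self) -> float:
        return KB_KCAL * self.temperature


def stokes_diffusion(radius: float, viscosity: float = 0.6913,
                     temperature: float = 310.0) -> DiffusionModel:
    """Stokes-Einstein diffusion model for a sphere.

    ``radius`` in A, ``viscosity`` in mPa s (0.6913 is water at 310 K).
    D_t = k_B T / (6 pi eta R), D_r = k_B T / (8 pi eta R^3), returned
    in A^2/ns and rad^2/ns.  A transparent stand-in for bead-model
    hydrodynamics calculations when only the scale of diffusion matters.
    """
    if radius <= 0 or viscosity <= 0 or temperature <= 0:
        raise ValueError("radius, viscosity and temperature must be > 0")
    kb_si = 1.380649e-23  # J/K
    kt = kb_si * temperature
    eta = viscosity * 1e-3  # Pa s
    r_m = radius * 1e-10
    d_trans = kt / (6.0 * np.pi * eta * r_m) * 1e11  # m^2/s -> A^2/ns
    d_rot = kt / (8.0 * np.pi * eta * r_m ** 3) * 1e-9  # rad^2/s -> rad^2/ns
    return DiffusionModel(d_trans=d_trans, d_rot=d_rot, temperature=temperature)


@dataclass(frozen=True)
class BDParams:
    """Propagation parameters; defaults follow the production protocol."""

    duration: float  # ns
    timestep: float = 200.0  # fs
    cutoff: float = 34.0  # A
    output_stride: float = 0.2  # ns
    seed: int = 0
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if self.timestep <= 0 or self.duration <= 0:
            raise ValueError("timestep and duration must be > 0")

    @property
    def dt_ns(self) -> float:
        return self.timestep * 1e-6

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt_ns))


@dataclass
class BDState:
    """Instantaneous pose plus time and RNG state of one replica."""

    position: np.ndarray
    quaternion: np.ndarray
    time: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        q = np.asarray(self.quaternion, dtype=float)
        self.quaternion = q / np.linalg.norm(q)


# ---------------------------------------------------------------------------
# force field assembly


def build_density_set(structure: Structure, spacing: float = 1.0,
                      margin: float = 2.0) -> DensitySet:
    """Deposit the mobile body's charge and per-category LJ densities.

    The grids live in the body frame: the structure's geometric centre
    is moved to the origin, and the propagator transforms occupied cell
    centres rigidly at each step (no re-deposition during a run).
    """
    centred = structure.translated(-structure.center_of_geometry())
    frame = frame_around(centred, spacing=spacing, margin=margin)
    charge = deposit_density(centred, "charge", frame)
    indices = categorize_atoms(centred)
    lj = {
        label: deposit_density(centred, "count", frame, category_indices=idx)
        for label, idx in indices.items()
        if idx.size > 0
    }
    return DensitySet(charge_density=charge, lj_density=lj)


def build_map_set(stationary: Structure, frame: GridMap,
                  solvent_dielectric: float = 78.0, ionic_strength: float = 0.0,
                  cutoff: float = 34.0, cap: float = 30.0,
                  eps_scale: float = 0.3,
                  elec_map: GridMap | None = None) -> MapSet:
    """Build the stationary body's electrostatic and LJ potential maps.

    If ``elec_map`` is given (e.g. imported from a Poisson-Boltzmann
    solver via DX) it is used verbatim and the provenance recorded;
    otherwise the built-in screened-Coulomb map is computed.
    """
    if elec_map is None:
        elec = screened_coulomb_map(stationary, frame, solvent_dielectric,
                                    ionic_strength, cutoff, cap)
        provenance = "internal-screened-coulomb"
    else:
        elec = elec_map
        provenance = "imported-dx"
    cats = collapse_lj_categories(stationary, scale=eps_scale)
    lj = {
        c.label: lj_potential_map(stationary, c, frame, cap=cap, cutoff=cutoff)
        for c in cats if c.n_members > 0
    }
    return MapSet(elec_potential=elec, lj_potential=lj, provenance=provenance)


def _pose_cells(density: DensitySet, maps: MapSet):
    pairs = [(maps.elec_potential, *density.charge_cells)]
    for label, (pts, wts) in density.lj_cells.items():
        if label not in maps.lj_potential:
            raise ValueError(
                f"density category {label!r} has no matching LJ potential map"
            )
        pairs.append((maps.lj_potential[label], pts, wts))
    return pairs


class _FusedField:
    """All maps of a MapSet stacked for one-shot gradient gathers.

    Every map of a MapSet shares one frame, so the occupied density
    cells of all maps can be evaluated with a single trilinear locate
    and flat-index gather per step; this is purely an evaluation-speed
    device and changes no numbers.
    """

    def __init__(self, density: DensitySet, maps: MapSet):
        frame = maps.elec_potential
        self.origin = frame.origin
        self.spacing = frame.spacing
        self.shape = np.array(frame.shape)
        values = [maps.elec_potential.values]
        pts = [density.charge_cells[0]]
        wts = [density.charge_cells[1]]
        for label, (p, w) in density.lj_cells.items():
            if label not in maps.lj_potential:
                raise ValueError(
                    f"density category {label!r} has no matching LJ potential map"
                )
            values.append(maps.lj_potential[label].values)
            pts.append(p)
            wts.append(w)
        self.flat = np.ascontiguousarray(np.stack(values)).ravel()
        nx, ny, nz = (int(s) for s in self.shape)
        self.points = np.concatenate(pts)
        self.weights = np.concatenate(wts)
        map_index = np.concatenate([np.full(len(p), m) for m, p in enumerate(pts)])
        self.map_offset = map_index * (nx * ny * nz)
        self.strides = (ny * nz, nz)

    def force_torque(self, position: np.ndarray, rot: np.ndarray):
        arms = self.points @ rot.T
        u = (arms + position - self.origin) / self.spacing
        n = self.shape
        inside = ((u[:, 0] >= 0) & (u[:, 0] <= n[0] - 1)
                  & (u[:, 1] >= 0) & (u[:, 1] <= n[1] - 1)
                  & (u[:, 2] >= 0) & (u[:, 2] <= n[2] - 1))
        i0 = np.floor(u).astype(np.int64)
        np.clip(i0, 0, n - 2, out=i0)
        f = u - i0
        fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
        sx, sy = self.strides
        base = self.map_offset + i0[:, 0] * sx + i0[:, 1] * sy + i0[:, 2]
        v = self.flat
        c000 = v[base]
        c001 = v[base + 1]
        c010 = v[base + sy]
        c011 = v[base + sy + 1]
        c100 = v[base + sx]
        c101 = v[base + sx + 1]
        c110 = v[base + sx + sy]
        c111 = v[base + sx + sy + 1]
        gy1, gz1 = 1.0 - fy, 1.0 - fz
        gx = ((c100 - c000) * gy1 * gz1 + (c110 - c010) * fy * gz1
              + (c101 - c001) * gy1 * fz + (c111 - c011) * fy * fz)
        gx1 = 1.0 - fx
        gy = ((c010 - c000) * gx1 * gz1 + (c110 - c100) * fx * gz1
              + (c011 - c001) * gx1 * fz + (c111 - c101) * fx * fz)
        gz = ((c001 - c000) * gx1 * gy1 + (c101 - c100) * fx * gy1
              + (c011 - c010) * gx1 * fy + (c111 - c110) * fx * fy)
        w = np.where(inside, self.weights, 0.0)
        f0 = -w * gx / self.spacing[0]
        f1 = -w * gy / self.spacing[1]
        f2 = -w * gz / self.spacing[2]
        ax, ay, az = arms[:, 0], arms[:, 1], arms[:, 2]
        force = np.array([f0.sum(), f1.sum(), f2.sum()])
        torque = np.array([
            (ay * f2 - az * f1).sum(),
            (az * f0 - ax * f2).sum(),
            (ax * f1 - ay * f0).sum(),
        ])
        return force, torque

    def force_torque_batch(self, positions: np.ndarray, rot: np.ndarray):
        """Forces/torques for a batch of poses (R,3)/(R,3,3) in one gather."""
        arms = np.einsum("rij,cj->rci", rot, self.points)
        u = (arms + positions[:, None, :] - self.origin) / self.spacing
        n = self.shape
        inside = ((u[..., 0] >= 0) & (u[..., 0] <= n[0] - 1)
                  & (u[..., 1] >= 0) & (u[..., 1] <= n[1] - 1)
                  & (u[..., 2] >= 0) & (u[..., 2] <= n[2] - 1))
        i0 = np.floor(u).astype(np.int64)
        np.clip(i0, 0, n - 2, out=i0)
        f = u - i0
        fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
        sx, sy = self.strides
        base = self.map_offset + i0[..., 0] * sx + i0[..., 1] * sy + i0[..., 2]
        v = self.flat
        c000 = v[base]
        c001 = v[base + 1]
        c010 = v[base + sy]
        c011 = v[base + sy + 1]
        c100 = v[base + sx]
        c101 = v[base + sx + 1]
        c110 = v[base + sx + sy]
        c111 = v[base + sx + sy + 1]
        gy1, gz1 = 1.0 - fy, 1.0 - fz
        gx1 = 1.0 - fx
        gx = ((c100 - c000) * gy1 * gz1 + (c110 - c010) * fy * gz1
              + (c101 - c001) * gy1 * fz + (c111 - c011) * fy * fz)
        gy = ((c010 - c000) * gx1 * gz1 + (c110 - c100) * fx * gz1
              + (c011 - c001) * gx1 * fz + (c111 - c101) * fx * fz)
        gz = ((c001 - c000) * gx1 * gy1 + (c101 - c100) * fx * gy1
              + (c011 - c010) * gx1 * fy + (c111 - c110) * fx * fy)
        w = np.where(inside, self.weights, 0.0)
        f0 = -w * gx / self.spacing[0]
        f1 = -w * gy / self.spacing[1]
        f2 = -w * gz / self.spacing[2]
        ax, ay, az = arms[..., 0], arms[..., 1], arms[..., 2]
        force = np.stack([f0.sum(axis=1), f1.sum(axis=1), f2.sum(axis=1)], axis=1)
        torque = np.stack([
            (ay * f2 - az * f1).sum(axis=1),
            (az * f0 - ax * f2).sum(axis=1),
            (ax * f1 - ay * f0).sum(axis=1),
        ], axis=1)
        return force, torque


def _fused_field(density: DensitySet, maps: MapSet) -> _FusedField:
    cache = getattr(density, "_fused_cache", None)
    if cache is None or cache[0] is not maps:
        field_obj = _FusedField(density, maps)
        density._fused_cache = (maps, field_obj)  # type: ignore[attr-defined]
        return field_obj
    return cache[1]


def grid_force_torque(density: DensitySet, maps: MapSet, position, quaternion):
    """Total grid force (kcal/mol/A) and torque (kcal/mol) on the mobile body.

    Deterministic function of the pose: each occupied density cell is
    transformed into the stationary frame, feels ``-rho grad V`` from
    its matching map (charge with the electrostatic map, each category
    count with its LJ map; no cross terms), and contributes a torque
    with its lever arm about the COM.
    """
    position = np.asarray(position, dtype=float)
    rot = rotation_matrix(np.asarray(quaternion, dtype=float))
    return _fused_field(density, maps).force_torque(position, rot)


def restraint_force_torque(restraints: RestraintSet, position, quaternion):
    """Force and torque from anchor z-potentials and the lateral wall."""
    position = np.asarray(position, dtype=float)
    rot = rotation_matrix(np.asarray(quaternion, dtype=float))
    force = wall_force(position, restraints.wall_radius, restraints.wall_stiffness)
    torque = np.zeros(3)
    z0 = position[2]
    for _label, (offset, pot) in restraints.anchors.items():
        arm = rot @ offset
        fz = pot.force(arm[2] + z0)
        force[2] += fz
        # torque of an axial force: arm x (0, 0, fz)
        torque[0] += arm[1] * fz
        torque[1] -= arm[0] * fz
    return force, torque


def total_energy(density: DensitySet, maps: MapSet | None,
                 restraints: RestraintSet | None, position, quaternion) -> float:
    """Pose energy (kcal/mol): grid interaction + restraints + wall."""
    position = np.asarray(position, dtype=float)
    rot = rotation_matrix(np.asarray(quaternion, dtype=float))
    e = 0.0
    if maps is not None:
        for grid_map, pts, wts in _pose_cells(density, maps):
            world = pts @ rot.T + position
            e += float(np.dot(wts, interpolate(grid_map, world)))
    if restraints is not None:
        e += wall_energy(position, restraints.wall_radius, restraints.wall_stiffness)
        for _label, (offset, pot) in restraints.anchors.items():
            arm = rot @ offset
            e += float(pot.energy(arm[2] + position[2]))
    return e


# ---------------------------------------------------------------------------
# propagation


def bd_step(state: BDState, force, torque, model: DiffusionModel, dt: float,
            noise: bool = True, max_displacement: float | None = None) -> BDState:
    """One overdamped Brownian step (dt in ns); returns the new state.

    The state's RNG advances by exactly two 3-vector draws when noise is
    on, so identical seeds reproduce identical paths bit for bit.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    kt = model.kt
    force = np.asarray(force, dtype=float)
    torque = np.asarray(torque, dtype=float)
    dx = (model.d_trans / kt) * force * dt
    dphi = (model.d_rot / kt) * torque * dt
    if noise:
        dx = dx + np.sqrt(2.0 * model.d_trans * dt) * state.rng.standard_normal(3)
        dphi = dphi + np.sqrt(2.0 * model.d_rot * dt) * state.rng.standard_normal(3)
    if max_displacement is not None and np.linalg.norm(dx) > max_displacement:
        warnings.warn(
            f"step displacement {np.linalg.norm(dx):.2f} A exceeds "
            f"{max_displacement:.2f} A; timestep too large for this field"
        )
    q = quat_multiply(quat_from_rotvec(dphi), state.quaternion)
    q /= np.linalg.norm(q)
    return BDState(position=state.position + dx, quaternion=q,
                   time=state.time + dt, rng=state.rng)


def run_bd(density: DensitySet | None, maps: MapSet | None,
           restraints: RestraintSet | None, model: DiffusionModel,
           params: BDParams, initial_poses, noise: bool = True,
           mobile_label: str = "mobile", stationary_label: str = "stationary",
           overlap_check: bool = True, cap: float = 30.0) -> list[Trajectory]:
    """Propagate one replica per initial pose; returns one trajectory each.

    ``initial_poses`` is a sequence of (position, quaternion).  Replica
    RNGs are spawned from ``params.seed`` so runs are reproducible and
    replicas independent (the same seed and inputs give bit-identical
    trajectories).  All replicas advance together through one vectorised
    stepping loop.  Frames are recorded every ``output_stride`` (plus
    the initial frame); trajectory metadata records the seed, parameters
    and map provenance.
    """
    if maps is not None and density is None:
        raise ValueError("grid maps supplied without a mobile density set")
    n_rep = len(initial_poses)
    seeds = np.random.SeedSequence(params.seed).spawn(n_rep)
    rngs = [np.random.default_rng(s) for s in seeds]
    stride_steps = max(1, int(round(params.output_stride / params.dt_ns)))
    n_steps = params.n_steps
    dt = params.dt_ns

    positions = np.array([np.asarray(p[0], dtype=float) for p in initial_poses])
    quats = np.array([np.asarray(p[1], dtype=float) for p in initial_poses])
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)

    if overlap_check and maps is not None and density is not None:
        for rep in range(n_rep):
            e0 = _max_lj_at_pose(density, maps, positions[rep], quats[rep])
            if e0 > cap / 2.0:
                raise ValueError(
                    f"replica {rep}: initial pose overlaps the stationary body "
                    f"(LJ map value {e0:.1f} kcal/mol)"
                )

    fused = _fused_field(density, maps) if maps is not None else None
    anchors = None
    if restraints is not None and restraints.anchors:
        anchors = (np.array([off for off, _ in restraints.anchors.values()]),
                   [pot for _, pot in restraints.anchors.values()])

    kt = model.kt
    mob_t = model.d_trans / kt * dt
    sig_t = np.sqrt(2.0 * model.d_trans * dt)
    mob_r = model.d_rot / kt * dt
    sig_r = np.sqrt(2.0 * model.d_rot * dt)
    max_disp = (2.0 * float(np.min(maps.elec_potential.spacing))
                if maps is not None else None)
    warned = False

    rec_times = [np.zeros(n_rep)]
    rec_pos = [positions.copy()]
    rec_quat = [quats.copy()]

    chunk = 512
    noise_buf = None
    for step in range(1, n_steps + 1):
        if noise:
            k = (step - 1) % chunk
            if k == 0:
                m = min(chunk, n_steps - (step - 1))
                noise_buf = np.stack([r.standard_normal((m, 6)) for r in rngs])
            xi = noise_buf[:, k, :]
        rot = _rotation_matrices(quats)
        force = np.zeros((n_rep, 3))
        torque = np.zeros((n_rep, 3))
        if fused is not None:
            f, t = fused.force_torque_batch(positions, rot)
            force += f
            torque += t
        if restraints is not None:
            f, t = _restraint_batch(restraints, anchors, positions, rot)
            force += f
            torque += t
        dx = mob_t * force
        dphi = mob_r * torque
        if noise:
            dx = dx + sig_t * xi[:, :3]
            dphi = dphi + sig_r * xi[:, 3:]
        if max_disp is not None and not warned:
            worst = float(np.max(np.linalg.norm(dx, axis=1)))
            if worst > max_disp:
                warnings.warn(
                    f"step displacement {worst:.2f} A exceeds {max_disp:.2f} A; "
                    "timestep too large for this field"
                )
                warned = True
        positions = positions + dx
        quats = _quat_increment(quats, dphi)
        if step % stride_steps == 0:
            rec_times.append(np.full(n_rep, step * dt))
            rec_pos.append(positions.copy())
            rec_quat.append(quats.copy())

    times = np.array([t[0] for t in rec_times])
    trajectories = []
    for rep in range(n_rep):
        trajectories.append(
            Trajectory(
                times=times,
                positions=np.array([p[rep] for p in rec_pos]),
                quaternions=np.array([q[rep] for q in rec_quat]),
                mobile_label=mobile_label,
                stationary_label=stationary_label,
                metadata={
                    "seed": params.seed,
                    "replica": rep,
                    "timestep_fs": params.timestep,
                    "temperature_K": params.temperature,
                    "provenance": maps.provenance if maps is not None else "none",
                },
            )
        )
    return trajectories


def _rotation_matrices(quats: np.ndarray) -> np.ndarray:
    w, x, y, z = quats[:, 0], quats[:, 1], quats[:, 2], quats[:, 3]
    rot = np.empty((quats.shape[0], 3, 3))
    rot[:, 0, 0] = 1 - 2 * (y * y + z * z)
    rot[:, 0, 1] = 2 * (x * y - w * z)
    rot[:, 0, 2] = 2 * (x * z + w * y)
    rot[:, 1, 0] = 2 * (x * y + w * z)
    rot[:, 1, 1] = 1 - 2 * (x * x + z * z)
    rot[:, 1, 2] = 2 * (y * z - w * x)
    rot[:, 2, 0] = 2 * (x * z - w * y)
    rot[:, 2, 1] = 2 * (y * z + w * x)
    rot[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return rot


def _quat_increment(quats: np.ndarray, dphi: np.ndarray) -> np.ndarray:
    """Apply exponential-map increments to a batch of quaternions."""
    angle = np.linalg.norm(dphi, axis=1)
    half = 0.5 * angle
    small = angle < 1e-12
    safe = np.where(small, 1.0, angle)
    s = np.where(small, 0.5, np.sin(half) / safe)
    dq = np.empty((quats.shape[0], 4))
    dq[:, 0] = np.cos(half)
    dq[:, 1:] = s[:, None] * dphi
    w1, x1, y1, z1 = dq[:, 0], dq[:, 1], dq[:, 2], dq[:, 3]
    w2, x2, y2, z2 = quats[:, 0], quats[:, 1], quats[:, 2], quats[:, 3]
    out = np.empty_like(quats)
    out[:, 0] = w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2
    out[:, 1] = w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2
    out[:, 2] = w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2
    out[:, 3] = w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


def _restraint_batch(restraints: RestraintSet, anchors, positions: np.ndarray,
                     rot: np.ndarray):
    n_rep = positions.shape[0]
    force = np.zeros((n_rep, 3))
    torque = np.zeros((n_rep, 3))
    # lateral wall on the COM
    r = np.hypot(positions[:, 0], positions[:, 1])
    beyond = r > restraints.wall_radius
    if beyond.any():
        mag = restraints.wall_stiffness * (r[beyond] - restraints.wall_radius) / r[beyond]
        force[beyond, 0] -= mag * positions[beyond, 0]
        force[beyond, 1] -= mag * positions[beyond, 1]
    if anchors is not None:
        offsets, pots = anchors
        arms = np.einsum("rij,aj->rai", rot, offsets)
        z = arms[:, :, 2] + positions[:, 2][:, None]
        for a, pot in enumerate(pots):
            fz = pot.force(z[:, a])
            force[:, 2] += fz
            torque[:, 0] += arms[:, a, 1] * fz
            torque[:, 1] -= arms[:, a, 0] * fz
    return force, torque


def _max_lj_at_pose(density: DensitySet, maps: MapSet, position, quaternion) -> float:
    rot = rotation_matrix(quaternion)
    worst = -np.inf
    for label, (pts, _wts) in density.lj_cells.items():
        if label not in maps.lj_potential:
            continue
        world = pts @ rot.T + position
        vals = interpolate(maps.lj_potential[label], world)
        if vals.size:
            worst = max(worst, float(vals.max()))
    return worst if np.isfinite(worst) else 0.0
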