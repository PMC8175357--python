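"""Trajectory post-processing: contacts, clusters, energies, hot spots.

Turns rigid-body association trajectories into the quantities a
binding-site search reports: which frames are in atomic contact, how
the contact poses cluster by RMSD, where the anchor's centre of mass
accumulates around the stationary body (hot spots), the pairwise
interaction energy of each pose, and how a charge perturbation at a
single site (a phosphomimetic) rescales the electrostatic component
cluster by cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

from rigidbd.bd_engine import rotation_matrix
from rigidbd.constants import COULOMB_KCAL
from rigidbd.io_formats import Structure, Trajectory

__all__ = [
    "PoseCluster",
    "HotspotDensity",
    "body_frame_coords",
    "frame_coordinates",
    "contact_frames",
    "cluster_poses",
    "interaction_energy",
    "score_clusters",
    "hotspot_density",
    "phospho_rescore",
    "tilt_angle",
    "membrane_depth_profile",
]


@dataclass
class PoseCluster:
    """One group of mutually similar in-contact poses.

    ``population`` is the cluster's share of all clustered frames;
    ``representative`` is a member frame index (the clustering seed, or
    after scoring the member with the most favourable interaction
    energy); ``rep_energy`` is that frame's (electrostatic, vdW) pair
    energy in kcal/mol.
    """

    member_frames: np.ndarray
    population: float
    representative: int
    rep_energy: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.member_frames = np.asarray(self.member_frames, dtype=int)
        if self.representative not in self.member_frames:
            raise ValueError("representative must be a member frame")


@dataclass
class HotspotDensity:
    """Normalised 2-D occupancy density of the anchor COM over the membrane plane."""

    x: np.ndarray
    y: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    @property
    def integral(self) -> float:
        dx = self.x[1] - self.x[0]
        dy = self.y[1] - self.y[0]
        return float(self.density.sum() * dx * dy)

    def mode(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.density), self.density.shape)
        return float(self.x[i]), float(self.y[j])


# ---------------------------------------------------------------------------
# coordinate plumbing


def body_frame_coords(structure: Structure) -> np.ndarray:
    """Atom coordinates relative to the body's geometric centre."""
    return structure.positions - structure.center_of_geometry()


def frame_coordinates(traj: Trajectory, mobile: Structure, frame: int,
                      atom_indices=None) -> np.ndarray:
    """World coordinates of the mobile body's atoms in one frame."""
    body = body_frame_coords(mobile)
    if atom_indices is not None:
        body = body[np.asarray(atom_indices, dtype=int)]
    rot = rotation_matrix(traj.quaternions[frame])
    return body @ rot.T + traj.positions[frame]


# ---------------------------------------------------------------------------
# contacts


def contact_frames(traj: Trajectory, mobile: Structure, stationary: Structure,
                   cutoff: float = 3.0) -> np.ndarray:
    """Frames where any inter-body atom pair is within the contact cutoff.

    Uses a k-d tree on the stationary body; equivalent to the brute
    force double loop over all atom pairs.
    """
    tree = cKDTree(stationary.positions)
    body = body_frame_coords(mobile)
    hits = []
    for i in range(len(traj)):
        rot = rotation_matrix(traj.quaternions[i])
        world = body @ rot.T + traj.positions[i]
        d, _ = tree.query(world, k=1, distance_upper_bound=cutoff + 1e-12)
        if np.any(np.isfinite(d) & (d <= cutoff)):
            hits.append(i)
    return np.asarray(hits, dtype=int)


# ---------------------------------------------------------------------------
# clustering


def cluster_poses(frame_coords: np.ndarray, rmsd_cutoff: float = 10.0,
                  frame_indices=None) -> list[PoseCluster]:
    """Greedy quality-threshold clustering of poses by pairwise RMSD.

    ``frame_coords`` has shape (n_frames, n_atoms, 3): the mobile
    body's reference atoms expressed in the stationary frame (no
    refitting — the stationary body defines the superposition).  The
    frame with the most neighbours within the RMSD cutoff seeds the
    first cluster, its neighbours are assigned and removed, and the
    procedure repeats; ties break on the lowest frame index.  Clusters
    are ordered by size and populations are fractions of the clustered
    frames.
    """
    coords = np.asarray(frame_coords, dtype=float)
    if coords.ndim != 3:
        raise ValueError("frame_coords must have shape (n_frames, n_atoms, 3)")
    n = coords.shape[0]
    if n == 0:
        return []
    if frame_indices is None:
        frame_indices = np.arange(n)
    frame_indices = np.asarray(frame_indices, dtype=int)

    flat = coords.reshape(n, -1)
    sq = np.sum((flat[:, None, :] - flat[None, :, :]) ** 2, axis=2)
    rmsd = np.sqrt(sq / coords.shape[1])
    neighbor = rmsd <= rmsd_cutoff

    remaining = np.ones(n, dtype=bool)
    clusters: list[np.ndarray] = []
    while remaining.any():
        counts = (neighbor & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        seed = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.nonzero(neighbor[seed] & remaining)[0]
        clusters.append((seed, members))
        remaining[members] = False

    clusters.sort(key=lambda sm: (-len(sm[1]), sm[0]))
    out = []
    for seed, members in clusters:
        out.append(
            PoseCluster(
                member_frames=frame_indices[members],
                population=len(members) / n,
                representative=int(frame_indices[seed]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# energies


def _pair_energy(pos_m, q_m, rh_m, eps_m, pos_s, q_s, rh_s, eps_s,
                 dielectric: float, cutoff: float) -> tuple[float, float]:
    tree = cKDTree(pos_s)
    pairs = tree.query_ball_point(pos_m, r=cutoff)
    elec = 0.0
    vdw = 0.0
    for i, js in enumerate(pairs):
        if not js:
            continue
        js = np.asarray(js, dtype=int)
        d = np.linalg.norm(pos_s[js] - pos_m[i], axis=1)
        if np.any(d < 0.1):
            raise ValueError(
                f"inter-body distance {d.min():.3g} A below 0.1 A: steric clash "
                "outside the model's validity"
            )
        elec += float(np.sum(COULOMB_KCAL * q_m[i] * q_s[js] / (dielectric * d)))
        eps_ij = np.sqrt(eps_m[i] * eps_s[js])
        r_ij = rh_m[i] + rh_s[js]
        s6 = (r_ij / d) ** 6
        vdw += float(np.sum(eps_ij * (s6 * s6 - 2.0 * s6)))
    return elec, vdw


def interaction_energy(mobile: Structure, stationary: Structure, pose=None,
                       dielectric: float = 78.0, cutoff: float = 12.0,
                       mobile_charges=None,
                       stationary_charges=None) -> tuple[float, float]:
    """Pairwise (electrostatic, vdW) interaction energy in kcal/mol.

    Coulomb 332.0636 q_i q_j / (eps_r r) plus Lennard-Jones
    eps_ij [(R_ij/r)^12 - 2 (R_ij/r)^6] with Lorentz-Berthelot
    combination, summed over inter-body pairs within a hard cutoff (no
    switching).  ``pose`` is an optional (position, quaternion) applied
    to the mobile body; charge overrides support perturbation rescoring.
    """
    pos_m = mobile.positions
    if pose is not None:
        position, quaternion = pose
        rot = rotation_matrix(np.asarray(quaternion, dtype=float))
        pos_m = body_frame_coords(mobile) @ rot.T + np.asarray(position, dtype=float)
    q_m = mobile.charges if mobile_charges is None else np.asarray(mobile_charges)
    q_s = stationary.charges if stationary_charges is None else np.asarray(stationary_charges)
    return _pair_energy(pos_m, q_m, mobile.lj_rmin_half, mobile.lj_epsilon,
                        stationary.positions, q_s, stationary.lj_rmin_half,
                        stationary.lj_epsilon, dielectric, cutoff)


def score_clusters(clusters: list[PoseCluster], traj: Trajectory,
                   mobile: Structure, stationary: Structure,
                   dielectric: float = 78.0, cutoff: float = 12.0) -> list[PoseCluster]:
    """Re-select each cluster's representative by interaction energy.

    The member frame with the most favourable (lowest electrostatic +
    vdW) interaction energy becomes the representative; its energy pair
    is stored on the cluster.
    """
    out = []
    for cl in clusters:
        best, best_e, best_pair = None, np.inf, None
        for fr in cl.member_frames:
            pair = interaction_energy(
                mobile, stationary,
                pose=(traj.positions[fr], traj.quaternions[fr]),
                dielectric=dielectric, cutoff=cutoff,
            )
            total = pair[0] + pair[1]
            if total < best_e:
                best, best_e, best_pair = int(fr), total, pair
        out.append(replace(cl, representative=best, rep_energy=best_pair))
    return out


# ---------------------------------------------------------------------------
# hot spots


def hotspot_density(traj: Trajectory, mobile: Structure, anchor_indices,
                    bandwidth: float | None = None, resolution: float = 1.0,
                    padding: float = 5.0, frames=None) -> HotspotDensity:
    """Gaussian kernel density of the anchor COM over the membrane (x, y) plane.

    Bandwidth defaults to Scott's rule on the frame set; the density is
    evaluated on a grid of the given resolution and renormalised to
    integrate to exactly 1 on that grid.
    """
    if frames is None:
        frames = np.arange(len(traj))
    frames = np.asarray(frames, dtype=int)
    if frames.size < 10:
        raise ValueError("need at least 10 frames for a density estimate")
    anchor_body = body_frame_coords(mobile)[np.asarray(anchor_indices, dtype=int)]
    com_body = anchor_body.mean(axis=0)
    xy = np.empty((frames.size, 2))
    for k, fr in enumerate(frames):
        rot = rotation_matrix(traj.quaternions[fr])
        xy[k] = (rot @ com_body + traj.positions[fr])[:2]
    if np.any(xy.std(axis=0) < 1e-9):
        # degenerate (point or collinear) cloud; keep the KDE covariance invertible
        xy = xy + 1e-6 * np.random.default_rng(0).standard_normal(xy.shape)
    kde = gaussian_kde(xy.T, bw_method=None if bandwidth is None else
                       bandwidth / max(xy.std(ddof=1), 1e-12))
    lo = xy.min(axis=0) - padding
    hi = xy.max(axis=0) + padding
    x = np.arange(lo[0], hi[0] + resolution, resolution)
    y = np.arange(lo[1], hi[1] + resolution, resolution)
    gx, gy = np.meshgrid(x, y, indexing="ij")
    dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(gx.shape)
    dens = np.maximum(dens, 0.0)
    dens /= dens.sum() * resolution * resolution
    bw = float(kde.factor * xy.std(ddof=1)) if bandwidth is None else bandwidth
    return HotspotDensity(x=x, y=y, density=dens, bandwidth=bw)


# ---------------------------------------------------------------------------
# perturbation rescoring


def phospho_rescore(clusters: list[PoseCluster], traj: Trajectory,
                    mobile: Structure, stationary: Structure,
                    site_residue_id: int, modified_charges: dict[str, float],
                    dielectric: float = 78.0, cutoff: float = 12.0) -> dict[int, float]:
    """Electrostatic-energy ratio per cluster after a site charge perturbation.

    The atoms of residue ``site_residue_id`` on the stationary body get
    the charges in ``modified_charges`` (atom name -> new charge, e;
    unlisted atoms keep their original charge), emulating e.g. a
    phosphoserine substitution.  For each cluster the mean electrostatic
    interaction energy over member frames is recomputed and the ratio
    original/modified returned, keyed by cluster index.
    """
    site_atoms = [i for i, a in enumerate(stationary.atoms)
                  if a.residue_id == site_residue_id]
    if not site_atoms:
        raise ValueError(f"no residue with id {site_residue_id} in the stationary body")
    q_mod = stationary.charges.copy()
    for i in site_atoms:
        name = stationary.atoms[i].name
        if name in modified_charges:
            q_mod[i] = modified_charges[name]

    ratios: dict[int, float] = {}
    for ci, cl in enumerate(clusters):
        orig, mod = [], []
        for fr in cl.member_frames:
            pose = (traj.positions[fr], traj.quaternions[fr])
            e_o, _ = interaction_energy(mobile, stationary, pose=pose,
                                        dielectric=dielectric, cutoff=cutoff)
            e_m, _ = interaction_energy(mobile, stationary, pose=pose,
                                        dielectric=dielectric, cutoff=cutoff,
                                        stationary_charges=q_mod)
            orig.append(e_o)
            mod.append(e_m)
        mean_o = float(np.mean(orig))
        mean_m = float(np.mean(mod))
        ratios[ci] = 1.0 if mean_o == mean_m else mean_o / mean_m
    return ratios


# ---------------------------------------------------------------------------
# geometry observables


def tilt_angle(traj: Trajectory, mobile: Structure, tail_indices,
               head_indices) -> np.ndarray:
    """Per-frame angle (deg) between the body axis and the membrane normal.

    The axis runs from the COM of ``tail_indices`` to the COM of
    ``head_indices``; the membrane normal is +z.
    """
    body = body_frame_coords(mobile)
    c1 = body[np.asarray(tail_indices, dtype=int)].mean(axis=0)
    c2 = body[np.asarray(head_indices, dtype=int)].mean(axis=0)
    axis_body = c2 - c1
    if np.linalg.norm(axis_body) < 1e-12:
        raise ValueError("axis endpoints coincide")
    out = np.empty(len(traj))
    for i in range(len(traj)):
        axis = rotation_matrix(traj.quaternions[i]) @ axis_body
        cosang = axis[2] / np.linalg.norm(axis)
        out[i] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return out


def membrane_depth_profile(traj: Trajectory, mobile: Structure,
                           selections: dict[str, "np.ndarray"],
                           phosphorus_plane_z: float,
                           frames=None) -> dict[str, tuple[float, float]]:
    """Mean and sd of each selection's COM z relative to the phosphate plane.

    Negative values lie below the plane (deeper in the membrane).
    """
    if not np.isfinite(phosphorus_plane_z):
        raise ValueError("phosphorus plane z must be finite")
    if frames is None:
        frames = np.arange(len(traj))
    frames = np.asarray(frames, dtype=int)
    body = body_frame_coords(mobile)
    out: dict[str, tuple[float, float]] = {}
    for label, idx in selections.items():
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            raise ValueError(f"selection {label!r} is empty")
        com_body = body[idx].mean(axis=0)
        zs = np.empty(frames.size)
        for k, fr in enumerate(frames):
            rot = rotation_matrix(traj.quaternions[fr])
            zs[k] = (rot @ com_body + traj.positions[fr])[2] - phosphorus_plane_z
        out[label] = (float(zs.mean()), float(zs.std()))
    return out
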