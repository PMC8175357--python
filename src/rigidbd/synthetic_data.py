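"""Synthetic fixtures with machine-readable ground truth.

Every stage of the pipeline can be exercised without any external
data: a charged beta-barrel-like stationary body with a designated rim
patch and a mutable "site" residue; a mobile anchor probe with four
labelled anchor residues; Gaussian z-samples emulating a membrane-bound
residue's fluctuations (the input to Boltzmann inversion); piecewise
ion z-tracks realising an exact schedule of complete crossings and
feints; and atom-built cylindrical pores of known radius with an
optional partially occluding cap.

All generators are pure functions of (spec, seed).  Scales are chosen
so a full association run finishes in about a minute on one CPU while
preserving the geometry ratios of a membrane channel system: barrel
radius 15 A and height 35 A (a beta-barrel channel scale), a 20-atom
anchor probe, and a 60 A confinement wall standing in for the
production 150 A wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rigidbd.constants import KB_KCAL
from rigidbd.channel_analysis import IonTrack
from rigidbd.io_formats import AtomRecord, Structure
from rigidbd.restraints import ZSampleSet

__all__ = [
    "ToyBodySpec",
    "make_toy_barrel",
    "make_anchor_probe",
    "sample_anchored_z",
    "make_ion_tracks",
    "make_cylinder_pore",
    "ANCHOR_LABELS",
]

ANCHOR_LABELS = ("M1", "F10", "N15", "Q20")
"""Labels of the four anchor residues carrying z-restraints."""


@dataclass(frozen=True)
class ToyBodySpec:
    """Parameters of a synthetic rigid body.

    ``kind`` selects barrel (stationary) or anchor-probe (mobile).
    Barrel geometry: cylindrical lattice of ``n_rings`` rings of
    ``n_per_ring`` atoms at ``radius``; the top ring is the "rim".
    ``patch_center_deg``/``patch_halfwidth_deg`` select a rim arc that
    shares ``patch_charge`` (e) equally among its atoms; one rim atom at
    ``site_angle_deg`` forms the mutable site residue (residue id
    ``site_residue_id``) used by perturbation rescoring.  Probe
    geometry: ``n_atoms`` on a helix of ``helix_radius`` and ``pitch``;
    ``probe_charge`` is shared equally by all probe atoms.
    """

    kind: str = "barrel"
    radius: float = 15.0
    height: float = 35.0
    n_rings: int = 12
    n_per_ring: int = 36
    patch_center_deg: float = 0.0
    patch_halfwidth_deg: float = 25.0
    patch_charge: float = 0.0
    site_angle_deg: float = 0.0
    site_residue_id: int = 215
    n_atoms: int = 20
    helix_radius: float = 2.3
    pitch: float = 1.5
    probe_charge: float = 0.0
    # the probe's charge lives on a contiguous bead segment (fractional
    # start/stop of the helix), emulating a charged interaction segment on
    # an otherwise hydrophobic anchor helix
    charge_segment: tuple[float, float] = (0.35, 0.65)
    # bead nonbonded defaults: Rmin/2 of 1.3 A puts the LJ pair minimum at
    # 2.6 A, inside the 3 A atomic-contact cutoff, so bound poses register
    # as contacts; the barrel lattice (36 per ring, 12 rings) is denser than
    # one bead diameter so the probe cannot slip through the wall
    lj_rmin_half: float = 1.3
    lj_epsilon: float = 0.1
    vdw_radius: float = 1.3
    seed: int = 0


def _angdiff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def make_toy_barrel(spec: ToyBodySpec) -> Structure:
    """A barrel-like stationary body on a cylindrical lattice.

    Alternating C/N/O/H-flavoured atoms give all three LJ categories
    members.  The top ring is the rim; patch atoms carry the charge
    pattern, and the rim atom nearest ``site_angle_deg`` becomes the
    single-atom "site" residue targeted by phosphomimetic rescoring.
    """
    if spec.radius <= 0 or spec.height <= 0:
        raise ValueError("barrel radius and height must be > 0")
    if spec.n_per_ring < 6:
        raise ValueError("n_per_ring too small to close the cylinder")
    elements = ("C", "N", "O", "H")
    atoms = []
    serial = 1
    rim_ring = spec.n_rings - 1
    angles = 360.0 * np.arange(spec.n_per_ring) / spec.n_per_ring
    patch_members = [
        j for j in range(spec.n_per_ring)
        if _angdiff(angles[j], spec.patch_center_deg) <= spec.patch_halfwidth_deg
    ]
    site_member = int(np.argmin([_angdiff(a, spec.site_angle_deg) for a in angles]))
    for i in range(spec.n_rings):
        z = -spec.height / 2.0 + spec.height * i / max(1, spec.n_rings - 1)
        for j in range(spec.n_per_ring):
            theta = np.radians(angles[j])
            charge = 0.0
            resname, resid = "BAR", i + 1
            if i == rim_ring:
                resname, resid = "RIM", 100 + j
                if j in patch_members and spec.patch_charge != 0.0:
                    charge = spec.patch_charge / len(patch_members)
                if j == site_member:
                    resname, resid = "SIT", spec.site_residue_id
            atoms.append(AtomRecord(
                serial=serial,
                name=f"X{j}",
                element=elements[(i + j) % len(elements)],
                residue_name=resname,
                residue_id=resid,
                chain="S",
                position=(spec.radius * np.cos(theta), spec.radius * np.sin(theta), z),
                charge=charge,
                lj_rmin_half=spec.lj_rmin_half,
                lj_epsilon=spec.lj_epsilon,
                vdw_radius=spec.vdw_radius,
            ))
            serial += 1
    return Structure(atoms, title=f"toy barrel seed={spec.seed}")


def make_anchor_probe(spec: ToyBodySpec) -> tuple[Structure, dict[str, int]]:
    """A helical mobile probe with four labelled anchor residues.

    Atoms sit on a helix along z (radius ``helix_radius``, axial rise
    ``pitch`` per atom); residues 1, 10, 15 and 20 are the anchors,
    mirroring the anchor-helix residues that carry z-restraints.
    Returns the structure and a map label -> atom index.
    """
    if spec.n_atoms < 20:
        raise ValueError("anchor probe needs at least 20 atoms for the 4 anchors")
    elements = ("C", "N", "O", "H")
    lo = int(np.floor(spec.charge_segment[0] * spec.n_atoms))
    hi = max(lo + 1, int(np.ceil(spec.charge_segment[1] * spec.n_atoms)))
    charged = set(range(lo, min(hi, spec.n_atoms)))
    per_atom_charge = spec.probe_charge / len(charged)
    anchor_residue_numbers = {"M1": 1, "F10": 10, "N15": 15, "Q20": 20}
    atoms = []
    for i in range(spec.n_atoms):
        theta = 2.0 * np.pi * i / 3.6  # ~3.6 atoms per turn, helix-like
        z = spec.pitch * (i - (spec.n_atoms - 1) / 2.0)
        atoms.append(AtomRecord(
            serial=i + 1,
            name=f"P{i}",
            element=elements[i % len(elements)],
            residue_name="PRB",
            residue_id=i + 1,
            chain="M",
            position=(spec.helix_radius * np.cos(theta),
                      spec.helix_radius * np.sin(theta), z),
            charge=per_atom_charge if i in charged else 0.0,
            lj_rmin_half=spec.lj_rmin_half,
            lj_epsilon=spec.lj_epsilon,
            vdw_radius=spec.vdw_radius,
        ))
    structure = Structure(atoms, title=f"anchor probe seed={spec.seed}")
    anchors = {label: num - 1 for label, num in anchor_residue_numbers.items()}
    return structure, anchors


def sample_anchored_z(k: float, z0: float, n: int, temperature: float = 310.0,
                      seed: int = 0, residue_label: str = "M1") -> ZSampleSet:
    """Gaussian z-samples of a harmonically anchored residue.

    Equipartition in a well of stiffness ``k`` (kcal/mol/A^2) gives
    variance k_B T / k about ``z0``; these samples stand in for the
    z-trace of a membrane-anchored residue in equilibrium.
    """
    if k <= 0 or temperature <= 0 or n <= 0:
        raise ValueError("k, temperature and n must be > 0")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(KB_KCAL * temperature / k)
    return ZSampleSet(residue_label=residue_label,
                      samples=z0 + sigma * rng.standard_normal(n),
                      temperature=temperature)


def make_ion_tracks(schedule, slab=(-20.0, 20.0), noise: float = 0.5,
                    seed: int = 0, samples_per_leg: int = 40,
                    margin: float = 10.0) -> list[tuple[IonTrack, tuple[int, int]]]:
    """Piecewise ion z-tracks realising an exact crossing schedule.

    ``schedule`` is a list of (species, n_up, n_down, n_feints); each
    ion's track is a sequence of legs: a full up-crossing runs from
    ``slab[0] - margin`` to ``slab[1] + margin`` (down the reverse), a
    feint enters from the current side to the slab midplane and
    retreats.  Gaussian noise of scale ``noise`` is added but clipped
    to less than half of the smallest threshold margin so the scheduled
    counts stay exact ground truth.  Returns (track, (n_up, n_down))
    pairs.
    """
    lo, hi = slab
    if not lo < hi:
        raise ValueError("slab lower bound must be below upper bound")
    half = (hi - lo) / 2.0
    clip = 0.45 * min(margin, half)
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    mid = (lo + hi) / 2.0
    out = []
    for ion_id, (species, n_up, n_down, n_feints) in enumerate(schedule):
        side = -1  # start below
        z_points = [lo - margin]
        legs = (["up"] * n_up) + (["down"] * n_down)
        rng.shuffle(legs)
        feints_left = n_feints
        track_legs = []
        for leg in legs:
            # interleave feints before crossings while any remain
            if feints_left > 0:
                track_legs.append("feint")
                feints_left -= 1
            track_legs.append(leg)
        track_legs.extend(["feint"] * feints_left)
        for leg in track_legs:
            start = z_points[-1]
            if leg == "feint":
                target = mid
                back = (lo - margin) if side < 0 else (hi + margin)
                z_points.extend(np.linspace(start, target, samples_per_leg)[1:])
                z_points.extend(np.linspace(target, back, samples_per_leg)[1:])
            elif leg == "up":
                if side > 0:
                    # teleport: a single-sample jump across the slab is not a
                    # crossing (no sample inside), so it resets the side freely
                    z_points.append(lo - margin)
                    side = -1
                z_points.extend(np.linspace(z_points[-1], hi + margin,
                                            2 * samples_per_leg)[1:])
                side = 1
            else:  # down
                if side < 0:
                    z_points.append(hi + margin)
                    side = 1
                z_points.extend(np.linspace(z_points[-1], lo - margin,
                                            2 * samples_per_leg)[1:])
                side = -1
        if len(z_points) < samples_per_leg:  # idle ion: dwell on its side
            z_points.extend([z_points[-1]] * (samples_per_leg - len(z_points)))
        z = np.asarray(z_points, dtype=float)
        if noise > 0:
            z = z + np.clip(noise * rng.standard_normal(z.size), -clip, clip)
        track = IonTrack(ion_id=ion_id, species=species, z=z, slab=(lo, hi))
        out.append((track, (n_up, n_down)))
    return out


def make_cylinder_pore(radius: float = 12.0, atom_vdw: float = 1.7,
                       z_height: float = 30.0, ring_spacing: float = 1.0,
                       cap_fraction: float = 0.0, seed: int = 0) -> Structure:
    """An atom-built cylindrical pore of known interior radius.

    Atoms tile the cylinder wall on rings ``ring_spacing`` apart, so
    the clash-free probe radius at any interior z is ``radius -
    atom_vdw`` (up to the ring discretisation).  ``cap_fraction`` in
    [0, 1] adds an annular cap at the top mouth occluding that fraction
    of the aperture area: 1 seals the mouth completely, intermediate
    values narrow it to ``radius * sqrt(1 - cap_fraction)``.
    """
    if radius <= 0 or z_height <= 0 or ring_spacing <= 0:
        raise ValueError("radius, z_height and ring_spacing must be > 0")
    if not 0.0 <= cap_fraction <= 1.0:
        raise ValueError("cap_fraction must be in [0, 1]")
    n_rings = int(np.floor(z_height / ring_spacing)) + 1
    n_per_ring = max(6, int(np.ceil(2.0 * np.pi * radius / ring_spacing)))
    atoms = []
    serial = 1
    for i in range(n_rings):
        z = -z_height / 2.0 + i * ring_spacing
        for j in range(n_per_ring):
            theta = 2.0 * np.pi * j / n_per_ring
            atoms.append(AtomRecord(
                serial=serial, name=f"W{j}", element="C", residue_name="CYL",
                residue_id=i + 1, chain="P",
                position=(radius * np.cos(theta), radius * np.sin(theta), z),
                vdw_radius=atom_vdw,
            ))
            serial += 1
    if cap_fraction > 0.0:
        r_inner = radius * np.sqrt(1.0 - cap_fraction)
        z_cap = z_height / 2.0
        r = radius
        resid = n_rings + 1
        while r >= max(r_inner, 1e-6):
            n_cap = max(6, int(np.ceil(2.0 * np.pi * r / ring_spacing)))
            for j in range(n_cap):
                theta = 2.0 * np.pi * j / n_cap
                atoms.append(AtomRecord(
                    serial=serial, name=f"K{j}", element="C", residue_name="CAP",
                    residue_id=resid, chain="P",
                    position=(r * np.cos(theta), r * np.sin(theta), z_cap),
                    vdw_radius=atom_vdw,
                ))
                serial += 1
            resid += 1
            r -= ring_spacing
        if cap_fraction >= 1.0:
            atoms.append(AtomRecord(
                serial=serial, name="K0", element="C", residue_name="CAP",
                residue_id=resid, chain="P", position=(0.0, 0.0, z_cap),
                vdw_radius=atom_vdw,
            ))
    return Structure(atoms, title=f"cylinder pore R={radius} cap={cap_fraction}")
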