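"""Membrane anchoring restraints and lateral confinement.

The membrane is not represented explicitly during Brownian dynamics.
Its effect on the mobile body enters through (i) one-dimensional
grid-based potentials U(z) coupled to named anchor residues, obtained
by Boltzmann inversion of the z-coordinate distribution those residues
sample in membrane-bound simulations, and (ii) a circular harmonic
wall (default radius 150 A) that confines the lateral search space
around the stationary body.  Frames are made commensurate by shifting
the mobile body so the two membrane midplanes coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rigidbd.constants import KB_KCAL

__all__ = [
    "ZSampleSet",
    "ZPotential",
    "RestraintSet",
    "boltzmann_invert",
    "wall_force",
    "wall_energy",
    "align_membrane_frames",
]


@dataclass
class ZSampleSet:
    """z-coordinate samples (A, relative to the membrane midplane) for one residue."""

    residue_label: str
    samples: np.ndarray
    temperature: float = 310.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"{self.residue_label}: non-finite z samples")


@dataclass
class ZPotential:
    """A 1-D potential U(z) on uniform bins, linear beyond its support.

    ``values`` holds U (kcal/mol, min shifted to 0) at bin centres
    ``z_min + bin_width * (i + 0.5)``.  Outside the sampled support the
    potential continues with the linear slope of the respective edge,
    so the force field is defined everywhere without infinite walls.
    """

    z_min: float
    bin_width: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.values.size < 2:
            raise ValueError("potential needs at least two bins")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("potential values must be finite")
        self._centers = self.z_min + self.bin_width * (np.arange(self.values.size) + 0.5)
        self._slopes = np.diff(self.values) / self.bin_width

    @property
    def centers(self) -> np.ndarray:
        return self._centers

    def energy(self, z) -> np.ndarray:
        """U(z), linearly interpolated between bin centres."""
        z = np.asarray(z, dtype=float)
        c = self._centers
        lo_slope, hi_slope = self._slopes[0], self._slopes[-1]
        inner = np.interp(z, c, self.values)
        below = self.values[0] + lo_slope * (z - c[0])
        above = self.values[-1] + hi_slope * (z - c[-1])
        return np.where(z < c[0], below, np.where(z > c[-1], above, inner))

    def force(self, z):
        """-dU/dz (kcal/mol/A), piecewise constant between bin centres."""
        c = self._centers
        slopes = self._slopes
        if np.ndim(z) == 0:
            zf = float(z)
            if zf < c[0]:
                return -float(slopes[0])
            if zf > c[-1]:
                return -float(slopes[-1])
            seg = min(max(int(np.searchsorted(c, zf)) - 1, 0), slopes.size - 1)
            return -float(slopes[seg])
        z = np.asarray(z, dtype=float)
        seg = np.clip(np.searchsorted(c, z) - 1, 0, slopes.size - 1)
        dudz = slopes[seg]
        dudz = np.where(z < c[0], slopes[0], np.where(z > c[-1], slopes[-1], dudz))
        return -dudz


@dataclass
class RestraintSet:
    """Per-anchor z-potentials plus the circular confinement wall.

    ``anchors`` maps residue labels to (body-frame offset from the COM,
    z-potential); the restraint force acts on the instantaneous world-z
    of the rotated anchor point, and its torque uses the anchor's lever
    arm about the COM like any other grid force.
    """

    anchors: dict[str, tuple[np.ndarray, ZPotential]] = field(default_factory=dict)
    wall_radius: float = 150.0
    wall_stiffness: float = 10.0

    def __post_init__(self) -> None:
        if self.wall_radius <= 0:
            raise ValueError("wall_radius must be > 0")
        if self.wall_stiffness < 0:
            raise ValueError("wall_stiffness must be >= 0")
        self.anchors = {
            k: (np.asarray(off, dtype=float), pot) for k, (off, pot) in self.anchors.items()
        }


def boltzmann_invert(samples: ZSampleSet, bin_width: float = 0.5,
                     pseudocount: float = 1.0) -> ZPotential:
    """Invert a z-coordinate distribution into a potential of mean force.

    U(z) = -k_B T ln p(z), with p estimated by a histogram of the given
    bin width; empty interior bins (between the first and last occupied
    bin) receive ``pseudocount`` counts so the log stays finite; the
    minimum is shifted to zero.
    """
    if samples.temperature <= 0:
        raise ValueError("temperature must be > 0")
    z = samples.samples
    if z.size < 100:
        raise ValueError(f"{samples.residue_label}: need >= 100 samples, got {z.size}")
    span = z.max() - z.min()
    if span == 0:
        raise ValueError(f"{samples.residue_label}: zero-width z distribution")
    nbins = max(2, int(np.ceil(span / bin_width)))
    counts, edges = np.histogram(z, bins=nbins, range=(z.min(), z.min() + nbins * bin_width))
    occupied = np.nonzero(counts)[0]
    interior = slice(occupied[0], occupied[-1] + 1)
    inner = counts[interior].astype(float)
    inner[inner == 0] = pseudocount
    p = inner / inner.sum()
    u = -KB_KCAL * samples.temperature * np.log(p)
    u -= u.min()
    return ZPotential(z_min=float(edges[occupied[0]]), bin_width=bin_width, values=u)


def wall_force(position, wall_radius: float = 150.0, stiffness: float = 10.0) -> np.ndarray:
    """Inward harmonic restoring force beyond the lateral wall radius.

    Zero for lateral distance r <= wall_radius; otherwise a radial force
    of magnitude stiffness * (r - wall_radius) pointing back toward the
    axis.  Continuous at the wall.
    """
    if stiffness < 0:
        raise ValueError("stiffness must be >= 0")
    position = np.asarray(position, dtype=float)
    r = float(np.hypot(position[0], position[1]))
    if r <= wall_radius or r == 0.0:
        return np.zeros(3)
    mag = stiffness * (r - wall_radius)
    return np.array([-mag * position[0] / r, -mag * position[1] / r, 0.0])


def wall_energy(position, wall_radius: float = 150.0, stiffness: float = 10.0) -> float:
    """Harmonic wall energy 0.5 k (r - R)^2 outside the wall, else 0."""
    position = np.asarray(position, dtype=float)
    r = float(np.hypot(position[0], position[1]))
    if r <= wall_radius:
        return 0.0
    return 0.5 * stiffness * (r - wall_radius) ** 2


def align_membrane_frames(mobile_midplane_z: float, stationary_midplane_z: float) -> float:
    """z-shift to apply to the mobile body so the membrane midplanes coincide."""
    if not (np.isfinite(mobile_midplane_z) and np.isfinite(stationary_midplane_z)):
        raise ValueError("midplane z-coordinates must be finite")
    return float(stationary_midplane_z - mobile_midplane_z)
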