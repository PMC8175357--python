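"""Channel permeation and geometry analysis.

Complete-crossing counting over a membrane slab, ionic current
I = N q / tau from the net crossing counts, largest-clash-free-probe
pore-radius profiles along a channel axis, and geometric hydrogen-bond
detection.  These operate on plain ion-track tables and atomic
structures; the simulations that produce them are external.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from rigidbd.constants import ELEMENTARY_CHARGE_C
from rigidbd.io_formats import Structure

__all__ = [
    "IonTrack",
    "CurrentResult",
    "PoreProfile",
    "ION_CHARGES",
    "count_crossings",
    "compute_current",
    "cumulative_crossings",
    "pore_profile",
    "hydrogen_bonds",
]

ION_CHARGES = {"Na+": 1.0, "Cl-": -1.0, "K+": 1.0, "Ca2+": 2.0}
"""Ion charge in units of e, by species label."""


@dataclass
class IonTrack:
    """One ion's z-coordinate time series and the membrane slab it may cross."""

    ion_id: int
    species: str
    z: np.ndarray
    slab: tuple[float, float]
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(self.z)):
            raise ValueError(f"ion {self.ion_id}: non-finite z coordinate")
        lo, hi = self.slab
        if not lo < hi:
            raise ValueError("slab lower bound must be below upper bound")
        if self.species not in ION_CHARGES:
            raise ValueError(f"unknown ion species {self.species!r}")

    @property
    def charge(self) -> float:
        return ION_CHARGES[self.species]


@dataclass
class CurrentResult:
    """Crossing counts per species and the resulting ionic current.

    ``counts`` maps species to (N_up, N_down); ``net`` to N_up - N_down.
    The sign convention is that an upward (+z) crossing of a positive
    ion contributes positive current.  ``current_A`` per species and
    ``total_A`` are in amperes.
    """

    counts: dict[str, tuple[int, int]]
    net: dict[str, int]
    tau: float  # seconds
    current_A: dict[str, float]
    total_A: float

    @property
    def total_pA(self) -> float:
        return self.total_A * 1e12


def _crossing_events(z: np.ndarray, slab: tuple[float, float]) -> list[tuple[int, int]]:
    """(sample index, direction) of each complete crossing of the slab.

    Three-state machine over {below, inside, above}: a crossing is
    registered only on below -> inside -> above (+1) or above ->
    inside -> below (-1).  Entries that retreat to the same side count
    nothing, and so does a discrete jump straight across the slab with
    no sample inside it.
    """
    lo, hi = slab
    region = np.where(z < lo, -1, np.where(z > hi, 1, 0))
    events: list[tuple[int, int]] = []
    prev = int(region[0])
    entered_from: int | None = None
    for k in range(1, region.size):
        r = int(region[k])
        if r == prev:
            continue
        if r == 0:
            entered_from = prev  # prev is +-1 here
        else:
            if prev == 0 and entered_from == -r:
                events.append((k, r))
            entered_from = None
        prev = r
    return events


def count_crossings(track: IonTrack) -> tuple[int, int]:
    """Count complete membrane crossings of one ion.

    An ion is below, inside or above the slab; a crossing is counted
    only when it traverses the whole slab — entering from one side and
    leaving on the other.  Entries that return to the same side
    (feints) count nothing.
    """
    if track.z.size < 2:
        raise ValueError("track must span at least 2 time points")
    events = _crossing_events(track.z, track.slab)
    n_up = sum(1 for _, d in events if d > 0)
    n_down = sum(1 for _, d in events if d < 0)
    return (n_up, n_down)


def compute_current(counts: dict[str, tuple[int, int]], tau: float) -> CurrentResult:
    """Ionic current from per-species crossing counts over interval tau (s).

    I_s = net_N_s * q_s / tau with q_s the signed ionic charge
    (+1.60217662e-19 C for Na+, the negative for Cl-) and net counts
    signed by direction (up = +); the total is the sum over species.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    net = {}
    current = {}
    for species, (n_up, n_down) in counts.items():
        if species not in ION_CHARGES:
            raise ValueError(f"unknown ion species {species!r}")
        n = n_up - n_down
        net[species] = n
        current[species] = n * ION_CHARGES[species] * ELEMENTARY_CHARGE_C / tau
    return CurrentResult(counts=dict(counts), net=net, tau=tau,
                         current_A=current, total_A=float(sum(current.values())))


def cumulative_crossings(tracks: list[IonTrack]) -> dict[str, np.ndarray]:
    """Per-species cumulative net crossings indexed by time sample.

    All tracks must share the same sampling; the result for each
    species is an array whose k-th entry is the net number of completed
    crossings up to sample k (the integrand of the current estimate).
    """
    if not tracks:
        return {}
    n = tracks[0].z.size
    out: dict[str, np.ndarray] = {}
    for track in tracks:
        if track.z.size != n:
            raise ValueError("all tracks must share the same sampling")
        series = np.zeros(n)
        for k, direction in _crossing_events(track.z, track.slab):
            series[k:] += direction
        acc = out.setdefault(track.species, np.zeros(n))
        acc += series
    return out


# ---------------------------------------------------------------------------
# pore geometry


@dataclass
class PoreProfile:
    """Largest clash-free probe radius along the pore axis.

    ``radius[i]`` is the radius (A) of the biggest sphere centred on
    the optimised pore centre at ``z[i]`` that touches no atom's van
    der Waals sphere; slices where the pore opens to bulk are clamped
    at ``clamp_radius`` and flagged.
    """

    z: np.ndarray
    radius: np.ndarray
    centers: np.ndarray
    clamp_radius: float
    clamped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if self.clamped is None:
            self.clamped = self.radius >= self.clamp_radius
        if np.any(self.radius < 0):
            raise ValueError("pore radius must be >= 0")

    @property
    def min_radius(self) -> float:
        return float(self.radius.min())


def _clearance(center_xy, z, positions, vdw) -> float:
    d = np.sqrt((positions[:, 0] - center_xy[0]) ** 2
                + (positions[:, 1] - center_xy[1]) ** 2
                + (positions[:, 2] - z) ** 2)
    return float(np.min(d - vdw))


def pore_profile(structure: Structure, axis_xy=None, z_range=None,
                 z_step: float = 1.0, lateral_search: float = 0.5,
                 search_halfwidth: float = 6.0,
                 clamp_radius: float = 15.0) -> PoreProfile:
    """Pore-radius profile by maximising the clash-free probe radius per slice.

    At each z the probe centre is optimised in the membrane plane: a
    coarse 2-D grid search (``lateral_search`` spacing, window of
    ``search_halfwidth`` around the seed) followed by Nelder-Mead
    refinement; each slice's optimum seeds the next, so the centre line
    tracks a curved pore.  The clash-free radius at a centre c is
    min_i(|c - x_i| - vdw_i) over all atoms (full 3-D distances).
    Radii are clamped at ``clamp_radius`` where the pore opens to bulk.
    """
    positions = structure.positions
    vdw = structure.vdw_radii
    if z_range is None:
        z_range = (positions[:, 2].min(), positions[:, 2].max())
    z_values = np.arange(z_range[0], z_range[1] + 0.5 * z_step, z_step)
    if axis_xy is None:
        seed = positions[:, :2].mean(axis=0)
    else:
        seed = np.asarray(axis_xy, dtype=float)

    radii = np.empty(z_values.size)
    centers = np.empty((z_values.size, 2))
    clamped = np.zeros(z_values.size, dtype=bool)
    offsets = np.arange(-search_halfwidth, search_halfwidth + 0.5 * lateral_search,
                        lateral_search)
    for k, z in enumerate(z_values):
        near = np.abs(positions[:, 2] - z) <= clamp_radius + vdw.max()
        if not near.any():
            radii[k] = clamp_radius
            centers[k] = seed
            clamped[k] = True
            continue
        pos_k = positions[near]
        vdw_k = vdw[near]
        # coarse grid around the running seed
        gx = seed[0] + offsets
        gy = seed[1] + offsets
        gxx, gyy = np.meshgrid(gx, gy, indexing="ij")
        pts = np.stack([gxx.ravel(), gyy.ravel()], axis=1)
        d = np.sqrt((pts[:, None, 0] - pos_k[None, :, 0]) ** 2
                    + (pts[:, None, 1] - pos_k[None, :, 1]) ** 2
                    + (z - pos_k[None, :, 2]) ** 2)
        clearance = np.min(d - vdw_k[None, :], axis=1)
        best = int(np.argmax(clearance))
        c0 = pts[best]
        res = minimize(lambda c: -_clearance(c, z, pos_k, vdw_k), c0,
                       method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 200})
        r = max(0.0, -res.fun)
        if r >= clamp_radius:
            radii[k] = clamp_radius
            clamped[k] = True
            centers[k] = res.x
        else:
            radii[k] = r
            centers[k] = res.x
            seed = res.x  # track the pore centre line
    return PoreProfile(z=z_values, radius=radii, centers=centers,
                       clamp_radius=clamp_radius, clamped=clamped)


# ---------------------------------------------------------------------------
# hydrogen bonds


def hydrogen_bonds(structure: Structure, donor_pairs=None, acceptors=None,
                   da_cutoff: float = 3.0, dha_min_angle: float = 120.0,
                   covalent_dh: float = 1.25) -> list[tuple[int, int, int]]:
    """Geometric hydrogen bonds: D-A < cutoff and D-H-A angle above minimum.

    ``donor_pairs`` is a list of (donor_index, hydrogen_index); if None,
    donors are detected as N/O atoms with a hydrogen within
    ``covalent_dh`` A (donors without any H are skipped with a
    warning).  ``acceptors`` defaults to all N/O atoms.  The angle is
    measured at H between the H->D and H->A directions.  Returns
    (donor, hydrogen, acceptor) index triples.
    """
    pos = structure.positions
    elements = structure.elements
    electroneg = np.nonzero(np.isin(elements, ("N", "O", "F")))[0]
    if acceptors is None:
        acceptors = electroneg
    acceptors = np.asarray(acceptors, dtype=int)

    if donor_pairs is None:
        hydrogens = np.nonzero(elements == "H")[0]
        donor_pairs = []
        for d in electroneg:
            if hydrogens.size == 0:
                dists = np.array([])
            else:
                dists = np.linalg.norm(pos[hydrogens] - pos[d], axis=1)
            attached = hydrogens[dists <= covalent_dh] if dists.size else []
            if len(attached) == 0:
                warnings.warn(
                    f"donor atom {structure.atoms[d].serial} has no bound hydrogen; skipped"
                )
                continue
            for h in attached:
                donor_pairs.append((int(d), int(h)))

    bonds = []
    for d, h in donor_pairs:
        for a in acceptors:
            if a == d or a == h:
                continue
            da = np.linalg.norm(pos[a] - pos[d])
            if da >= da_cutoff:
                continue
            v_hd = pos[d] - pos[h]
            v_ha = pos[a] - pos[h]
            denom = np.linalg.norm(v_hd) * np.linalg.norm(v_ha)
            if denom < 1e-12:
                continue
            angle = np.degrees(np.arccos(np.clip(np.dot(v_hd, v_ha) / denom, -1, 1)))
            if angle > dha_min_angle:
                bonds.append((int(d), int(h), int(a)))
    return bonds
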