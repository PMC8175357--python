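"""Potential and density grids defining the rigid-body force field.

The stationary body is represented by scalar potential maps on a
regular grid: one electrostatic map (kcal/(mol e)) and one
Lennard-Jones map per collapsed atom category (kcal/mol).  The mobile
body is represented by density grids: charge per cell and LJ-particle
count per cell and category.  During propagation each occupied density
cell feels the local force ``-rho * grad V`` from the matching
potential map; this module provides the map builders and the trilinear
interpolation / gradient kernel those forces are based on.

LJ parameters are collapsed into three element categories — all
hydrogens; oxygen + nitrogen; carbon + sulfur — each carrying the
arithmetic mean Rmin and mean epsilon scaled down (default 0.3) to
avoid artificial stickiness of rigid bodies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from rigidbd.constants import COULOMB_KCAL, DEBYE_CONST
from rigidbd.io_formats import GridMap, Structure

__all__ = [
    "LJCategory",
    "MapSet",
    "DensitySet",
    "CATEGORY_ELEMENTS",
    "collapse_lj_categories",
    "categorize_atoms",
    "make_frame",
    "frame_around",
    "deposit_density",
    "screened_coulomb_map",
    "lj_potential_map",
    "interpolate",
    "gradient",
]

CATEGORY_ELEMENTS: dict[str, tuple[str, ...]] = {
    "H": ("H",),
    "O,N": ("O", "N"),
    "C,S": ("C", "S"),
}


@dataclass(frozen=True)
class LJCategory:
    """One collapsed LJ atom class.

    ``rmin_mean`` is the mean of the member atoms' full Rmin (A, i.e.
    2 x Rmin/2) and ``eps_scaled`` the mean well depth multiplied by the
    softening scale factor (kcal/mol).
    """

    label: str
    rmin_mean: float
    eps_scaled: float
    n_members: int


@dataclass
class MapSet:
    """Stationary-body potential maps sharing one grid frame."""

    elec_potential: GridMap
    lj_potential: dict[str, GridMap]
    provenance: str = "internal-screened-coulomb"

    def __post_init__(self) -> None:
        for label, m in self.lj_potential.items():
            if not m.same_frame(self.elec_potential):
                raise ValueError(f"LJ map {label!r} frame differs from electrostatic map")


@dataclass
class DensitySet:
    """Mobile-body density grids in the body frame (COM at the origin)."""

    charge_density: GridMap
    lj_density: dict[str, GridMap]
    # compact nonzero-cell representation used by the propagator:
    # (cell centres in the body frame, per-cell weights)
    charge_cells: tuple[np.ndarray, np.ndarray] = field(default=None, repr=False)  # type: ignore[assignment]
    lj_cells: dict[str, tuple[np.ndarray, np.ndarray]] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.charge_cells is None:
            self.charge_cells = _nonzero_cells(self.charge_density)
        if self.lj_cells is None:
            self.lj_cells = {k: _nonzero_cells(m) for k, m in self.lj_density.items()}


def _nonzero_cells(grid_map: GridMap) -> tuple[np.ndarray, np.ndarray]:
    idx = np.argwhere(grid_map.values != 0.0)
    points = grid_map.origin + idx * grid_map.spacing
    weights = grid_map.values[tuple(idx.T)]
    return points, weights


# ---------------------------------------------------------------------------
# LJ category collapsing


def categorize_atoms(structure: Structure) -> dict[str, np.ndarray]:
    """Indices of atoms belonging to each of the three element classes."""
    elements = structure.elements
    out: dict[str, np.ndarray] = {}
    assigned = np.zeros(len(structure), dtype=bool)
    for label, members in CATEGORY_ELEMENTS.items():
        mask = np.isin(elements, members)
        out[label] = np.nonzero(mask)[0]
        assigned |= mask
    if not assigned.all():
        bad = int(np.nonzero(~assigned)[0][0])
        atom = structure.atoms[bad]
        raise ValueError(
            f"atom {atom.serial} has element {atom.element!r}; only H, O, N, C, S "
            "can be collapsed into LJ categories"
        )
    return out


def collapse_lj_categories(structure: Structure, scale: float = 0.3) -> list[LJCategory]:
    """Collapse per-atom LJ parameters into three element categories.

    Each category gets the arithmetic mean of the member atoms' Rmin
    (2 x Rmin/2) and of their well-depth magnitudes; the mean well
    depth is multiplied by ``scale`` (default 0.3) to soften rigid-body
    sticking.  Empty categories are retained with zero members.
    """
    indices = categorize_atoms(structure)
    cats = []
    for label, idx in indices.items():
        if idx.size == 0:
            warnings.warn(f"LJ category {label!r} has no member atoms; its map will be skipped")
            cats.append(LJCategory(label=label, rmin_mean=0.0, eps_scaled=0.0, n_members=0))
            continue
        rmin_mean = float(np.mean(2.0 * structure.lj_rmin_half[idx]))
        eps_mean = float(np.mean(np.abs(structure.lj_epsilon[idx])))
        cats.append(
            LJCategory(label=label, rmin_mean=rmin_mean,
                       eps_scaled=eps_mean * scale, n_members=int(idx.size))
        )
    return cats


# ---------------------------------------------------------------------------
# grid frames and deposition


def make_frame(origin, spacing, shape, unit: str = "", out_of_bounds: str = "zero") -> GridMap:
    """An empty grid with the given geometry."""
    shape = tuple(int(s) for s in shape)
    return GridMap(origin=np.asarray(origin, dtype=float),
                   spacing=spacing, values=np.zeros(shape),
                   unit=unit, out_of_bounds=out_of_bounds)


def frame_around(structure: Structure, spacing: float = 1.0, margin: float = 2.0,
                 center=None) -> GridMap:
    """A grid frame covering a structure with the given margin (A)."""
    lo = structure.positions.min(axis=0) - margin
    hi = structure.positions.max(axis=0) + margin
    if center is not None:
        center = np.asarray(center, dtype=float)
        half = np.maximum(np.abs(lo - center), np.abs(hi - center))
        lo, hi = center - half, center + half
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    return make_frame(lo, spacing, shape)


def deposit_density(structure: Structure, prop: str, frame: GridMap,
                    category_indices=None) -> GridMap:
    """Deposit per-atom weights onto a grid by cloud-in-cell (trilinear) weighting.

    ``prop`` is ``"charge"`` (weights = partial charges, e per cell) or
    ``"count"`` (weights = 1 per atom, optionally restricted to
    ``category_indices``).  Trilinear deposition conserves the total
    exactly, so the summed grid equals the summed weights to round-off.
    """
    if prop == "charge":
        idx = np.arange(len(structure))
        weights = structure.charges
    elif prop == "count":
        idx = np.arange(len(structure)) if category_indices is None \
            else np.asarray(category_indices, dtype=int)
        weights = np.ones(idx.size)
    else:
        raise ValueError(f"unknown deposition property {prop!r}")

    positions = structure.positions[idx]
    values = np.zeros(frame.shape)
    n = np.array(frame.shape)
    u = (positions - frame.origin) / frame.spacing
    inside = np.all((u >= 0) & (u <= n - 1), axis=1)
    if not inside.all():
        bad = int(np.nonzero(~inside)[0][0])
        raise ValueError(
            f"atom {structure.atoms[idx[bad]].serial} lies outside the deposition grid"
        )
    i0 = np.minimum(np.floor(u).astype(int), n - 2)
    f = u - i0
    for corner in range(8):
        d = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        w = np.prod(np.where(d, f, 1.0 - f), axis=1) * weights
        np.add.at(values, (i0[:, 0] + d[0], i0[:, 1] + d[1], i0[:, 2] + d[2]), w)
    unit = "e per cell" if prop == "charge" else "particles per cell"
    return GridMap(origin=frame.origin, spacing=frame.spacing, values=values,
                   unit=unit, out_of_bounds=frame.out_of_bounds)


# ---------------------------------------------------------------------------
# potential maps


def _node_coords(frame: GridMap) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return tuple(frame.axis_coords(ax) for ax in range(3))  # type: ignore[return-value]


def _atom_box_slices(frame: GridMap, position: np.ndarray, cutoff: float):
    """Index slices of the sub-grid within ``cutoff`` of an atom (bounding box)."""
    lo = np.floor((position - cutoff - frame.origin) / frame.spacing).astype(int)
    hi = np.ceil((position + cutoff - frame.origin) / frame.spacing).astype(int) + 1
    lo = np.clip(lo, 0, np.array(frame.shape))
    hi = np.clip(hi, 0, np.array(frame.shape))
    if np.any(lo >= hi):
        return None
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def screened_coulomb_map(structure: Structure, frame: GridMap,
                         solvent_dielectric: float = 78.0,
                         ionic_strength: float = 0.0,
                         cutoff: float = 34.0,
                         cap: float = 30.0) -> GridMap:
    """Debye-Hueckel electrostatic potential map (kcal/(mol e)).

    V(r) = k_e * sum_i q_i exp(-d_i/lambda_D) / (eps_s d_i) for
    d_i <= cutoff, with lambda_D = 3.04/sqrt(I) A (I in molar; I = 0
    turns screening off).  A uniform-dielectric stand-in for a
    Poisson-Boltzmann map; import a solver-produced DX grid instead when
    a dielectric boundary matters.  Values are clamped to +-cap so cells
    near atom centres stay finite.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    inv_lambda = 0.0 if ionic_strength == 0 else np.sqrt(ionic_strength) / DEBYE_CONST
    values = np.zeros(frame.shape)
    xs, ys, zs = _node_coords(frame)
    for q, pos in zip(structure.charges, structure.positions):
        if q == 0.0:
            continue
        box = _atom_box_slices(frame, pos, cutoff)
        if box is None:
            continue
        dx = xs[box[0]] - pos[0]
        dy = ys[box[1]] - pos[1]
        dz = zs[box[2]] - pos[2]
        d = np.sqrt(dx[:, None, None] ** 2 + dy[None, :, None] ** 2
                    + dz[None, None, :] ** 2)
        with np.errstate(divide="ignore"):
            contrib = COULOMB_KCAL * q * np.exp(-d * inv_lambda) / (solvent_dielectric * d)
        contrib[d > cutoff] = 0.0
        contrib[d < 1e-9] = np.sign(q) * cap
        values[box] += contrib
    np.clip(values, -cap, cap, out=values)
    return GridMap(origin=frame.origin, spacing=frame.spacing, values=values,
                   unit="kcal/(mol e)", out_of_bounds=frame.out_of_bounds)


def lj_potential_map(structure: Structure, category: LJCategory, frame: GridMap,
                     cap: float = 30.0, cutoff: float = 34.0) -> GridMap:
    """Lennard-Jones potential map for one probe category (kcal/mol).

    At each node, U = sum_i eps_ij [(R_ij/d)^12 - 2 (R_ij/d)^6] over
    stationary atoms within the cutoff, with Lorentz-Berthelot
    combination of the category parameters against each atom's own
    (R_ij = Rmin_cat/2 + Rmin_i/2, eps_ij = sqrt(eps_cat eps_i));
    clamped from above at ``cap`` so nodes inside atoms stay finite.
    """
    if cap <= 0:
        raise ValueError("cap must be > 0")
    values = np.zeros(frame.shape)
    xs, ys, zs = _node_coords(frame)
    rmin_half_cat = category.rmin_mean / 2.0
    for rmin_half, eps, pos in zip(structure.lj_rmin_half, structure.lj_epsilon,
                                   structure.positions):
        eps_ij = np.sqrt(category.eps_scaled * eps)
        if eps_ij == 0.0:
            continue
        r_ij = rmin_half_cat + rmin_half
        box = _atom_box_slices(frame, pos, cutoff)
        if box is None:
            continue
        dx = xs[box[0]] - pos[0]
        dy = ys[box[1]] - pos[1]
        dz = zs[box[2]] - pos[2]
        d = np.sqrt(dx[:, None, None] ** 2 + dy[None, :, None] ** 2
                    + dz[None, None, :] ** 2)
        d = np.maximum(d, 1e-6)
        s6 = (r_ij / d) ** 6
        contrib = eps_ij * (s6 * s6 - 2.0 * s6)
        contrib[d > cutoff] = 0.0
        values[box] += contrib
    np.minimum(values, cap, out=values)
    return GridMap(origin=frame.origin, spacing=frame.spacing, values=values,
                   unit="kcal/mol", out_of_bounds=frame.out_of_bounds)


# ---------------------------------------------------------------------------
# trilinear interpolation


def _locate(grid_map: GridMap, points: np.ndarray):
    """Cell indices, fractional offsets and inside-mask for query points."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = np.array(grid_map.shape)
    u = (points - grid_map.origin) / grid_map.spacing
    inside = np.all((u >= 0) & (u <= n - 1), axis=1)
    if grid_map.out_of_bounds == "error" and not inside.all():
        bad = points[~inside][0]
        raise ValueError(f"point {bad} is outside the grid")
    if grid_map.out_of_bounds == "clamp":
        u = np.clip(u, 0, n - 1)
        inside = np.ones(len(points), dtype=bool)
    i0 = np.clip(np.floor(u).astype(int), 0, n - 2)
    f = u - i0
    return i0, f, inside


def interpolate(grid_map: GridMap, points) -> np.ndarray:
    """Trilinear interpolation of the scalar field at one or more points."""
    single = np.asarray(points).ndim == 1
    i0, f, inside = _locate(grid_map, points)
    v = grid_map.values
    out = np.zeros(len(i0))
    for corner in range(8):
        d = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        w = np.prod(np.where(d, f, 1.0 - f), axis=1)
        out += w * v[i0[:, 0] + d[0], i0[:, 1] + d[1], i0[:, 2] + d[2]]
    out[~inside] = 0.0
    return out[0] if single else out


def gradient(grid_map: GridMap, points) -> np.ndarray:
    """Analytic gradient of the trilinear interpolant (per-axis units 1/A).

    Piecewise multilinear: within a cell the derivative along one axis
    is the bilinear interpolation (over the other two axes) of the
    finite differences across that axis, divided by the spacing.
    """
    single = np.asarray(points).ndim == 1
    i0, f, inside = _locate(grid_map, points)
    v = grid_map.values
    corners = np.empty((2, 2, 2, len(i0)))
    for a in range(2):
        for b in range(2):
            for c in range(2):
                corners[a, b, c] = v[i0[:, 0] + a, i0[:, 1] + b, i0[:, 2] + c]
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
    gx = np.zeros(len(i0))
    gy = np.zeros(len(i0))
    gz = np.zeros(len(i0))
    for b in range(2):
        wb = fy if b else 1.0 - fy
        for c in range(2):
            wc = fz if c else 1.0 - fz
            gx += wb * wc * (corners[1, b, c] - corners[0, b, c])
    for a in range(2):
        wa = fx if a else 1.0 - fx
        for c in range(2):
            wc = fz if c else 1.0 - fz
            gy += wa * wc * (corners[a, 1, c] - corners[a, 0, c])
    for a in range(2):
        wa = fx if a else 1.0 - fx
        for b in range(2):
            wb = fy if b else 1.0 - fy
            gz += wa * wb * (corners[a, b, 1] - corners[a, b, 0])
    grad = np.stack([gx, gy, gz], axis=1) / grid_map.spacing
    grad[~inside] = 0.0
    return grad[0] if single else grad
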