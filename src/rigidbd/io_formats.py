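"""Structure, grid and trajectory I/O.

Three interchange formats cover the whole pipeline:

* PQR — whitespace-separated ATOM records carrying per-atom partial
  charge and radius; the primary atomic input because the force field
  needs charge + radius per atom.  Plain PDB is accepted only together
  with a sidecar parameter table mapping (residue_name, atom_name) to
  (charge, Rmin/2, epsilon, vdW radius).
* OpenDX scalar grids ("regular positions, regular connections") for
  every potential and density map, read and written through
  GridDataFormats.  Storage order is z-fastest (the OpenDX convention);
  in-memory arrays are C-ordered with shape (nx, ny, nz) so that a flat
  view reproduces the file order.
* Columnar trajectory text — one row per saved frame with the mobile
  body's centre-of-mass position and orientation quaternion.  Brownian
  poses are rigid-body states, not per-atom frames, so a plain table is
  the right container.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from gridData import Grid

__all__ = [
    "AtomRecord",
    "Structure",
    "GridMap",
    "Trajectory",
    "ParseError",
    "read_pqr",
    "write_pqr",
    "read_pdb",
    "read_param_table",
    "apply_param_table",
    "read_dx",
    "write_dx",
    "read_trajectory",
    "write_trajectory",
]

_QUAT_TOL = 1e-9


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# atomic structures


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, position and nonbonded parameters.

    ``charge`` is the partial charge in units of e; ``lj_rmin_half`` and
    ``lj_epsilon`` are the Lennard-Jones Rmin/2 (A) and well-depth
    magnitude (kcal/mol); ``vdw_radius`` the hard-sphere radius used for
    pore profiling and contact geometry.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str
    position: tuple[float, float, float]
    charge: float = 0.0
    lj_rmin_half: float = 0.0
    lj_epsilon: float = 0.0
    vdw_radius: float = 1.5

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: non-finite position")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be > 0")
        if self.lj_rmin_half < 0 or self.lj_epsilon < 0:
            raise ValueError(f"atom {self.serial}: LJ parameters must be >= 0")


class Structure:
    """An ordered collection of atoms with unique serials.

    Provides vectorised array views (positions, charges, ...) computed
    lazily; bodies in this pipeline are rigid, so the arrays are built
    once and cached.
    """

    def __init__(self, atoms: Sequence[AtomRecord], title: str = ""):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("Structure must contain at least one atom")
        serials = [a.serial for a in atoms]
        if len(set(serials)) != len(serials):
            dup = next(s for s in serials if serials.count(s) > 1)
            raise ValueError(f"duplicate atom serial {dup}")
        self.atoms: list[AtomRecord] = atoms
        self.title = title
        self._cache: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def _array(self, key: str, fn) -> np.ndarray:
        if key not in self._cache:
            self._cache[key] = np.asarray([fn(a) for a in self.atoms])
        return self._cache[key]

    @property
    def positions(self) -> np.ndarray:
        return self._array("positions", lambda a: a.position)

    @property
    def charges(self) -> np.ndarray:
        return self._array("charges", lambda a: a.charge)

    @property
    def lj_rmin_half(self) -> np.ndarray:
        return self._array("lj_rmin_half", lambda a: a.lj_rmin_half)

    @property
    def lj_epsilon(self) -> np.ndarray:
        return self._array("lj_epsilon", lambda a: a.lj_epsilon)

    @property
    def vdw_radii(self) -> np.ndarray:
        return self._array("vdw_radii", lambda a: a.vdw_radius)

    @property
    def elements(self) -> np.ndarray:
        return self._array("elements", lambda a: a.element)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def center_of_geometry(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def select(self, predicate) -> "Structure":
        """Sub-structure of atoms for which ``predicate(atom)`` is true."""
        picked = [a for a in self.atoms if predicate(a)]
        if not picked:
            raise ValueError("selection matched no atoms")
        return Structure(picked, title=self.title)

    def translated(self, shift) -> "Structure":
        shift = np.asarray(shift, dtype=float)
        moved = [
            replace(a, position=tuple(np.asarray(a.position) + shift))
            for a in self.atoms
        ]
        return Structure(moved, title=self.title)


_ELEMENT_FALLBACK = {"CL": "Cl", "NA": "Na", "MG": "Mg", "ZN": "Zn", "FE": "Fe"}


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[:2].upper() in _ELEMENT_FALLBACK:
        return _ELEMENT_FALLBACK[stripped[:2].upper()]
    return stripped[0].upper()


def read_pqr(path) -> Structure:
    """Read a PQR file (whitespace-separated ATOM records).

    The last two numeric columns of each ATOM/HETATM line are taken as
    partial charge (e) and radius (A); LJ fields default to zero and can
    be filled in afterwards from a sidecar table with
    :func:`apply_param_table`.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    title = ""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(("REMARK", "TITLE")):
                if line.startswith("TITLE"):
                    title = line[5:].strip()
                continue
            if not line.startswith(("ATOM", "HETATM")):
                continue
            toks = line.split()
            # ATOM serial name resname [chain] resid x y z charge radius
            if len(toks) not in (10, 11):
                raise ParseError(
                    f"{path.name}:{lineno}: expected 10 or 11 fields, got {len(toks)}"
                )
            try:
                serial = int(toks[1])
                name = toks[2]
                resname = toks[3]
                if len(toks) == 11:
                    chain, resid = toks[4], int(toks[5])
                else:
                    chain, resid = "", int(toks[4])
                x, y, z, charge, radius = (float(t) for t in toks[-5:])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=_guess_element(name),
                    residue_name=resname,
                    residue_id=resid,
                    chain=chain,
                    position=(x, y, z),
                    charge=charge,
                    vdw_radius=radius,
                )
            )
    if not atoms:
        raise ParseError(f"{path.name}: no ATOM records found")
    return Structure(atoms, title=title)


def write_pqr(structure: Structure, path) -> None:
    """Write ATOM records with charge and radius in the last two columns."""
    with open(path, "w") as fh:
        if structure.title:
            fh.write(f"TITLE {structure.title}\n")
        for a in structure.atoms:
            chain = a.chain if a.chain else ""
            fh.write(
                f"ATOM {a.serial:6d} {a.name:<4s} {a.residue_name:<4s} "
                f"{chain + ' ' if chain else ''}{a.residue_id:5d} "
                f"{a.position[0]:12.6f} {a.position[1]:12.6f} {a.position[2]:12.6f} "
                f"{a.charge:10.6f} {a.vdw_radius:8.4f}\n"
            )


def read_pdb(path) -> Structure:
    """Read a plain PDB file (fixed columns); charges and LJ default to 0.

    Intended to be combined with :func:`apply_param_table`, which
    supplies charges and LJ parameters per (residue_name, atom_name).
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.startswith(("ATOM", "HETATM")):
                continue
            try:
                serial = int(raw[6:11])
                name = raw[12:16].strip()
                resname = raw[17:20].strip()
                chain = raw[21].strip()
                resid = int(raw[22:26])
                x = float(raw[30:38])
                y = float(raw[38:46])
                z = float(raw[46:54])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
            element = raw[76:78].strip() or _guess_element(name)
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=element.capitalize(),
                    residue_name=resname,
                    residue_id=resid,
                    chain=chain,
                    position=(x, y, z),
                )
            )
    if not atoms:
        raise ParseError(f"{path.name}: no ATOM records found")
    return Structure(atoms)


def read_param_table(path) -> dict[tuple[str, str], tuple[float, float, float, float]]:
    """Read a sidecar nonbonded-parameter table.

    Whitespace/comma-delimited columns: residue_name, atom_name, charge,
    rmin_half, epsilon, vdw_radius.  Lines starting with '#' are
    comments.
    """
    table: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.replace(",", " ").split()
            if len(toks) != 6:
                raise ParseError(f"{path.name}:{lineno}: expected 6 fields")
            try:
                vals = tuple(float(t) for t in toks[2:])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
            table[(toks[0], toks[1])] = vals  # type: ignore[assignment]
    return table


def apply_param_table(structure: Structure, table) -> Structure:
    """Return a structure with charge/LJ/vdW fields filled from a table."""
    out = []
    for a in structure.atoms:
        key = (a.residue_name, a.name)
        if key not in table:
            raise KeyError(
                f"no parameters for atom {a.serial} ({a.residue_name}/{a.name})"
            )
        q, rmin_half, eps, rvdw = table[key]
        out.append(
            replace(a, charge=q, lj_rmin_half=rmin_half, lj_epsilon=eps,
                    vdw_radius=rvdw)
        )
    return Structure(out, title=structure.title)


# ---------------------------------------------------------------------------
# scalar grids


@dataclass
class GridMap:
    """Regular 3-D scalar field with trilinear interpolation semantics.

    ``values`` has shape ``shape`` = (nx, ny, nz) in C order, so the
    flattened array is z-fastest, matching the OpenDX file layout.
    ``out_of_bounds`` selects what happens when a point is interpolated
    outside the grid: "zero", "clamp" (clamp to edge) or "error".
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    unit: str = ""
    out_of_bounds: str = "zero"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.atleast_1d(np.asarray(self.spacing, dtype=float))
        if self.spacing.size == 1:
            self.spacing = np.repeat(self.spacing, 3)
        self.values = np.ascontiguousarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("GridMap values must be a 3-D array")
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if self.out_of_bounds not in ("zero", "clamp", "error"):
            raise ValueError(f"unknown out_of_bounds policy {self.out_of_bounds!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def upper(self) -> np.ndarray:
        """Position of the last grid node along each axis."""
        return self.origin + self.spacing * (np.array(self.shape) - 1)

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def same_frame(self, other: "GridMap", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )


def _validate_dx_item_count(path: Path) -> None:
    """Fail early (with counts) on a truncated DX data array."""
    import re

    expected = None
    found = 0
    in_data = False
    with open(path) as fh:
        for line in fh:
            if not in_data:
                m = re.search(r"class\s+array.*items\s+(\d+)", line)
                if m:
                    expected = int(m.group(1))
                    in_data = True
                continue
            toks = line.split()
            if not toks or toks[0] in ("attribute", "object", "component"):
                break
            try:
                found += len([float(t) for t in toks])
            except ValueError:
                break
    if expected is not None and found != expected:
        raise ParseError(
            f"{path.name}: truncated data array (expected {expected} values, "
            f"found {found})"
        )


def read_dx(path) -> GridMap:
    """Read an OpenDX regular scalar grid."""
    path = Path(path)
    _validate_dx_item_count(path)
    try:
        g = Grid(str(path))
    except (ValueError, IndexError, OSError) as exc:
        raise ParseError(f"{path.name}: not a regular OpenDX scalar grid ({exc})") from exc
    delta = np.asarray(g.delta, dtype=float)
    if delta.ndim == 2:
        off = delta - np.diag(np.diag(delta))
        if np.any(np.abs(off) > 1e-12):
            raise ParseError(f"{path.name}: non-axis-aligned grid is unsupported")
        delta = np.diag(delta)
    return GridMap(origin=np.asarray(g.origin, dtype=float), spacing=delta,
                   values=g.grid)


def write_dx(grid_map: GridMap, path) -> None:
    """Write an OpenDX regular scalar grid (z-fastest order)."""
    g = Grid(grid_map.values, origin=grid_map.origin, delta=grid_map.spacing)
    g.export(str(path), typequote="")


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """Time-stamped rigid-body poses of the mobile body.

    ``times`` is in ns and strictly increasing; ``positions`` holds the
    per-frame COM (A) and ``quaternions`` the orientation as unit
    quaternions (w, x, y, z) to within 1e-9.
    """

    times: np.ndarray
    positions: np.ndarray
    quaternions: np.ndarray
    mobile_label: str = "mobile"
    stationary_label: str = "stationary"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        n = self.times.shape[0]
        if self.positions.shape != (n, 3) or self.quaternions.shape != (n, 4):
            raise ValueError("inconsistent trajectory array shapes")
        if n > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        norms = np.linalg.norm(self.quaternions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(norms - 1.0)))
            raise ValueError(
                f"frame {bad}: quaternion norm {norms[bad]:.6g} is not 1"
            )
        # renormalise residual float error down to the 1e-9 contract
        self.quaternions = self.quaternions / norms[:, None]

    def __len__(self) -> int:
        return self.times.shape[0]


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a columnar trajectory table with >= 9 significant digits."""
    with open(path, "w") as fh:
        fh.write(f"# mobile={traj.mobile_label} stationary={traj.stationary_label}\n")
        for key, val in sorted(traj.metadata.items()):
            fh.write(f"# {key}={val}\n")
        fh.write("time_ns x y z qw qx qy qz\n")
        for t, p, q in zip(traj.times, traj.positions, traj.quaternions):
            fh.write(
                f"{t:.10g} {p[0]:.10g} {p[1]:.10g} {p[2]:.10g} "
                f"{q[0]:.12g} {q[1]:.12g} {q[2]:.12g} {q[3]:.12g}\n"
            )


def read_trajectory(path) -> Trajectory:
    """Read a columnar trajectory table written by :func:`write_trajectory`."""
    path = Path(path)
    metadata: dict[str, str] = {}
    mobile, stationary = "mobile", "stationary"
    rows = []
    with open(path) as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                for tok in body.split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        if k == "mobile":
                            mobile = v
                        elif k == "stationary":
                            stationary = v
                        else:
                            metadata[k] = v
                continue
            if not header_seen and line.split()[0] == "time_ns":
                header_seen = True
                continue
            toks = line.split()
            if len(toks) != 8:
                raise ParseError(f"{path.name}:{lineno}: expected 8 columns")
            try:
                rows.append([float(t) for t in toks])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
    if not rows:
        raise ParseError(f"{path.name}: no trajectory frames found")
    arr = np.asarray(rows)
    return Trajectory(
        times=arr[:, 0],
        positions=arr[:, 1:4],
        quaternions=arr[:, 4:8],
        mobile_label=mobile,
        stationary_label=stationary,
        metadata=metadata,
    )
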