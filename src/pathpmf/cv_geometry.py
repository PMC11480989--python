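"""Geometric collective variables (CVs) on molecular structures.

The CV types used to describe an enzyme acylation reaction together with a
ring-orientation degree of freedom:

* ``distance`` — Euclidean distance between two atoms (Å),
* ``dihedral`` — torsion angle over four atoms (degrees, right-handed
  convention, wrapped to (−180, 180]),
* ``point_to_plane`` — signed distance from an atom to the total-least-squares
  plane of a set of atoms (Å); tracks the hybridization state of an ester
  carbon,
* ``plane_angle`` — acute angle between the best-fit planes of two rings
  (degrees in [0, 90]); distinguishes T-stacked (≈90°) from parallel (≈0°)
  aromatic stacking.

Angles are degrees externally and radians internally.  Structures are plain
coordinate containers read from PDB (via biotite) or XYZ files; no topology
or bond perception is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Structure",
    "CVDefinition",
    "CVVector",
    "ParseError",
    "GeometryError",
    "read_structure",
    "distance",
    "dihedral",
    "point_to_plane",
    "plane_angle",
    "cv_evaluate",
    "cv_gradient",
    "wrap_degrees",
]

CVKind = Literal["distance", "dihedral", "point_to_plane", "plane_angle"]


class ParseError(ValueError):
    """A structure file could not be parsed."""


class GeometryError(ValueError):
    """A CV is undefined for the given geometry (collinear atoms etc.)."""


def wrap_degrees(angle):
    """Wrap an angle in degrees into (−180, 180]."""
    wrapped = np.asarray(angle) % 360.0
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    # the % above maps exact -180 to 180 already; keep scalars scalar
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class Structure:
    """Atom labels plus Cartesian coordinates (Å) for one frame."""

    atom_ids: tuple[str, ...]
    coords: np.ndarray
    elements: tuple[str, ...] | None = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError("coords must have shape (n_atoms >= 1, 3)")
        if len(self.atom_ids) != coords.shape[0]:
            raise ValueError("atom_ids length must match coords")
        if len(set(self.atom_ids)) != len(self.atom_ids):
            raise ValueError("atom_ids must be unique within a frame")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class CVDefinition:
    """One collective variable: its kind, the atoms defining it, and the
    scale used when mixing CVs of different units in a CV-space metric.

    ``atoms`` holds 2 indices for a distance, 4 for a dihedral; for
    ``point_to_plane`` the first index is the point and the rest span the
    plane; for ``plane_angle`` the two rings are ``atoms`` and ``atoms_b``.
    Indices are 0-based.
    """

    kind: CVKind
    atoms: tuple[int, ...]
    atoms_b: tuple[int, ...] = ()
    scale: float = 1.0
    periodic: bool = False
    name: str = ""

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        n = len(self.atoms)
        if self.kind == "distance" and n != 2:
            raise ValueError("distance needs exactly 2 atoms")
        if self.kind == "dihedral":
            if n != 4 or len(set(self.atoms)) != 4:
                raise ValueError("dihedral needs 4 distinct atoms")
            if not self.periodic:
                object.__setattr__(self, "periodic", True)
        if self.kind == "point_to_plane" and n < 4:
            raise ValueError("point_to_plane needs 1 point + >=3 plane atoms")
        if self.kind == "plane_angle" and (n < 3 or len(self.atoms_b) < 3):
            raise ValueError("plane_angle needs two rings of >=3 atoms")

    @classmethod
    def from_dict(cls, d: dict) -> "CVDefinition":
        d = dict(d)
        kind = d.pop("kind")
        atoms = tuple(d.pop("atoms"))
        atoms_b = tuple(d.pop("atoms_b", ()))
        return cls(kind=kind, atoms=atoms, atoms_b=atoms_b, **d)


@dataclass(frozen=True)
class CVVector:
    """CV values aligned with an ordered list of definitions."""

    values: np.ndarray
    defs: tuple[CVDefinition, ...] = field(default=(), compare=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if self.defs and len(values) != len(self.defs):
            raise ValueError("values length must match CV definitions")
        if self.defs:
            periodic = np.array([d.periodic for d in self.defs])
            values = np.where(periodic, wrap_degrees(values), values)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# file reading


def _read_xyz(path: Path) -> list[Structure]:
    frames: list[Structure] = []
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            raise ParseError(f"{path}:{i + 1}: expected atom count") from None
        if i + 2 + n > len(lines):
            raise ParseError(f"{path}:{i + 1}: truncated frame of {n} atoms")
        symbols, coords = [], []
        for k, line in enumerate(lines[i + 2 : i + 2 + n], start=i + 3):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{k}: malformed XYZ atom record")
            try:
                coords.append([float(x) for x in parts[1:4]])
            except ValueError:
                raise ParseError(f"{path}:{k}: non-numeric coordinate") from None
            symbols.append(parts[0])
        ids = tuple(f"{sym}{j}" for j, sym in enumerate(symbols))
        frames.append(Structure(ids, np.array(coords), tuple(symbols)))
        i += 2 + n
    if not frames:
        raise ParseError(f"{path}: no atoms found")
    return frames


def _pdb_first_bad_line(path: Path) -> int | None:
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except (ValueError, IndexError):
                return lineno
    return None


def _read_pdb(path: Path, all_frames: bool) -> list[Structure]:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        # altloc policy: keep the highest-occupancy location (ties resolve
        # to the first listed, i.e. 'A'); HETATM records are kept.
        stack = pdb.get_structure(model=None, altloc="occupancy")
    except Exception as exc:  # biotite raises various error types
        bad = _pdb_first_bad_line(path)
        loc = f":{bad}" if bad is not None else ""
        raise ParseError(f"{path}{loc}: failed to parse PDB ({exc})") from exc
    if stack.array_length() == 0:
        raise ParseError(f"{path}: no atoms found")
    n_models = stack.stack_depth() if isinstance(stack, struc.AtomArrayStack) else 1
    frames = []
    for m in range(n_models):
        arr = stack[m] if isinstance(stack, struc.AtomArrayStack) else stack
        ids, seen = [], {}
        for chain, res, name in zip(arr.chain_id, arr.res_id, arr.atom_name):
            base = f"{chain}:{res}:{name}"
            if base in seen:
                seen[base] += 1
                base = f"{base}#{seen[base]}"
            else:
                seen[base] = 0
            ids.append(base)
        frames.append(Structure(tuple(ids), np.array(arr.coord, dtype=float),
                                tuple(arr.element)))
        if not all_frames:
            break
    return frames


def read_structure(path, format: str | None = None,
                   all_frames: bool = True) -> list[Structure]:
    """Read a PDB or XYZ file into a list of frames.

    ``format`` is inferred from the suffix when not given.  For PDB, each
    MODEL block is one frame; by default all frames are returned and
    ``all_frames=False`` keeps only the first model.
    """
    path = Path(path)
    if not path.is_file():
        raise ParseError(f"{path}: no such file")
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "xyz":
        frames = _read_xyz(path)
        return frames if all_frames else frames[:1]
    if format == "pdb":
        return _read_pdb(path, all_frames)
    raise ParseError(f"unknown structure format: {format!r}")


# ---------------------------------------------------------------------------
# elementary CVs


def _check_indices(s: Structure, idx: Sequence[int]):
    for i in idx:
        if not 0 <= i < s.n_atoms:
            raise IndexError(f"atom index {i} out of range (n={s.n_atoms})")


def distance(s: Structure, i: int, j: int) -> float:
    """Euclidean distance between atoms i and j in Å."""
    if i == j:
        raise ValueError("distance requires two distinct atoms")
    _check_indices(s, (i, j))
    return float(np.linalg.norm(s.coords[i] - s.coords[j]))


def _dihedral_rad(p: np.ndarray) -> float:
    b1 = p[1] - p[0]
    b2 = p[2] - p[1]
    b3 = p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("dihedral undefined: three consecutive atoms collinear")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m @ n2)
    return math.atan2(y, x)


def dihedral(s: Structure, i: int, j: int, k: int, l: int) -> float:
    """Torsion angle i-j-k-l in degrees, wrapped to (−180, 180].

    Right-handed sign convention: the cis-planar arrangement gives 0° and the
    trans-planar one 180°; mirroring the structure flips the sign.
    """
    if len({i, j, k, l}) != 4:
        raise ValueError("dihedral requires four distinct atoms")
    _check_indices(s, (i, j, k, l))
    return wrap_degrees(math.degrees(_dihedral_rad(s.coords[[i, j, k, l]])))


def _ls_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane: returns (centroid, unit normal).

    The normal is the principal axis of smallest variance; its sign is fixed
    by the cross product of the first three (ordered) atoms so that signed
    quantities are reproducible.
    """
    c = points.mean(axis=0)
    x = points - c
    # smallest right singular vector == smallest-inertia principal axis
    _, svals, vt = np.linalg.svd(x, full_matrices=False)
    if svals[-2] < 1e-8 * max(1.0, svals[0]):
        raise GeometryError("plane undefined: atoms are collinear")
    n = vt[-1]
    ref = np.cross(points[1] - points[0], points[2] - points[0])
    if np.linalg.norm(ref) > 1e-12 and float(ref @ n) < 0:
        n = -n
    return c, n


def point_to_plane(s: Structure, point: int, plane: Sequence[int]) -> float:
    """Signed distance (Å) from atom ``point`` to the TLS plane of ``plane``."""
    _check_indices(s, [point, *plane])
    if len(plane) < 3:
        raise ValueError("plane needs at least 3 atoms")
    c, n = _ls_plane(s.coords[list(plane)])
    return float(n @ (s.coords[point] - c))


def plane_angle(s: Structure, ring_a: Sequence[int], ring_b: Sequence[int]) -> float:
    """Acute angle in degrees between the best-fit planes of two rings."""
    _check_indices(s, [*ring_a, *ring_b])
    _, na = _ls_plane(s.coords[list(ring_a)])
    _, nb = _ls_plane(s.coords[list(ring_b)])
    cosang = abs(float(na @ nb))
    return math.degrees(math.acos(min(1.0, cosang)))


def _evaluate_one(d: CVDefinition, s: Structure) -> float:
    if d.kind == "distance":
        return distance(s, *d.atoms)
    if d.kind == "dihedral":
        return dihedral(s, *d.atoms)
    if d.kind == "point_to_plane":
        return point_to_plane(s, d.atoms[0], d.atoms[1:])
    if d.kind == "plane_angle":
        return plane_angle(s, d.atoms, d.atoms_b)
    raise ValueError(f"unknown CV kind {d.kind!r}")


def cv_evaluate(defs: Sequence[CVDefinition], s: Structure) -> CVVector:
    """Evaluate an ordered list of CV definitions on one structure."""
    values = np.array([_evaluate_one(d, s) for d in defs])
    return CVVector(values, tuple(defs))


# ---------------------------------------------------------------------------
# gradients


def _distance_gradient(s: Structure, i: int, j: int) -> np.ndarray:
    g = np.zeros_like(s.coords)
    r = s.coords[i] - s.coords[j]
    norm = np.linalg.norm(r)
    if norm < 1e-12:
        raise GeometryError("distance gradient undefined for coincident atoms")
    u = r / norm
    g[i] = u
    g[j] = -u
    return g


def _dihedral_gradient(s: Structure, idx: tuple[int, ...]) -> np.ndarray:
    # standard analytic torsion gradient (degrees per Å)
    p = s.coords[list(idx)]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq, n2sq = float(n1 @ n1), float(n2 @ n2)
    b2n = float(np.linalg.norm(b2))
    if n1sq < 1e-20 or n2sq < 1e-20:
        raise GeometryError("dihedral gradient undefined: collinear atoms")
    g1 = b2n / n1sq * n1
    g4 = -b2n / n2sq * n2
    c12 = float(b1 @ b2) / (b2n * b2n)
    c32 = float(b3 @ b2) / (b2n * b2n)
    g2 = -(1.0 + c12) * g1 + c32 * g4
    g3 = -(1.0 + c32) * g4 + c12 * g1
    g = np.zeros_like(s.coords)
    for a, ga in zip(idx, (g1, g2, g3, g4)):
        g[a] += ga
    return np.degrees(g)


def _numeric_gradient(d: CVDefinition, s: Structure, h: float = 1e-5) -> np.ndarray:
    """Central-difference Cartesian gradient, periodic-aware for angles."""
    moving = sorted(set(d.atoms) | set(d.atoms_b))
    g = np.zeros_like(s.coords)
    base = s.coords.copy()
    for a in moving:
        for ax in range(3):
            for sign, slot in ((+1, 0), (-1, 1)):
                coords = base.copy()
                coords[a, ax] += sign * h
                val = _evaluate_one(d, Structure(s.atom_ids, coords, s.elements))
                if slot == 0:
                    plus = val
                else:
                    minus = val
            diff = plus - minus
            if d.periodic:
                diff = wrap_degrees(diff)
            g[a, ax] = diff / (2 * h)
    return g


def cv_gradient(d: CVDefinition, s: Structure) -> np.ndarray:
    """Per-atom Cartesian gradient of one CV, shape (n_atoms, 3).

    Distances and dihedrals use analytic formulas; the plane-based CVs use
    central finite differences (step 1e-5 Å), which meet the same accuracy
    contract without differentiating through the plane eigenproblem.
    """
    if d.kind == "distance":
        return _distance_gradient(s, *d.atoms)
    if d.kind == "dihedral":
        _ = dihedral(s, *d.atoms)  # raise on degenerate geometry first
        return _dihedral_gradient(s, d.atoms)
    _ = _evaluate_one(d, s)
    return _numeric_gradient(d, s)


def cv_series_frame(defs: Sequence[CVDefinition], frames: Sequence[Structure]):
    """Per-frame CV table as a pandas DataFrame (one column per CV)."""
    import pandas as pd

    names = [d.name or f"{d.kind}_{i}" for i, d in enumerate(defs)]
    rows = [cv_evaluate(defs, fr).values for fr in frames]
    df = pd.DataFrame(rows, columns=names)
    df.insert(0, "frame", np.arange(len(frames)))
    return df
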