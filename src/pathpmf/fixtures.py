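"""Synthetic idealized ring geometries for stacking-angle analysis.

These are constructed (not experimental) two-ring fixtures: a planar
six-membered ring standing in for the substrate's benzene ring and a second
ring standing in for the active-site tryptophan's six-ring.  The T-stacked
arrangement has perpendicular ring planes (plane angle 90°) and a surrogate
dihedral θ of exactly 0°; rotating the second ring about its in-plane axis
parallel to x by α carries θ to α and the plane angle to 90° − α, so the
parallel-stacked arrangement (α = 90°) has plane angle 0° and θ = 90°.

The four θ-defining atoms are chosen so that two of them lie on the rotation
axis, which makes θ track the ring rotation exactly.
"""

from __future__ import annotations

import numpy as np

from .cv_geometry import CVDefinition, Structure

__all__ = [
    "hexagon",
    "stacked_ring_pair",
    "t_stacked_pair",
    "parallel_stacked_pair",
    "RING_A",
    "RING_B",
    "THETA_ATOMS",
    "stacking_cv_definitions",
]

RING_RADIUS = 1.4  # Å, aromatic C6 circumradius
STACK_SEPARATION = 3.5  # Å, typical ring-centroid stacking distance

#: atom indices of the two rings within the fixture structures
RING_A = tuple(range(0, 6))
RING_B = tuple(range(6, 12))
#: θ-defining atoms (p1 in ring A; p2, p3 the ring-B para pair on the
#: rotation axis; p4 a ring-B atom off the axis)
THETA_ATOMS = (0, 9, 6, 11)


def hexagon(center, u, v, radius: float = RING_RADIUS) -> np.ndarray:
    """Vertices of a regular hexagon spanned by orthonormal in-plane axes
    ``u`` and ``v``, at azimuths 0°, 60°, ..., 300° measured from ``u``."""
    center = np.asarray(center, float)
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    ang = np.deg2rad(60.0 * np.arange(6))
    return center + radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))


def stacked_ring_pair(alpha_deg: float) -> Structure:
    """Two stacked rings with the second ring rotated by ``alpha_deg`` about
    the in-plane x axis through its center.

    ``alpha_deg = 0`` is the ideal T-stack (plane angle 90°, θ = 0°);
    ``alpha_deg = 90`` is the ideal parallel stack (plane angle 0°, θ = 90°).
    """
    ring_a = hexagon([0.0, 0.0, 0.0], [1, 0, 0], [0, 1, 0])
    # T-stacked reference: ring B in the xz-plane above ring A
    center_b = np.array([0.0, 0.0, STACK_SEPARATION])
    a = np.deg2rad(alpha_deg)
    # in-plane axis u stays along x; v = z rotated by alpha toward +y
    v = np.array([0.0, np.sin(a), np.cos(a)])
    ring_b = hexagon(center_b, [1, 0, 0], v)
    coords = np.vstack([ring_a, ring_b])
    ids = tuple(f"A{i}" for i in range(6)) + tuple(f"B{i}" for i in range(6))
    return Structure(ids, coords, ("C",) * 12)


def t_stacked_pair() -> Structure:
    return stacked_ring_pair(0.0)


def parallel_stacked_pair() -> Structure:
    return stacked_ring_pair(90.0)


def stacking_cv_definitions() -> list[CVDefinition]:
    """The plane-angle and surrogate-dihedral CVs of the ring fixtures."""
    return [
        CVDefinition(kind="plane_angle", atoms=RING_A, atoms_b=RING_B,
                     scale=30.0, name="plane_angle"),
        CVDefinition(kind="dihedral", atoms=THETA_ATOMS, scale=30.0,
                     periodic=True, name="theta"),
    ]
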