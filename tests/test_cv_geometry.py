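"""Geometric CV evaluation: parsing, angles, signed distances, gradients,
and rigid-motion invariance."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pathpmf import fixtures as rings
from pathpmf.cv_geometry import (CVDefinition, GeometryError, ParseError,
                                 Structure, cv_evaluate, cv_gradient, dihedral,
                                 distance, plane_angle, point_to_plane,
                                 read_structure, wrap_degrees)

RNG = np.random.default_rng(42)


def _structure(coords):
    coords = np.asarray(coords, float)
    ids = tuple(f"a{i}" for i in range(len(coords)))
    return Structure(ids, coords)


# ---------------------------------------------------------------- parsing


def test_xyz_roundtrip_and_frames(tmp_path):
    p = tmp_path / "two.xyz"
    p.write_text(
        "3\nframe one\nC 0.0 0.0 0.0\nO 1.0 0.0 0.0\nN 0.0 1.0 0.0\n"
        "3\nframe two\nC 0.1 0.0 0.0\nO 1.1 0.0 0.0\nN 0.1 1.0 0.0\n")
    frames = read_structure(p)
    assert len(frames) == 2
    assert frames[0].n_atoms == 3
    assert np.allclose(frames[1].coords[0], [0.1, 0, 0])
    assert read_structure(p, all_frames=False)[0].coords[1, 0] == 1.0


def test_xyz_malformed_names_line(tmp_path):
    p = tmp_path / "bad.xyz"
    p.write_text("2\nc\nC 0 0 0\nO 1 zero 0\n")
    with pytest.raises(ParseError, match=":4"):
        read_structure(p)


PDB_TWO_MODELS = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CB AALA A   1       1.000   0.000   0.000  0.30  0.00           C
ATOM      3  CB BALA A   1       2.000   0.000   0.000  0.70  0.00           C
HETATM    4  O   HOH A   2       0.000   2.000   0.000  1.00  0.00           O
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       0.000   0.000   1.000  1.00  0.00           C
ATOM      2  CB AALA A   1       1.000   0.000   1.000  0.30  0.00           C
ATOM      3  CB BALA A   1       2.000   0.000   1.000  0.70  0.00           C
HETATM    4  O   HOH A   2       0.000   2.000   1.000  1.00  0.00           O
ENDMDL
END
"""


def test_pdb_models_altloc_hetatm(tmp_path):
    p = tmp_path / "m.pdb"
    p.write_text(PDB_TWO_MODELS)
    frames = read_structure(p)
    assert len(frames) == 2
    # altloc: highest occupancy (B at 0.70) kept; HETATM read like ATOM
    assert frames[0].n_atoms == 3
    assert 2.0 in frames[0].coords[:, 0]
    assert 1.0 not in frames[0].coords[:, 0]
    assert frames[1].coords[0, 2] == 1.0
    assert len(read_structure(p, all_frames=False)) == 1


def test_unreadable_inputs(tmp_path):
    with pytest.raises(ParseError):
        read_structure(tmp_path / "absent.xyz")
    empty = tmp_path / "empty.xyz"
    empty.write_text("")
    with pytest.raises(ParseError):
        read_structure(empty)


# ------------------------------------------------------------ elementary CVs


def test_distance_values_and_symmetry():
    s = _structure([[0, 0, 0], [3, 4, 0], [3, 4, 0]])
    assert distance(s, 0, 1) == pytest.approx(5.0)
    assert distance(s, 1, 0) == pytest.approx(5.0)
    assert distance(s, 1, 2) == 0.0
    with pytest.raises(ValueError):
        distance(s, 1, 1)
    with pytest.raises(IndexError):
        distance(s, 0, 9)


def test_distance_matches_brute_force_norm():
    coords = RNG.normal(size=(8, 3))
    s = _structure(coords)
    for i, j in [(0, 5), (2, 7), (3, 4)]:
        expected = float(np.sqrt(((coords[i] - coords[j]) ** 2).sum()))
        assert distance(s, i, j) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("coords,expected", [
    ([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], 0.0),       # cis
    ([[0, 0, 0], [1, 0, 0], [1, 1, 0], [2, 1, 0]], 180.0),     # trans
    ([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1]], -90.0),     # gauche
])
def test_dihedral_reference_values(coords, expected):
    assert dihedral(_structure(coords), 0, 1, 2, 3) == pytest.approx(expected)


def test_dihedral_symmetries():
    coords = RNG.normal(size=(4, 3))
    s = _structure(coords)
    phi = dihedral(s, 0, 1, 2, 3)
    assert dihedral(s, 3, 2, 1, 0) == pytest.approx(phi)
    mirrored = _structure(coords * [1, 1, -1])
    assert dihedral(mirrored, 0, 1, 2, 3) == pytest.approx(-phi)


def test_dihedral_collinear_raises():
    s = _structure([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]])
    with pytest.raises(GeometryError):
        dihedral(s, 0, 1, 2, 3)


def test_point_to_plane_values():
    plane = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]
    s = _structure(plane + [[0.3, 0.4, 2.0], [0.5, 0.5, 0.0]])
    assert abs(point_to_plane(s, 4, [0, 1, 2, 3])) == pytest.approx(2.0)
    assert point_to_plane(s, 5, [0, 1, 2, 3]) == pytest.approx(0.0, abs=1e-12)
    # sign flips with the side of the plane
    below = _structure(plane + [[0.3, 0.4, -2.0]])
    assert point_to_plane(below, 4, [0, 1, 2, 3]) == pytest.approx(
        -point_to_plane(s, 4, [0, 1, 2, 3]))


def test_point_to_plane_analytic_oracle():
    # plane through 3 random points vs direct plane-equation solution
    pts = RNG.normal(size=(3, 3))
    q = RNG.normal(size=3)
    n = np.cross(pts[1] - pts[0], pts[2] - pts[0])
    n = n / np.linalg.norm(n)
    expected = float(n @ (q - pts.mean(axis=0)))
    s = _structure(np.vstack([pts, q]))
    assert point_to_plane(s, 3, [0, 1, 2]) == pytest.approx(expected, rel=1e-9)


def test_point_to_plane_collinear_raises():
    s = _structure([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 0, 1]])
    with pytest.raises(GeometryError):
        point_to_plane(s, 3, [0, 1, 2])


def test_plane_angle_reference_orientations():
    t = rings.t_stacked_pair()
    assert plane_angle(t, rings.RING_A, rings.RING_B) == pytest.approx(90.0)
    p = rings.parallel_stacked_pair()
    assert plane_angle(p, rings.RING_A, rings.RING_B) == pytest.approx(0.0, abs=1e-9)


def test_plane_angle_tracks_ring_rotation():
    # second ring rotated by alpha from coplanar -> plane angle alpha
    for alpha in (5.0, 30.0, 45.0, 77.0, 90.0):
        s = rings.stacked_ring_pair(90.0 - alpha)
        assert plane_angle(s, rings.RING_A, rings.RING_B) == pytest.approx(
            alpha, abs=1e-6)


def test_plane_angle_ring_order_invariance():
    s = rings.stacked_ring_pair(33.0)
    a = plane_angle(s, rings.RING_A, rings.RING_B)
    shuffled = tuple(np.array(rings.RING_B)[[3, 1, 5, 0, 4, 2]])
    assert plane_angle(s, rings.RING_A, shuffled) == pytest.approx(a, abs=1e-9)


def test_cv_evaluate_composes_and_wraps():
    s = rings.t_stacked_pair()
    defs = rings.stacking_cv_definitions() + [
        CVDefinition(kind="distance", atoms=(0, 6), name="d")]
    vec = cv_evaluate(defs, s)
    assert len(vec) == 3
    assert vec.values[0] == pytest.approx(90.0)
    assert vec.values[1] == pytest.approx(0.0, abs=1e-9)
    assert -180.0 < vec.values[1] <= 180.0


def test_rigid_motion_invariance_all_kinds():
    base = rings.stacked_ring_pair(40.0)
    defs = rings.stacking_cv_definitions() + [
        CVDefinition(kind="distance", atoms=(0, 8)),
        CVDefinition(kind="point_to_plane", atoms=(6, 0, 1, 2, 3, 4, 5)),
    ]
    ref = cv_evaluate(defs, base).values
    rng = np.random.default_rng(7)
    for _ in range(10):
        rot = Rotation.random(random_state=rng)
        shift = rng.normal(scale=5.0, size=3)
        moved = Structure(base.atom_ids, rot.apply(base.coords) + shift)
        got = cv_evaluate(defs, moved).values
        assert np.allclose(wrap_degrees(got - ref), 0.0, atol=1e-6)


# ---------------------------------------------------------------- gradients


def _fd_gradient(d, s, h=1e-6):
    from pathpmf.cv_geometry import _evaluate_one

    g = np.zeros_like(s.coords)
    for a in range(s.n_atoms):
        for ax in range(3):
            cp, cm = s.coords.copy(), s.coords.copy()
            cp[a, ax] += h
            cm[a, ax] -= h
            diff = (_evaluate_one(d, Structure(s.atom_ids, cp))
                    - _evaluate_one(d, Structure(s.atom_ids, cm)))
            if d.periodic:
                diff = wrap_degrees(diff)
            g[a, ax] = diff / (2 * h)
    return g


def test_distance_gradient_unit_vectors():
    s = _structure([[0, 0, 0], [1, 0, 0]])
    g = cv_gradient(CVDefinition(kind="distance", atoms=(0, 1)), s)
    assert np.allclose(g[0], [-1, 0, 0])
    assert np.allclose(g[1], [1, 0, 0])


@pytest.mark.parametrize("kind", ["distance", "dihedral", "point_to_plane",
                                  "plane_angle"])
def test_gradients_match_central_differences(kind):
    rng = np.random.default_rng(11)
    n_ok = 0
    for _ in range(25):
        if kind == "plane_angle":
            s = rings.stacked_ring_pair(rng.uniform(10, 80))
            s = Structure(s.atom_ids, s.coords + rng.normal(0, 0.05, s.coords.shape))
            d = CVDefinition(kind=kind, atoms=rings.RING_A, atoms_b=rings.RING_B)
        else:
            coords = rng.normal(scale=1.5, size=(6, 3))
            s = _structure(coords)
            atoms = {"distance": (0, 1), "dihedral": (0, 1, 2, 3),
                     "point_to_plane": (0, 1, 2, 3, 4)}[kind]
            d = CVDefinition(kind=kind, atoms=atoms)
        try:
            g = cv_gradient(d, s)
        except GeometryError:
            continue
        assert np.allclose(g, _fd_gradient(d, s), rtol=1e-4, atol=1e-4)
        n_ok += 1
    assert n_ok >= 15


@pytest.mark.parametrize("kind,atoms,atoms_b", [
    ("distance", (0, 7), ()),
    ("dihedral", (0, 9, 6, 11), ()),
    ("point_to_plane", (6, 0, 1, 2, 3, 4, 5), ()),
    ("plane_angle", rings.RING_A, rings.RING_B),
])
def test_gradient_net_force_is_zero(kind, atoms, atoms_b):
    s = rings.stacked_ring_pair(35.0)
    d = CVDefinition(kind=kind, atoms=atoms, atoms_b=atoms_b)
    g = cv_gradient(d, s)
    assert np.allclose(g.sum(axis=0), 0.0, atol=1e-5)
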