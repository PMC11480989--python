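"""Cubic-spline correction of a low-level PMF to a high-level surface."""

import numpy as np
import pytest

from pathpmf.correction import (CorrectionTable, build_correction,
                                check_path_similarity, spline_correct)
from pathpmf.path_cv import CVMetric, PathCV
from pathpmf.profiles import analyze_profile
from pathpmf.surfaces import (LowHighSurfacePair, TwoStepSurfaceParams,
                              exact_marginal_pmf, two_step_pair,
                              two_step_surface)


def straight_path(n=25):
    nodes = np.linspace(0, 1, n)[:, None] * [1.0, 90.0]
    return PathCV(nodes, CVMetric([1.0, 30.0], [False, True]))


def bump_profile(dip=0.0, n=201):
    s = np.linspace(0, 1, n)
    a = 14.0 * np.exp(-((s - 0.5) ** 2) / 0.05) - dip * np.exp(
        -((s - 0.5) ** 2) / 0.004)
    return analyze_profile(s, a, np.zeros(n))


# -------------------------------------------------------------- tables


def test_table_validation():
    s = np.linspace(0, 1, 6)
    CorrectionTable(s, np.zeros(6), np.ones(6))
    with pytest.raises(ValueError):
        CorrectionTable(s[:3], np.zeros(3), np.zeros(3))  # < 4 points
    with pytest.raises(ValueError):
        CorrectionTable(s[::-1], np.zeros(6), np.zeros(6))  # unsorted
    with pytest.raises(ValueError):
        CorrectionTable(s + 0.5, np.zeros(6), np.zeros(6))  # beyond [0, 1]


def test_build_correction_identical_and_offset_surfaces():
    pair_same = two_step_pair(ti_deepening=0.0)
    path = straight_path()
    table = build_correction(pair_same, path, n_points=9, local_relax=False)
    assert np.allclose(table.delta, 0.0, atol=1e-12)

    low = two_step_surface()
    from pathpmf.surfaces import EnergySurface

    high = EnergySurface(low.names, low.domain, low.periodic,
                         _energy=lambda x: low._energy(x) + 3.25,
                         _gradient=low._gradient)
    table = build_correction(LowHighSurfacePair(low, high), path, 9,
                             local_relax=False)
    assert np.allclose(table.delta, 3.25, atol=1e-12)
    with pytest.raises(ValueError):
        build_correction(pair_same, path, n_points=3)


def test_build_correction_recovers_known_delta_of_s():
    p = TwoStepSurfaceParams()
    pair = two_step_pair(p, ti_deepening=1.5, ti_width=0.1)
    # path along the equilibrium ridge: s maps linearly onto r
    t = np.linspace(0, 1, 41)
    nodes = np.stack([t, p.theta_eq(t)], axis=-1)
    path = PathCV(nodes, CVMetric([1.0, 30.0], [False, True]))
    table = build_correction(pair, path, n_points=21, local_relax=False)
    r_of_s = np.array([path.point_at(s)[0] for s in table.s])

    def f(r):
        return -1.5 * np.exp(-((r - p.r_ti) ** 2) / (2 * 0.1**2))

    assert np.allclose(table.delta, f(r_of_s), atol=1e-9)
    # with in-tube relaxation the evaluation points may move perpendicular
    # to the path (which has an r component); ΔE must stay within the
    # envelope of f over that radius
    relaxed = build_correction(pair, path, n_points=21, local_relax=True)
    for s_i, d in zip(relaxed.s, relaxed.delta):
        r0 = float(np.interp(s_i, relaxed.s, r_of_s))
        rr = np.linspace(r0 - 0.25, r0 + 0.25, 101)
        assert f(rr).min() - 1e-6 <= d <= f(rr).max() + 1e-6


# -------------------------------------------------------------- splines


def test_zero_delta_leaves_profile_unchanged():
    prof = bump_profile(dip=1.0)
    table = CorrectionTable(np.linspace(0, 1, 7), np.zeros(7), np.zeros(7))
    out = spline_correct(prof, table)
    assert np.allclose(out.a, prof.a, atol=1e-12)
    assert out.classification == prof.classification


def test_cubic_delta_reproduced_exactly():
    s_i = np.linspace(0, 1, 9)
    coef = (2.0, -1.5, 0.7, 0.25)
    poly = np.polynomial.Polynomial(coef[::-1])
    prof = bump_profile()
    table = CorrectionTable(s_i, np.zeros(9), poly(s_i))
    out = spline_correct(prof, table)
    applied = out.a - (prof.a - prof.a.min())
    expected = poly(prof.s)
    # both profiles are min-normalized; compare up to the common shift
    assert np.max(np.abs((applied - applied[0]) - (expected - expected[0]))) < 1e-10


def test_designed_delta_flips_classification():
    prof = bump_profile(dip=0.1)  # shallow: one_step
    assert prof.classification == "one_step"
    s_i = np.linspace(0, 1, 25)
    delta = -2.0 * np.exp(-((s_i - 0.5) ** 2) / 0.004)
    table = CorrectionTable(s_i, np.zeros(25), delta)
    out = spline_correct(prof, table, min_depth=0.1)
    assert out.classification == "two_step"


def test_sign_convention_tracks_high_level_surface():
    p = TwoStepSurfaceParams(e_ti=13.8)
    pair = two_step_pair(p, ti_deepening=1.5, ti_width=0.1)
    t = np.linspace(0, 1, 41)
    nodes = np.stack([t, p.theta_eq(t)], axis=-1)
    path = PathCV(nodes, CVMetric([1.0, 30.0], [False, True]))
    grid = np.linspace(0, 1, 201)
    low_marg = exact_marginal_pmf(pair.low, "r", grid)
    # map the r-grid PMF onto the path's s (linear here by construction)
    s_of_r = np.array([path.project(np.array([r, p.theta_eq(r)]))[0]
                       for r in grid])
    a_s = np.interp(grid, s_of_r, low_marg.a)
    prof = analyze_profile(grid, a_s, np.zeros_like(grid))
    table = build_correction(pair, path, 21, local_relax=False)
    out = spline_correct(prof, table, convention="add_high_minus_low")
    high_marg = exact_marginal_pmf(pair.high, "r", grid)
    a_high = np.interp(grid, s_of_r, high_marg.a)
    assert np.max(np.abs(out.a - (a_high - a_high.min()))) < 0.15
    flipped = spline_correct(prof, table, convention="subtract_delta")
    assert np.max(np.abs(flipped.a - (a_high - a_high.min()))) > 1.0


def test_extrapolation_rejected():
    prof = bump_profile()
    table = CorrectionTable(np.linspace(0.1, 0.9, 7), np.zeros(7), np.zeros(7))
    with pytest.raises(ValueError, match="beyond"):
        spline_correct(prof, table)


def test_correction_commutes_with_normalization():
    prof = bump_profile(dip=0.5)
    s_i = np.linspace(0, 1, 9)
    table = CorrectionTable(s_i, np.zeros(9), np.sin(3 * s_i))
    a1 = spline_correct(prof, table).a
    shifted = analyze_profile(prof.s, prof.a + 5.0, prof.ci)
    a2 = spline_correct(shifted, table).a
    assert np.allclose(a1, a2, atol=1e-10)


def test_monotone_delta_preserves_monotone_regions():
    s = np.linspace(0, 1, 201)
    a = 10.0 * s  # strictly increasing profile
    prof = analyze_profile(s, a, np.zeros_like(s))
    s_i = np.linspace(0, 1, 9)
    table = CorrectionTable(s_i, np.zeros(9), 2.0 * s_i)  # monotone delta
    out = spline_correct(prof, table)
    assert np.all(np.diff(out.a) > 0)
    assert len(out.stationary_points) == 2  # the two ends only


# ------------------------------------------------------- path similarity


def test_check_path_similarity_report_and_warning():
    metric = CVMetric([1.0, 30.0], [False, True])
    t = np.linspace(0, 1, 30)
    a = PathCV(np.stack([t, 90 * t], axis=-1), metric)
    same = check_path_similarity(a, a, tol=0.1)
    assert same["ok"] and same["rmsd"] == pytest.approx(0.0, abs=1e-12)
    near = PathCV(np.stack([t + 0.05, 90 * t], axis=-1), metric)
    assert check_path_similarity(a, near, tol=0.1)["ok"]
    far = PathCV(np.stack([t + 0.8, 90 * t], axis=-1), metric)
    with pytest.warns(UserWarning, match="differ"):
        report = check_path_similarity(a, far, tol=0.1)
    assert not report["ok"]
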