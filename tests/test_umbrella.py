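"""Umbrella sampling and umbrella-integration PMF estimation."""

import numpy as np
import pytest

from pathpmf.path_cv import CVMetric, PathCV
from pathpmf.profiles import analyze_profile
from pathpmf.surfaces import EnergySurface, KT_300K
from pathpmf.umbrella import (UmbrellaConfig, UmbrellaWindow, classify_profile,
                              run_umbrella, ui_confidence, ui_pmf)


def line_path_1d(n=25):
    nodes = np.linspace(0, 1, n)[:, None]
    return PathCV(nodes, CVMetric([1.0], [False]))


def surface_1d(fn, grad):
    return EnergySurface(("x",), ((-0.5, 1.5),), (False,),
                         _energy=fn, _gradient=grad)


def gaussian_windows(a_curv, n_windows=24, n_samples=4000, seed=0,
                     standardize=False):
    """Windows sampled from the exact biased densities of A(s) = a·(s−½)²."""
    rng = np.random.default_rng(seed)
    wins = []
    k = 2 * KT_300K * (n_windows - 1) ** 2
    for c in np.linspace(0, 1, n_windows):
        mu = (a_curv * 0.5 + k * c) / (a_curv + k)
        var = KT_300K / (2 * (a_curv + k))
        x = rng.standard_normal(n_samples)
        if standardize:
            x = (x - x.mean()) / x.std(ddof=1)
        wins.append(UmbrellaWindow(center=float(c), k=float(k),
                                   samples=mu + np.sqrt(var) * x))
    return wins


# ----------------------------------------------------------- window sampling


def test_window_means_shift_by_mean_force(acyl_metric):
    # linear potential: biased mean sits at c - f/(2k)
    f = 30.0
    surf = surface_1d(lambda x: f * x[..., 0],
                      lambda x: np.full_like(x, f))
    path = line_path_1d()
    cfg = UmbrellaConfig(n_steps=4000)
    wins = run_umbrella(path, surf, cfg, seed=3)
    k = wins[0].k
    shifts = np.array([w.mean - w.center for w in wins[2:-2]])
    expected = -f / (2 * k)
    se = np.array([np.sqrt(w.var / (w.n / 20)) for w in wins[2:-2]])
    assert np.all(np.abs(shifts - expected) < 3 * se + 5e-4)


def test_zero_force_window_means_match_centers():
    surf = surface_1d(lambda x: np.zeros(x.shape[:-1]),
                      lambda x: np.zeros_like(x))
    wins = run_umbrella(line_path_1d(), surf, UmbrellaConfig(n_steps=3000), seed=8)
    # boundary windows are half-clipped at s = 0 and 1; check the interior
    for w in wins[1:-1]:
        assert abs(w.mean - w.center) < 4 * np.sqrt(w.var / (w.n / 20)) + 5e-4


def test_fixed_seed_reproduces_window_statistics():
    surf = surface_1d(lambda x: 4 * x[..., 0] ** 2,
                      lambda x: 8 * x)
    cfg = UmbrellaConfig(n_steps=1000)
    a = run_umbrella(line_path_1d(), surf, cfg, seed=5)
    b = run_umbrella(line_path_1d(), surf, cfg, seed=5)
    for wa, wb in zip(a, b):
        assert np.array_equal(wa.samples, wb.samples)


def test_constant_energy_offset_leaves_windows_unchanged():
    base = surface_1d(lambda x: 4 * x[..., 0] ** 2, lambda x: 8 * x)
    shifted = surface_1d(lambda x: 4 * x[..., 0] ** 2 + 25.0, lambda x: 8 * x)
    cfg = UmbrellaConfig(n_steps=800)
    a = run_umbrella(line_path_1d(), base, cfg, seed=6)
    b = run_umbrella(line_path_1d(), shifted, cfg, seed=6)
    ga = ui_pmf(a, np.linspace(0, 1, 51))
    gb = ui_pmf(b, np.linspace(0, 1, 51))
    assert np.array_equal(ga.a, gb.a)


# ------------------------------------------------------------- UI estimator


def test_ui_exact_for_exact_gaussian_moments():
    wins = gaussian_windows(32.0, standardize=True)
    grid = np.linspace(0, 1, 201)
    prof = ui_pmf(wins, grid)
    exact = 32.0 * (grid - 0.5) ** 2
    exact -= exact.min()
    assert np.max(np.abs(prof.a - exact)) < 1e-6


def test_ui_recovers_quadratic_from_sampled_gaussians():
    wins = gaussian_windows(8 * 4.0, seed=11)  # A = 8(2s-1)^2 = 32(s-1/2)^2
    grid = np.linspace(0, 1, 201)
    prof = ui_pmf(wins, grid)
    exact = 8.0 * (2 * grid - 1) ** 2
    exact -= exact.min()
    rms = np.sqrt(np.mean((prof.a - exact) ** 2))
    assert rms < 0.05


def test_ui_flat_profile_stays_within_its_own_ci():
    wins = gaussian_windows(1e-9, seed=3)
    grid = np.linspace(0, 1, 101)
    prof = ui_pmf(wins, grid)
    ci = ui_confidence(wins, grid, n_boot=100, seed=4)
    spread = prof.a.max() - prof.a.min()
    assert spread < 3 * ci.max() + 1e-6


def test_ui_requires_overlap_and_enough_windows():
    grid = np.linspace(0, 1, 51)
    with pytest.raises(ValueError):
        ui_pmf([gaussian_windows(1.0)[0]], grid)
    rng = np.random.default_rng(0)
    far = [UmbrellaWindow(center=c, k=1e5,
                          samples=c + 1e-3 * rng.standard_normal(200))
           for c in (0.0, 0.9)]
    with pytest.raises(ValueError, match="gap"):
        ui_pmf(far, grid)


# ----------------------------------------------------------- confidence bands


def test_ci_zero_for_degenerate_windows():
    rng = np.random.default_rng(1)
    wins = []
    for c in np.linspace(0, 1, 12):
        block = np.full(400, c) + 1e-6  # constant series
        wins.append(UmbrellaWindow(center=float(c), k=100.0, samples=block))
    ci = ui_confidence(wins, np.linspace(0, 1, 51), n_boot=60, seed=2)
    assert np.allclose(ci, 0.0, atol=1e-4)


def test_ci_scales_with_sample_size():
    grid = np.linspace(0, 1, 101)
    small = gaussian_windows(32.0, n_samples=1000, seed=7)
    big = gaussian_windows(32.0, n_samples=4000, seed=7)
    ci_small = ui_confidence(small, grid, n_boot=200, seed=9)
    ci_big = ui_confidence(big, grid, n_boot=200, seed=9)
    ratio = ci_big[20:-20].mean() / ci_small[20:-20].mean()
    assert 0.35 < ratio < 0.65


def test_ci_deterministic_under_fixed_seed():
    wins = gaussian_windows(32.0, seed=5)
    grid = np.linspace(0, 1, 51)
    a = ui_confidence(wins, grid, n_boot=80, seed=13)
    b = ui_confidence(wins, grid, n_boot=80, seed=13)
    assert np.array_equal(a, b)
    with pytest.raises(ValueError):
        ui_confidence(wins, grid, n_boot=20, seed=13)


# ------------------------------------------------------------ classification


def _two_bump(dip):
    """Broad barrier with a central dip of depth ~``dip`` between the two
    resulting maxima."""
    s = np.linspace(0, 1, 201)
    a = (14.0 * np.exp(-((s - 0.5) ** 2) / 0.05)
         - dip * np.exp(-((s - 0.5) ** 2) / 0.001))
    return s, a


def test_classify_two_bump_with_clear_dip():
    s, a = _two_bump(2.0)  # realized interior dip depth ~1.2
    prof = analyze_profile(s, a, min_depth=0.5)
    assert prof.classification == "two_step"
    heights = [v["height"] for k, v in prof.barriers.items()
               if k.startswith("ts")]
    assert len(heights) == 2


def test_classify_monotone_single_bump_one_step():
    s = np.linspace(0, 1, 101)
    a = 10.0 * np.exp(-((s - 0.5) ** 2) / 0.03)
    prof = analyze_profile(s, a, min_depth=0.1)
    assert prof.classification == "one_step"


def test_classify_shallow_dip_below_threshold_one_step():
    s, a = _two_bump(0.15)  # realized dip ~0.06, under the 0.1 floor
    prof = analyze_profile(s, a, min_depth=0.1)
    assert prof.classification == "one_step"


def test_classify_profile_reclassifies_with_ci():
    s, a = _two_bump(0.8)  # realized dip ~0.23
    prof = analyze_profile(s, a, np.full_like(a, 0.2))
    assert prof.classification == "two_step"
    strict = classify_profile(prof, min_depth=1.0)
    assert strict.classification == "one_step"
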