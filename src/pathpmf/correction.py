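"""Cubic-spline correction of a low-level PMF to a high-level energy
function from pointwise single-point energy differences along the path.

The workflow mirrors the standard semiempirical-to-DFT correction of
QM/MM free-energy profiles: structures along the reaction path are
(optionally) relaxed on the low-level surface within the path tube, both
energy functions are evaluated at those points, the pointwise difference
ΔE = E_high − E_low is interpolated with a cubic spline in the progress
coordinate s, and the interpolant is applied to the PMF.  The sign
convention is fixture-validated: with the default ``add_high_minus_low``
the corrected profile matches the high-level surface when the low-level
profile matches the low-level surface.  The method assumes the low- and
high-level minimum free-energy paths are similar, which
:func:`check_path_similarity` quantifies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize

from .path_cv import PathCV, path_rmsd
from .profiles import PMFProfile, analyze_profile
from .surfaces import LowHighSurfacePair

__all__ = [
    "CorrectionTable",
    "build_correction",
    "spline_correct",
    "check_path_similarity",
]


@dataclass(frozen=True)
class CorrectionTable:
    """Sampled low/high single-point energies along the path."""

    s: np.ndarray
    e_low: np.ndarray
    e_high: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.s, float)
        e_low = np.asarray(self.e_low, float)
        e_high = np.asarray(self.e_high, float)
        if s.ndim != 1 or len(s) < 4:
            raise ValueError("a cubic-spline correction needs >= 4 points")
        if np.any(np.diff(s) <= 0):
            raise ValueError("correction s values must be sorted and distinct")
        if s[0] < -1e-9 or s[-1] > 1 + 1e-9:
            raise ValueError("correction points must lie in s ∈ [0, 1]")
        if e_low.shape != s.shape or e_high.shape != s.shape:
            raise ValueError("energy columns must align with s")
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "e_low", e_low)
        object.__setattr__(self, "e_high", e_high)

    @property
    def delta(self) -> np.ndarray:
        """ΔE = E_high − E_low at the sample points."""
        return self.e_high - self.e_low

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"s": self.s, "E_low": self.e_low,
                             "E_high": self.e_high, "dE": self.delta})


def _relax_in_tube(pair: LowHighSurfacePair, path: PathCV, x0: np.ndarray,
                   s_fix: float, radius: float = 0.2) -> np.ndarray:
    """Minimize the low-level energy in the hyperplane perpendicular to the
    path tangent at s_fix (scaled CV space), i.e. relax within the tube
    cross-section before taking single-point energies.

    The search is bounded to ``radius`` (scaled units) around the path so
    the relaxation stays local instead of sliding into a flanking basin.
    """
    from scipy.optimize import minimize_scalar

    metric = path.metric
    y0 = metric.unwrap_sequence(np.vstack([path.point_at(s_fix), x0]))[1] \
        / metric.scales
    _, _, seg, _, _ = path.project_full(x0)
    tan = path.scaled[seg + 1] - path.scaled[seg]
    tan = tan / np.linalg.norm(tan)
    # orthonormal basis of the tangent's complement
    basis = np.linalg.svd(tan[None, :])[2][1:]
    if basis.shape[0] == 0:
        return np.array(x0, float)

    def energy_u(u):
        y = y0 + np.atleast_1d(u) @ basis
        return float(pair.low.energy(metric.wrap(y * metric.scales)))

    if basis.shape[0] == 1:
        res = minimize_scalar(energy_u, bounds=(-radius, radius),
                              method="bounded",
                              options={"xatol": 1e-10})
        u_best = np.array([res.x])
    else:
        res = minimize(energy_u, np.zeros(basis.shape[0]),
                       method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 400})
        u_best = np.clip(res.x, -radius, radius)
    y = y0 + u_best @ basis
    return metric.wrap(y * metric.scales)


def build_correction(pair: LowHighSurfacePair, path: PathCV,
                     n_points: int = 13,
                     local_relax: bool = True) -> CorrectionTable:
    """Tabulate E_low / E_high at ``n_points`` equally spaced s values.

    With ``local_relax`` the evaluation points are first relaxed on the
    low-level surface within the tube cross-section (the analogue of
    optimizing structures at the low level before the high-level
    single-point calculations).
    """
    if n_points < 4:
        raise ValueError("n_points must be >= 4 for a cubic spline")
    s_vals = np.linspace(0.0, 1.0, n_points)
    pts = path.point_at(s_vals)
    if local_relax:
        pts = np.array([
            _relax_in_tube(pair, path, pts[i], s_vals[i])
            for i in range(n_points)
        ])
    return CorrectionTable(s=s_vals, e_low=pair.low.energy(pts),
                           e_high=pair.high.energy(pts))


def spline_correct(profile: PMFProfile, table: CorrectionTable,
                   convention: str = "add_high_minus_low",
                   bc_type: str = "not-a-knot",
                   min_depth: float | None = None) -> PMFProfile:
    """Apply the interpolated ΔE to a PMF and re-analyze it.

    ``convention='add_high_minus_low'`` (default, fixture-validated) adds
    ΔE = E_high − E_low so the corrected profile tracks the high-level
    surface; ``'subtract_delta'`` applies the opposite sign.  The default
    ``not-a-knot`` boundary condition reproduces polynomial ΔE up to cubic
    exactly; ``'natural'`` and ``'clamped'`` are accepted as well.
    Confidence halfwidths are propagated unchanged (the single-point
    energies carry no sampling error of their own).  Grid points outside
    the table range are rejected rather than extrapolated.
    """
    if convention not in ("add_high_minus_low", "subtract_delta"):
        raise ValueError(f"unknown correction convention {convention!r}")
    grid = profile.s
    if grid[0] < table.s[0] - 1e-9 or grid[-1] > table.s[-1] + 1e-9:
        raise ValueError(
            f"profile grid [{grid[0]:.3f}, {grid[-1]:.3f}] extends beyond "
            f"the correction table range [{table.s[0]:.3f}, {table.s[-1]:.3f}]")
    spline = CubicSpline(table.s, table.delta, bc_type=bc_type)
    signed = 1.0 if convention == "add_high_minus_low" else -1.0
    corrected = profile.a + signed * spline(grid)
    return analyze_profile(grid, corrected, profile.ci, min_depth=min_depth)


def check_path_similarity(path_low: PathCV, path_high: PathCV,
                          tol: float = 0.25) -> dict:
    """Compare low- and high-level paths; warn (not fail) beyond ``tol``.

    Returns a report dict with the arc-length-matched path RMSD (scaled CV
    units), the tolerance and a pass flag.
    """
    rmsd = path_rmsd(path_low, path_high)
    ok = rmsd <= tol
    if not ok:
        warnings.warn(
            f"low- and high-level paths differ (RMSD {rmsd:.3f} > tol {tol}); "
            "the spline correction assumes similar paths", stacklevel=2)
    return {"rmsd": rmsd, "tol": tol, "ok": ok}
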