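"""Analytic energy surfaces emulating a two-step acylation landscape.

The central object is :class:`EnergySurface`, a differentiable energy
function over a small set of named collective variables.  Two families are
provided:

* :func:`muller_brown` — the standard four-Gaussian 2-D validation surface
  for minimum-free-energy-path (MFEP) methods;
* :func:`two_step_surface` — a reaction coordinate ``r`` carrying a
  double-barrier profile (proton-transfer TS1, bond-cleavage TS2, shallow
  tetrahedral-intermediate minimum in between) coupled to a periodic
  angle-like coordinate ``theta`` whose equilibrium value switches smoothly
  from ≈0° on the reactant side to ≈90° on the product side, emulating the
  T-stacked → parallel ring flip that accompanies acylation.

Energies are in reduced units chosen so that numbers read as kcal/mol at
300 K (kT = 0.5962).  Brute-force oracles — the exact marginal free energy
by quadrature and steepest-descent reference MFEPs through located saddle
points — live here as well, so the sampling pipeline can be validated
against closed-form answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import BPoly
from scipy.optimize import minimize, root
from scipy.special import expit, logsumexp

from .profiles import PMFProfile, analyze_profile

__all__ = [
    "KT_300K",
    "EnergySurface",
    "TwoStepSurfaceParams",
    "LowHighSurfacePair",
    "muller_brown",
    "two_step_surface",
    "two_step_pair",
    "exact_marginal_pmf",
    "reference_mfep",
    "find_stationary_points",
]

#: kT in kcal/mol at 300 K (k_B = 1.987204e-3 kcal/mol/K)
KT_300K = 0.5962


@dataclass(frozen=True)
class EnergySurface:
    """Differentiable energy over named coordinates.

    ``energy`` and ``gradient`` accept arrays of shape (..., dim) and return
    (...) and (..., dim) respectively, so walker ensembles evaluate in one
    vectorized call.  ``domain`` bounds the region used by quadrature and
    stationary-point searches; periodic coordinates use degrees on
    (−180, 180].
    """

    names: tuple[str, ...]
    domain: tuple[tuple[float, float], ...]
    periodic: tuple[bool, ...]
    _energy: Callable = field(repr=False)
    _gradient: Callable | None = field(default=None, repr=False)

    @property
    def dim(self) -> int:
        return len(self.names)

    def energy(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        e = self._energy(x)
        if not np.all(np.isfinite(e)):
            raise FloatingPointError("energy overflow / non-finite energy")
        return e

    def gradient(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        if self._gradient is not None:
            return self._gradient(x)
        return self._fd_gradient(x)

    def _fd_gradient(self, x, h: float = 1e-6) -> np.ndarray:
        g = np.empty_like(x, dtype=float)
        for k in range(self.dim):
            dx = np.zeros(self.dim)
            dx[k] = h
            g[..., k] = (self._energy(x + dx) - self._energy(x - dx)) / (2 * h)
        return g

    def index(self, name: str) -> int:
        return self.names.index(name)


# ---------------------------------------------------------------------------
# Müller–Brown


_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])


def muller_brown() -> EnergySurface:
    """The standard Müller–Brown four-Gaussian test surface."""

    def energy(x):
        dx = x[..., 0, None] - _MB_x0
        dy = x[..., 1, None] - _MB_y0
        expo = np.minimum(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2, 500.0)
        terms = _MB_A * np.exp(expo)
        return terms.sum(axis=-1)

    def gradient(x):
        dx = x[..., 0, None] - _MB_x0
        dy = x[..., 1, None] - _MB_y0
        expo = np.minimum(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2, 500.0)
        terms = _MB_A * np.exp(expo)
        gx = (terms * (2 * _MB_a * dx + _MB_b * dy)).sum(axis=-1)
        gy = (terms * (_MB_b * dx + 2 * _MB_c * dy)).sum(axis=-1)
        return np.stack([gx, gy], axis=-1)

    return EnergySurface(
        names=("x", "y"),
        domain=((-1.8, 1.2), (-0.5, 2.2)),
        periodic=(False, False),
        _energy=energy,
        _gradient=gradient,
    )


# ---------------------------------------------------------------------------
# two-step acylation surrogate


@dataclass(frozen=True)
class TwoStepSurfaceParams:
    """Geometry of the two-step reaction profile and its angle coupling.

    Positions are along the reduced reaction coordinate ``r`` (MC at
    ``r_mc``, AE at ``r_ae``); energies are reduced kcal/mol relative to the
    Michaelis complex.  ``kappa`` is the stiffness (energy/deg², convention
    E = κ·Δθ²) tying ``theta`` to its reaction-dependent equilibrium
    ``theta_eq(r)``, a logistic switch of width ``switch_width`` centered at
    ``switch_center``.  ``theta_friction`` is the relative Langevin friction
    multiplier for ``theta`` (its relaxation-time dial).
    """

    r_mc: float = 0.0
    r_ts1: float = 0.25
    r_ti: float = 0.5
    r_ts2: float = 0.75
    r_ae: float = 1.0
    e_mc: float = 0.0
    e_ts1: float = 14.0
    e_ti: float = 13.0
    e_ts2: float = 16.0
    e_ae: float = -2.0
    kappa: float = 0.006
    theta_mc: float = 0.0
    theta_ae: float = 90.0
    switch_center: float = 0.5
    switch_width: float = 0.18
    wall_k: float = 200.0
    theta_friction: float = 5.0

    def validate(self) -> None:
        r = [self.r_mc, self.r_ts1, self.r_ti, self.r_ts2, self.r_ae]
        if any(b <= a for a, b in zip(r, r[1:])):
            raise ValueError("stationary-point positions must be strictly ordered")
        if not (self.e_ts1 > self.e_ti and self.e_ts2 > self.e_ti):
            raise ValueError("TI must lie below both transition states "
                             "(TI depth must be positive)")
        if not (self.e_ts1 > self.e_mc and self.e_ts2 > self.e_ae):
            raise ValueError("barriers must lie above their adjacent basins")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.switch_width <= 0:
            raise ValueError("switch_width must be > 0 (theta_eq must be "
                             "monotone in r)")

    @property
    def ti_depth(self) -> float:
        return min(self.e_ts1, self.e_ts2) - self.e_ti

    def theta_eq(self, r):
        z = (np.asarray(r, float) - self.switch_center) / self.switch_width
        return self.theta_mc + (self.theta_ae - self.theta_mc) * expit(z)

    def theta_eq_prime(self, r):
        z = (np.asarray(r, float) - self.switch_center) / self.switch_width
        sig = expit(z)
        return (self.theta_ae - self.theta_mc) * sig * (1 - sig) / self.switch_width

    def to_dict(self) -> dict:
        return asdict(self)


def _wrap_deg(x):
    w = np.asarray(x) % 360.0
    return np.where(w > 180.0, w - 360.0, w)


def two_step_surface(params: TwoStepSurfaceParams | None = None) -> EnergySurface:
    """Build the coupled (r, theta) two-step acylation surrogate surface.

    Along ``theta = theta_eq(r)`` the energy is a piecewise-cubic Hermite
    profile with stationary points exactly at the configured MC, TS1, TI,
    TS2 and AE positions (zero slope at each), continued outside the
    reaction interval by harmonic confinement walls.  The coupling term
    ``κ·wrap(θ − θ_eq(r))²`` vanishes identically on the equilibrium curve,
    so the ridge profile equals the 1-D profile by construction.
    """
    p = params or TwoStepSurfaceParams()
    p.validate()
    knots = np.array([p.r_mc, p.r_ts1, p.r_ti, p.r_ts2, p.r_ae])
    vals = np.array([p.e_mc, p.e_ts1, p.e_ti, p.e_ts2, p.e_ae])
    # C2 quintic backbone: stationary (zero slope) at every knot, second
    # derivatives from local second differences so curvature varies smoothly
    # across the saddles (a kinked curvature profile is unphysical and
    # breaks local-Gaussian PMF estimators sampling across it)
    second = np.empty(5)
    for i in range(5):
        lo, hi = max(0, i - 1), min(4, i + 1)
        if lo == i:
            lo, hi = i, i + 1
            second[i] = 2 * (vals[hi] - vals[i]) / (knots[hi] - knots[i]) ** 2
        elif hi == i:
            second[i] = 2 * (vals[lo] - vals[i]) / (knots[lo] - knots[i]) ** 2
        else:
            h1, h2 = knots[i] - knots[lo], knots[hi] - knots[i]
            second[i] = 2 * ((vals[hi] - vals[i]) / h2
                             + (vals[lo] - vals[i]) / h1) / (h1 + h2)
    # back off the knot curvatures if the quintic wiggles between knots
    # (alpha = 0 gives the zero-curvature quintic, monotone per interval)
    rr = np.linspace(p.r_mc, p.r_ae, 2001)
    for alpha in (1.0, 0.5, 0.25, 0.1, 0.0):
        spline = BPoly.from_derivatives(
            knots, [[v, 0.0, alpha * s2] for v, s2 in zip(vals, second)])
        dspline = spline.derivative()
        signs = np.sign(dspline(rr))
        signs = signs[signs != 0]
        flips = np.sum(np.abs(np.diff(signs)) > 1)
        if flips == 3:  # rising, falling, rising, falling across 4 intervals
            break
    else:
        raise ValueError("surface parameters produce a wiggly backbone "
                         "(extra stationary points between the knots)")

    def v_r(r):
        r = np.asarray(r, float)
        rc = np.clip(r, p.r_mc, p.r_ae)
        v = spline(rc)
        lo = r < p.r_mc
        hi = r > p.r_ae
        v = v + np.where(lo, p.wall_k * (r - p.r_mc) ** 2, 0.0)
        v = v + np.where(hi, p.wall_k * (r - p.r_ae) ** 2, 0.0)
        return v

    def v_r_prime(r):
        r = np.asarray(r, float)
        rc = np.clip(r, p.r_mc, p.r_ae)
        g = dspline(rc)
        g = g + np.where(r < p.r_mc, 2 * p.wall_k * (r - p.r_mc), 0.0)
        g = g + np.where(r > p.r_ae, 2 * p.wall_k * (r - p.r_ae), 0.0)
        return g

    def energy(x):
        r, th = x[..., 0], x[..., 1]
        d = _wrap_deg(th - p.theta_eq(r))
        return v_r(r) + p.kappa * d**2

    def gradient(x):
        r, th = x[..., 0], x[..., 1]
        d = _wrap_deg(th - p.theta_eq(r))
        gr = v_r_prime(r) - 2 * p.kappa * d * p.theta_eq_prime(r)
        gt = 2 * p.kappa * d
        return np.stack([gr, gt], axis=-1)

    return EnergySurface(
        names=("r", "theta"),
        domain=((p.r_mc - 0.3, p.r_ae + 0.3), (-180.0, 180.0)),
        periodic=(False, True),
        _energy=energy,
        _gradient=gradient,
    )


@dataclass(frozen=True)
class LowHighSurfacePair:
    """A low-level surface and a high-level one over the same coordinates,
    emulating a semiempirical landscape and its DFT counterpart."""

    low: EnergySurface
    high: EnergySurface

    def __post_init__(self):
        if self.low.names != self.high.names or self.low.domain != self.high.domain:
            raise ValueError("paired surfaces must share coordinates and domain")

    def delta(self, x) -> np.ndarray:
        """E_high − E_low at x."""
        return self.high.energy(x) - self.low.energy(x)


def _perturbed(surface: EnergySurface, extra: Callable,
               extra_grad: Callable | None = None) -> EnergySurface:
    def energy(x):
        return surface._energy(x) + extra(x)

    grad = None
    if extra_grad is not None and surface._gradient is not None:
        def grad(x):  # noqa: E306
            return surface._gradient(x) + extra_grad(x)

    return EnergySurface(surface.names, surface.domain, surface.periodic,
                         _energy=energy, _gradient=grad)


def two_step_pair(low_params: TwoStepSurfaceParams | None = None,
                  ti_deepening: float = 1.5,
                  ti_width: float = 0.1) -> LowHighSurfacePair:
    """Low/high surface pair whose high level deepens the TI dip by a smooth
    Gaussian well of depth ``ti_deepening`` centered at the TI position —
    the situation where a higher-level correction turns a marginal
    intermediate into a clear one."""
    p = low_params or TwoStepSurfaceParams()
    low = two_step_surface(p)

    def extra(x):
        r = x[..., 0]
        return -ti_deepening * np.exp(-((r - p.r_ti) ** 2) / (2 * ti_width**2))

    def extra_grad(x):
        r = x[..., 0]
        g = np.zeros_like(x, dtype=float)
        g[..., 0] = (ti_deepening * (r - p.r_ti) / ti_width**2
                     * np.exp(-((r - p.r_ti) ** 2) / (2 * ti_width**2)))
        return g

    return LowHighSurfacePair(low=low, high=_perturbed(low, extra, extra_grad))


# ---------------------------------------------------------------------------
# oracles


def exact_marginal_pmf(surface: EnergySurface, coordinate: str,
                       grid, temperature: float = KT_300K,
                       tol: float = 1e-4) -> PMFProfile:
    """Exact marginal free energy F(x) = −kT ln ∫ exp(−E/kT) d(others) by
    refined trapezoid quadrature, min-normalized.

    Only 2-D surfaces are supported (all surfaces in this package are 2-D);
    the integrated coordinate uses its full periodic circle when periodic,
    its domain interval otherwise.  The quadrature grid is doubled until
    successive profiles differ by less than ``tol`` everywhere.
    """
    if surface.dim != 2:
        raise ValueError("exact_marginal_pmf supports 2-D surfaces")
    kt = float(temperature)
    keep = surface.index(coordinate)
    other = 1 - keep
    lo, hi = surface.domain[other]
    grid = np.asarray(grid, float)

    def profile(n: int) -> np.ndarray:
        u = np.linspace(lo, hi, n, endpoint=not surface.periodic[other])
        pts = np.empty((len(grid), len(u), 2))
        pts[..., keep] = grid[:, None]
        pts[..., other] = u[None, :]
        e = surface.energy(pts)
        du = (hi - lo) / (n - (0 if surface.periodic[other] else 1))
        return -kt * (logsumexp(-e / kt, axis=1) + np.log(du))

    n = 129
    f_prev = profile(n)
    for _ in range(12):
        n = 2 * n - 1
        f = profile(n)
        if np.max(np.abs(f - f_prev)) < tol:
            break
        f_prev = f
    else:
        raise RuntimeError("marginal quadrature did not converge")
    if not np.all(np.isfinite(f)):
        raise ValueError("divergent marginal integral")
    return analyze_profile(grid, f - f.min(), min_depth=1e-3)


def find_stationary_points(surface: EnergySurface, n_grid: int = 121,
                           gtol: float = 1e-8) -> dict:
    """Locate minima and index-1 saddles by polishing gradient roots seeded
    from a dense grid; classification by the finite-difference Hessian."""
    (x0, x1), (y0, y1) = surface.domain
    xs = np.linspace(x0, x1, n_grid)
    ys = np.linspace(y0, y1, n_grid)
    pts = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1)
    gn = np.linalg.norm(surface.gradient(pts), axis=-1)
    # candidate seeds: local minima of |grad| on the grid
    seeds = []
    interior = gn[1:-1, 1:-1]
    neigh = np.stack([gn[:-2, 1:-1], gn[2:, 1:-1], gn[1:-1, :-2], gn[1:-1, 2:]])
    mask = (interior <= neigh.min(axis=0))
    ii, jj = np.where(mask)
    for i, j in zip(ii + 1, jj + 1):
        seeds.append(pts[i, j])

    def hess(x, h=1e-4):
        H = np.empty((2, 2))
        for k in range(2):
            dx = np.zeros(2)
            dx[k] = h
            H[:, k] = (surface.gradient(x + dx) - surface.gradient(x - dx)) / (2 * h)
        return 0.5 * (H + H.T)

    minima, saddles = [], []
    for seed in seeds:
        sol = root(lambda x: surface.gradient(x), seed, tol=1e-12)
        if not sol.success or np.linalg.norm(surface.gradient(sol.x)) > gtol:
            continue
        x = sol.x
        if not all(lo - 1e-9 <= xi <= hi + 1e-9
                   for xi, (lo, hi) in zip(x, surface.domain)):
            continue
        ev = np.linalg.eigvalsh(hess(x))
        bucket = None
        if np.all(ev > 1e-8):
            bucket = minima
        elif ev[0] < -1e-8 < 1e-8 < ev[1]:
            bucket = saddles
        if bucket is None:
            continue
        if not any(np.linalg.norm(x - q) < 1e-5 for q in bucket):
            bucket.append(x)
    return {"minima": [np.array(m) for m in minima],
            "saddles": [np.array(s) for s in saddles]}


def _descend(surface: EnergySurface, start: np.ndarray,
             step: float = 2e-3, max_steps: int = 20000,
             gtol: float = 1e-3) -> np.ndarray:
    """Normalized steepest-descent polyline from ``start`` to a minimum.

    The descent uses normalized steps; once it stops making net progress
    (jittering around the basin bottom) the step is halved until it becomes
    negligible, and the endpoint is polished onto the minimum by BFGS, so
    the polyline does not accumulate jitter arc length.
    """
    path = [np.array(start, float)]
    x = np.array(start, float)
    step_cur = step
    checkpoint = x.copy()
    for i in range(1, max_steps + 1):
        g = surface.gradient(x)
        gn = np.linalg.norm(g)
        if gn < gtol or step_cur < 1e-7:
            break
        x = x - step_cur * g / max(gn, 1e-12)
        path.append(x.copy())
        if i % 25 == 0:
            if np.linalg.norm(x - checkpoint) < 0.3 * 25 * step_cur:
                step_cur *= 0.25
            checkpoint = x.copy()
    # polish endpoint onto the minimum
    res = minimize(lambda p: float(surface.energy(p)), x,
                   jac=lambda p: surface.gradient(p), method="BFGS",
                   options={"gtol": 1e-10})
    path.append(res.x)
    return np.array(path)


def _nearest(points: Sequence[np.ndarray], x: np.ndarray) -> int:
    return int(np.argmin([np.linalg.norm(q - x) for q in points]))


def reference_mfep(surface: EnergySurface, end_a, end_b,
                   resolution: float = 0.01) -> np.ndarray:
    """Reference MFEP as concatenated steepest-descent paths from saddles.

    Saddles and minima are located by dense-grid search; descent paths from
    each saddle identify which minima it connects, and a breadth-first
    search over the resulting minimum/saddle graph builds the route from
    the basin of ``end_a`` to that of ``end_b``.  The returned polyline is
    resampled to a spacing of at most ``resolution``.
    """
    end_a = np.atleast_1d(np.asarray(end_a, float))
    end_b = np.atleast_1d(np.asarray(end_b, float))
    if surface.dim == 1:
        # in one dimension the MFEP is the interval itself
        ra = minimize(lambda p: float(surface.energy(p)), end_a, method="BFGS",
                      options={"gtol": 1e-10}).x
        rb = minimize(lambda p: float(surface.energy(p)), end_b, method="BFGS",
                      options={"gtol": 1e-10}).x
        return _resample_polyline(np.array([ra, rb]), resolution)

    sp = find_stationary_points(surface)
    minima, saddles = sp["minima"], sp["saddles"]
    if not saddles or len(minima) < 2:
        raise ValueError("no connecting saddle found")

    def hess(x, h=1e-4):
        H = np.empty((2, 2))
        for k in range(2):
            dx = np.zeros(2)
            dx[k] = h
            H[:, k] = (surface.gradient(x + dx) - surface.gradient(x - dx)) / (2 * h)
        return 0.5 * (H + H.T)

    edges = {}  # (i, j) min indices -> polyline i -> j through the saddle
    for s in saddles:
        w, v = np.linalg.eigh(hess(s))
        u = v[:, 0]  # unstable direction
        down1 = _descend(surface, s + 1e-4 * u)
        down2 = _descend(surface, s - 1e-4 * u)
        i = _nearest(minima, down1[-1])
        j = _nearest(minima, down2[-1])
        if i == j:
            continue
        poly = np.vstack([down1[::-1], [s], down2])
        edges[(i, j)] = poly
        edges[(j, i)] = poly[::-1]

    start = _nearest(minima, end_a)
    goal = _nearest(minima, end_b)
    # BFS over the minima graph
    prev: dict[int, int | None] = {start: None}
    queue = [start]
    while queue:
        node = queue.pop(0)
        if node == goal:
            break
        for (i, j) in edges:
            if i == node and j not in prev:
                prev[j] = node
                queue.append(j)
    if goal not in prev:
        raise ValueError("no connecting saddle found between the endpoints")
    route = [goal]
    while prev[route[-1]] is not None:
        route.append(prev[route[-1]])
    route.reverse()
    pieces = [edges[(i, j)] for i, j in zip(route, route[1:])]
    return _resample_polyline(np.vstack(pieces), resolution)


def _resample_polyline(path: np.ndarray, spacing: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-12])
    path = path[keep]
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(2, int(np.ceil(total / spacing)) + 1)
    s_new = np.linspace(0.0, total, n)
    out = np.empty((n, path.shape[1]))
    for k in range(path.shape[1]):
        out[:, k] = np.interp(s_new, arc, path[:, k])
    return out
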