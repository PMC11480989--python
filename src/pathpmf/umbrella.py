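"""Umbrella sampling along the path progress coordinate s and PMF
estimation by umbrella integration (UI).

One umbrella window is spawned per string node, restrained to the node's
arc-length position by a harmonic bias on s plus a harmonic tube restraint
on the perpendicular distance z.  The tube keeps each window's sampling
local to the path — near a saddle the direction perpendicular to the path
can have negative curvature, and without the tube windows slide into the
flanking basins.  The reported A(s) is therefore the free energy along the
path within the tube (curvature/Jacobian corrections are out of scope).

UI combines per-window Gaussian approximations of the biased marginals:

    dA/ds |_i (s) = kT (s − s̄_i) / σ_i² − dU_i/ds,   U_i = k_i (s − c_i)²

weighted by p_i(s) ∝ n_i N(s; s̄_i, σ_i²), and integrates the mixture
derivative on the output grid.  The estimator is exact for quadratic A with
Gaussian window samples.  95% confidence bands come from a moving-block
bootstrap over each window's time series (block length from the integrated
autocorrelation time), re-normalized at the reactant minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .path_cv import PathCV
from .profiles import PMFProfile, analyze_profile, reclassify
from .sampler import run_langevin, stable_timestep
from .string_method import max_scaled_stiffness
from .surfaces import EnergySurface, KT_300K

__all__ = [
    "UmbrellaConfig",
    "UmbrellaWindow",
    "PathBias",
    "run_umbrella",
    "ui_pmf",
    "ui_confidence",
    "classify_profile",
    "converge_pmf",
]


@dataclass(frozen=True)
class UmbrellaWindow:
    """Post-equilibration s samples of one umbrella window."""

    center: float
    k: float
    samples: np.ndarray
    mean_cv: np.ndarray | None = None  # mean full-surface coordinates

    def __post_init__(self):
        samples = np.asarray(self.samples, float)
        if samples.ndim != 1 or len(samples) < 2:
            raise ValueError("a window needs at least 2 samples")
        object.__setattr__(self, "samples", samples)

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def var(self) -> float:
        return float(self.samples.var(ddof=1))


@dataclass(frozen=True)
class UmbrellaConfig:
    """Umbrella-sampling stage parameters.

    ``k_s`` and ``k_z`` default to auto-tuning: k_s = 2·kT/h² for window
    spacing h (stationary σ_s of half a spacing, convention E = k·Δ²), and
    k_z = k_s/L² so the tube is as stiff transversally (scaled CV units) as
    the windows are longitudinally.
    """

    n_steps: int = 4000
    equil_frac: float = 0.2
    temperature: float = KT_300K
    friction: float | None = None
    theta_friction: float = 1.0  # multiplier on the angle coordinate
    k_s: float | None = None
    k_z: float | None = None
    dt: float | None = None
    stride: int = 1
    half_convention: bool = False
    # the string polyline is spline-resampled this densely before umbrella
    # sampling so that polyline kinks cannot distort the window statistics;
    # smoothing None = adaptive: increase until every bend radius clears the
    # tube width (walkers must never reach the projection's medial axis,
    # where s jumps discontinuously)
    path_resolution: int = 1001
    path_smoothing: float | None = None


class PathBias:
    """Harmonic restraint on (s, z) of the path-CV projection.

    Per-walker centers: walker m is restrained to ``centers[m]``.  The s
    force uses the tangent of the projected segment (zero at vertex
    projections, where s is locally stationary); the z force is the exact
    gradient of the squared distance to the path.

    For speed each walker projects only onto a local span of segments
    around its own center — restrained walkers never travel further, and
    the span is sized with a generous margin from the window width.
    """

    def __init__(self, path: PathCV, centers, k_s: float, k_z: float,
                 cv_indices, dim: int, half: bool = False,
                 temperature: float = KT_300K):
        self.path = path
        self.centers = np.asarray(centers, float)
        factor = 0.5 if half else 1.0
        self.k_s = factor * float(k_s)
        self.k_z = factor * float(k_z)
        self.idx = list(cv_indices)
        self.dim = dim
        seg_vec = np.diff(path.scaled, axis=0)
        seg_len = np.linalg.norm(seg_vec, axis=1)
        n_seg = len(seg_len)
        sigma_s = np.sqrt(temperature / max(2.0 * self.k_s, 1e-12))
        span = min(n_seg, int(np.ceil((8 * sigma_s + 0.01) * n_seg)) + 8)
        c_seg = np.clip((self.centers * n_seg).astype(int), 0, n_seg - 1)
        lo = np.clip(c_seg - span, 0, max(0, n_seg - 2 * span - 1))
        self._segs = lo[:, None] + np.arange(2 * span + 1)[None, :]  # (M, W)
        self._a = path.scaled[:-1][self._segs]          # (M, W, d)
        self._ab = seg_vec[self._segs]
        self._len = seg_len[self._segs]
        self._tan = self._ab / self._len[..., None]
        self._arc = path.arcs[:-1][self._segs]
        per = path.metric.periodic
        self._periodic = per
        self._period = 360.0 / path.metric.scales[per]

    def _project_local(self, pts):
        """Project walker m onto its own segment span. pts: (M, d_cv)."""
        y = pts / self.path.metric.scales
        diff = y[:, None, :] - self._a
        if self._periodic.any():
            d = diff[..., self._periodic]
            diff[..., self._periodic] = d - np.round(d / self._period) * self._period
        t = np.clip(np.einsum("mwd,mwd->mw", diff, self._ab) / self._len**2,
                    0.0, 1.0)
        perp = diff - t[..., None] * self._ab
        dist = np.linalg.norm(perp, axis=-1)
        w = np.argmin(dist, axis=1)
        m = np.arange(len(y))
        s = (self._arc[m, w] + t[m, w] * self._len[m, w]) / self.path.length
        return s, dist[m, w], t[m, w], perp[m, w], self._tan[m, w]

    def project_s(self, x):
        """s values of full-surface samples (..., dim) via the local spans;
        trailing axis of the leading shape must index the walkers."""
        pts = x[..., self.idx]
        flat = pts.reshape(-1, len(self.centers), len(self.idx))
        out = np.empty(flat.shape[:2])
        for i in range(flat.shape[0]):
            out[i] = self._project_local(flat[i])[0]
        return out.reshape(pts.shape[:-1])

    def energy(self, x, scale: float = 1.0):
        s, z, *_ = self._project_local(x[..., self.idx])
        return scale * (self.k_s * (s - self.centers) ** 2 + self.k_z * z**2)

    def gradient(self, x, scale: float = 1.0):
        s, z, t, perp, tan = self._project_local(x[..., self.idx])
        g = np.zeros_like(x)
        # vertex projections keep the adjacent segment's tangent: on the
        # densely resampled curve the wedge where s is formally stationary
        # is a discretization artifact, and dropping the force there would
        # bias flank windows downhill
        ds = 2.0 * self.k_s * (s - self.centers)
        # chain rule to raw CV units: d/dx = (1/scale) d/dy
        g_cv = (ds[..., None] * tan / self.path.length
                + 2.0 * self.k_z * perp) / self.path.metric.scales
        g[..., self.idx] = g_cv
        return scale * g


def auto_window_constants(path: PathCV, n_windows: int,
                          temperature: float) -> tuple[float, float]:
    h = 1.0 / max(n_windows - 1, 1)
    k_s = 2.0 * temperature / h**2
    k_z = k_s / path.length**2
    return k_s, k_z


def _max_curvature(path: PathCV) -> float:
    t = np.diff(path.scaled, axis=0)
    tl = np.linalg.norm(t, axis=1)
    tn = t / tl[:, None]
    dphi = np.arccos(np.clip((tn[:-1] * tn[1:]).sum(axis=1), -1.0, 1.0))
    return float((dphi / (0.5 * (tl[:-1] + tl[1:]))).max())


def _smooth_until_round(path: PathCV, n: int, min_radius: float,
                        max_tries: int = 12) -> PathCV:
    """Spline-smooth the string until no bend is tighter than ``min_radius``
    (scaled units), so tube-confined walkers stay on one projection branch."""
    smoothing = 0.0
    for _ in range(max_tries):
        dense = path.smooth_resample(n, smoothing)
        if 1.0 / max(_max_curvature(dense), 1e-12) >= min_radius:
            return dense
        smoothing = max(4.0 * smoothing, 1e-4)
    return dense


def run_umbrella(path: PathCV, surface: EnergySurface, cfg: UmbrellaConfig,
                 seed: int, cv_indices=None, init_template=None,
                 centers=None) -> list[UmbrellaWindow]:
    """Sample one umbrella window per string node (vectorized ensemble).

    ``init_template`` supplies full surface coordinates per window for
    coordinates outside the path space (e.g. the angle CV in a run that
    excludes it); by default windows start on the path nodes and, for
    excluded coordinates, from the template rows.
    """
    metric = path.metric
    if cv_indices is None:
        cv_indices = tuple(range(surface.dim))
    idx = list(cv_indices)
    if centers is None:
        centers = path.node_s()
    centers = np.asarray(centers, float)
    m = len(centers)
    kt = cfg.temperature
    k_s, k_z = auto_window_constants(path, m, kt)
    if cfg.k_s is not None:
        k_s = cfg.k_s
    if cfg.k_z is not None:
        k_z = cfg.k_z
    if cfg.path_resolution > path.n_nodes:
        if cfg.path_smoothing is not None:
            path = path.smooth_resample(cfg.path_resolution, cfg.path_smoothing)
        else:
            sigma_z = np.sqrt(kt / (2.0 * k_z))
            path = _smooth_until_round(path, cfg.path_resolution,
                                       min_radius=4.0 * sigma_z)
        k_s_auto, k_z_auto = auto_window_constants(path, m, kt)
        k_s = cfg.k_s if cfg.k_s is not None else k_s_auto
        k_z = cfg.k_z if cfg.k_z is not None else k_z_auto

    if init_template is None:
        init = np.zeros((m, surface.dim))
    else:
        init = np.array(np.broadcast_to(init_template, (m, surface.dim)), float)
    init[:, idx] = path.point_at(centers)

    mass = np.ones(surface.dim)
    for j, coord in enumerate(idx):
        mass[coord] = 1.0 / metric.scales[j] ** 2
    # stiffness seen in scaled units: s-bias acts through arc length L
    k_bias_scaled = max(k_s / path.length**2, k_z)
    k_stiff = max(k_bias_scaled, max_scaled_stiffness(surface, init, mass))
    dt = cfg.dt or stable_timestep(k_stiff)
    friction = np.full(surface.dim,
                       cfg.friction if cfg.friction is not None
                       else np.sqrt(2.0 * k_bias_scaled))
    theta_like = [c for c in range(surface.dim) if surface.periodic[c]]
    friction[theta_like] *= cfg.theta_friction

    bias = PathBias(path, centers, k_s, k_z, idx, surface.dim,
                    half=cfg.half_convention, temperature=kt)
    traj = run_langevin(surface, [bias], init, n_steps=cfg.n_steps, dt=dt,
                        temperature=kt, friction=friction, seed=seed,
                        mass=mass, stride=cfg.stride)
    n_equil = int(np.ceil(cfg.equil_frac * traj.positions.shape[0]))
    kept = traj.positions[n_equil:]
    if kept.shape[0] < 2:
        raise ValueError("no post-equilibration samples in umbrella windows")
    s_all = bias.project_s(kept)

    windows = []
    for w in range(m):
        coords = kept[:, w, :]
        mean_cv = coords.mean(axis=0)
        for c in theta_like:
            ang = np.deg2rad(coords[:, c])
            mean_cv[c] = np.rad2deg(np.arctan2(np.sin(ang).mean(),
                                               np.cos(ang).mean()))
        windows.append(UmbrellaWindow(center=float(centers[w]), k=k_s,
                                      samples=s_all[:, w], mean_cv=mean_cv))
    return windows


def _window_stats(windows):
    c = np.array([w.center for w in windows])
    k = np.array([w.k for w in windows])
    mu = np.array([w.mean for w in windows])
    var = np.array([w.var for w in windows])
    n = np.array([w.n for w in windows], float)
    if np.any(var <= 0):
        var = np.maximum(var, 1e-12)
    return c, k, mu, var, n


def _ui_integrate(grid, c, k, mu, var, n, kt, half):
    """Weighted UI mean-force mixture, integrated by trapezoid."""
    keff = 0.5 * k if half else k
    s = grid[:, None]
    da_i = kt * (s - mu) / var - 2.0 * keff * (s - c)
    log_w = np.log(n) - 0.5 * (s - mu) ** 2 / var - 0.5 * np.log(var)
    log_w -= log_w.max(axis=1, keepdims=True)
    w = np.exp(log_w)
    da = (w * da_i).sum(axis=1) / w.sum(axis=1)
    a = np.concatenate([[0.0], np.cumsum(0.5 * (da[1:] + da[:-1]) * np.diff(grid))])
    return a - a.min()


def ui_pmf(windows, grid, temperature: float = KT_300K,
           half_convention: bool = False, min_depth: float | None = None,
           depth_floor: float | None = None) -> PMFProfile:
    """Umbrella-integration PMF on ``grid`` from sampled windows."""
    if len(windows) < 2:
        raise ValueError("umbrella integration needs at least 2 windows")
    grid = np.asarray(grid, float)
    c, k, mu, var, n = _window_stats(windows)
    order = np.argsort(mu)
    gaps = np.diff(mu[order]) - 3.0 * (np.sqrt(var[order][:-1]) + np.sqrt(var[order][1:]))
    bad = np.where(gaps > 0)[0]
    if len(bad):
        locs = ", ".join(f"({mu[order][i]:.3f}, {mu[order][i + 1]:.3f})"
                         for i in bad[:5])
        raise ValueError(f"umbrella windows do not overlap; coverage gaps at {locs}")
    a = _ui_integrate(grid, c, k, mu, var, n, float(temperature), half_convention)
    kwargs = {} if depth_floor is None else {"depth_floor": depth_floor}
    return analyze_profile(grid, a, min_depth=min_depth, **kwargs)


def _block_length(x: np.ndarray, cap_frac: float = 0.1) -> int:
    """Integrated autocorrelation time estimate, capped at n/10."""
    x = x - x.mean()
    n = len(x)
    v = float(x @ x) / n
    if v <= 0:
        return 1
    tau = 1.0
    for lag in range(1, n // 2):
        rho = float(x[:-lag] @ x[lag:]) / ((n - lag) * v)
        if rho < 0.05:
            break
        tau += 2.0 * rho
    return int(np.clip(np.ceil(tau), 1, max(1, int(cap_frac * n))))


def ui_confidence(windows, grid, n_boot: int = 200,
                  block_len: int | None = None, seed: int = 0,
                  temperature: float = KT_300K,
                  half_convention: bool = False) -> np.ndarray:
    """95% CI halfwidths of the UI profile by moving-block bootstrap.

    Each bootstrap replicate resamples every window's time series in blocks
    (length = integrated autocorrelation time unless given), re-estimates
    A(s), re-normalizes at the reactant minimum of the point estimate, and
    the halfwidth is 1.96 × the replicate standard deviation.
    """
    if n_boot < 50:
        raise ValueError("n_boot must be at least 50")
    grid = np.asarray(grid, float)
    kt = float(temperature)
    c, k, mu, var, n = _window_stats(windows)
    point = _ui_integrate(grid, c, k, mu, var, n, kt, half_convention)
    # reactant reference: leftmost local minimum of the point estimate
    ref_idx = 0
    for i in range(1, len(point) - 1):
        if point[i] <= point[i - 1] and point[i] <= point[i + 1]:
            ref_idx = i
            break

    rng = np.random.default_rng(seed)
    boot_mu = np.empty((n_boot, len(windows)))
    boot_var = np.empty((n_boot, len(windows)))
    for j, w in enumerate(windows):
        x = w.samples
        b = block_len or _block_length(x)
        n_blocks = int(np.ceil(len(x) / b))
        starts = rng.integers(0, max(1, len(x) - b + 1), size=(n_boot, n_blocks))
        take = (starts[..., None] + np.arange(b)).reshape(n_boot, -1)[:, :len(x)]
        res = x[take]
        boot_mu[:, j] = res.mean(axis=1)
        boot_var[:, j] = res.var(axis=1, ddof=1)
    boot_var = np.maximum(boot_var, 1e-12)
    profiles = np.empty((n_boot, len(grid)))
    for r in range(n_boot):
        a = _ui_integrate(grid, c, k, boot_mu[r], boot_var[r], n, kt,
                          half_convention)
        profiles[r] = a - a[ref_idx]
    return 1.96 * profiles.std(axis=0, ddof=1)


def classify_profile(profile: PMFProfile, min_depth: float | None = None,
                     depth_floor: float = 0.1) -> PMFProfile:
    """Re-run stationary-point analysis / classification on a profile.

    An interior minimum only counts when its depth below the lower flanking
    maximum reaches ``min_depth`` (default: the local CI, floored).
    """
    return reclassify(profile, min_depth=min_depth, depth_floor=depth_floor)


def converge_pmf(path: PathCV, surface: EnergySurface, cfg: UmbrellaConfig,
                 grid, seed: int, threshold: float = 1.0,
                 max_rounds: int = 6, n_boot: int = 200,
                 cv_indices=None, init_template=None,
                 windows_per_node: int = 2):
    """Double the window sampling until the 95% CI at the highest barrier
    drops below ``threshold`` (the convergence rule of the workflow).

    Returns (profile, windows, rounds_used).
    """
    grid = np.asarray(grid, float)
    centers = np.linspace(0.0, 1.0, windows_per_node * (path.n_nodes - 1) + 1)
    for round_idx in range(max_rounds):
        windows = run_umbrella(path, surface, cfg, seed=seed + round_idx,
                               cv_indices=cv_indices, centers=centers,
                               init_template=init_template)
        prof = ui_pmf(windows, grid, cfg.temperature, cfg.half_convention)
        ci = ui_confidence(windows, grid, n_boot=n_boot, seed=seed + 7919,
                           temperature=cfg.temperature,
                           half_convention=cfg.half_convention)
        prof = analyze_profile(grid, prof.a, ci)
        if prof.maxima:
            top = max(prof.maxima, key=lambda p: p.a)
            if ci[top.index] < threshold:
                return prof, windows, round_idx + 1
        cfg = replace(cfg, n_steps=cfg.n_steps * 2)
    return prof, windows, max_rounds
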