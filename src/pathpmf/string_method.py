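"""Adaptive string method: evolve a discretized path of nodes in CV space
toward the minimum free-energy path (MFEP).

Each iteration runs restrained Langevin sampling at every node (the whole
string samples as one vectorized walker ensemble), moves each node a step
``eta`` toward its sampled mean CV (a mean-drift update whose fixed point
is the MFEP), re-anchors the endpoints to their basin minima by local
minimization, and reparameterizes the string to equal arc length in the
scaled CV metric.  Convergence is monitored through the mean per-node
displacement over a trailing window.

Node bias force constants are auto-tuned so that the stationary sampling
standard deviation is about half the inter-node spacing: in scaled CV
space, k_scaled = 2·kT/h² with h the mean node spacing (convention
E = k·Δ², for which the stationary variance is kT/(2k)); per-CV constants
are k_scaled divided by the squared CV scale.  Sampling masses are set to
1/scale² per CV so every scaled coordinate relaxes on the same timescale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .path_cv import CVMetric, PathCV
from .sampler import BiasSpec, CoordinateBias, RampSchedule, run_langevin, stable_timestep
from .surfaces import EnergySurface, KT_300K

__all__ = [
    "StringConfig",
    "StringState",
    "initialize_string",
    "iterate_string",
    "string_converged",
    "optimize_string",
]


@dataclass(frozen=True)
class StringConfig:
    """Knobs of the string optimization (defaults sized for 2-D surfaces)."""

    n_nodes: int = 96
    eta: float = 0.5
    samples_per_node: int = 250
    ramp_steps: int = 250
    friction: float | None = None  # None -> critically damp the bias mode
    temperature: float = KT_300K
    dt: float | None = None
    k_factor: float = 1.0
    max_iter: int = 80
    tol: float = 5e-3
    window: int = 5
    # reparameterizing inscribes chords and slowly shortens tight bends; doing
    # it every few iterations lets the mean drift push back in between
    reparam_every: int = 2


@dataclass(frozen=True)
class StringState:
    """Ordered node positions in CV space plus optimization bookkeeping.

    ``cv_indices`` maps CV components onto surface coordinates, so a string
    may live in a subspace of the surface (e.g. with the angle CV excluded);
    ``walker_x`` carries the full-dimensional sampling walkers between
    iterations — initially the endpoint-basin structures, half tagged to
    the reactant side and half to the product side.
    """

    nodes: np.ndarray
    metric: CVMetric
    cv_indices: tuple[int, ...]
    walker_x: np.ndarray | None = None
    k_scaled: float = 0.0
    iteration: int = 0
    displacement_history: tuple[float, ...] = ()

    def __post_init__(self):
        nodes = self.metric.wrap(np.asarray(self.nodes, float))
        object.__setattr__(self, "nodes", nodes)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def from_a(self) -> np.ndarray:
        """Which nodes started their walkers from the reactant basin."""
        return np.arange(self.n_nodes) < self.n_nodes // 2

    def path(self) -> PathCV:
        return PathCV(self.nodes, self.metric)


def _reparameterize(nodes: np.ndarray, metric: CVMetric) -> np.ndarray:
    """Resample nodes to equal arc length along their own polyline."""
    scaled = metric.unwrap_sequence(nodes) / metric.scales
    seg = np.linalg.norm(np.diff(scaled, axis=0), axis=1)
    arcs = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, arcs[-1], len(nodes))
    out = np.empty_like(scaled)
    for k in range(scaled.shape[1]):
        out[:, k] = np.interp(target, arcs, scaled[:, k])
    out[0], out[-1] = scaled[0], scaled[-1]
    return metric.wrap(out * metric.scales)


def initialize_string(end_a, end_b, n_nodes: int = 96,
                      metric: CVMetric | None = None,
                      cv_indices=None) -> StringState:
    """Straight initial string between two endpoint CV vectors.

    Interpolation is linear in scaled CV space; periodic CVs follow the
    shorter arc between the endpoint angles.  Node spacing is exactly
    equidistant by construction.
    """
    a = np.atleast_1d(np.asarray(end_a, float))
    b = np.atleast_1d(np.asarray(end_b, float))
    if metric is None:
        metric = CVMetric(np.ones(a.shape), np.zeros(a.shape, bool))
    if n_nodes < 3:
        raise ValueError("a string needs at least 3 nodes")
    if np.allclose(metric.diff(a, b), 0.0):
        raise ValueError("string endpoints must differ")
    step = metric.diff(b, a)  # shorter-arc difference for periodic CVs
    t = np.linspace(0.0, 1.0, n_nodes)[:, None]
    nodes = metric.wrap(a + t * step)
    if cv_indices is None:
        cv_indices = tuple(range(len(a)))
    return StringState(nodes=nodes, metric=metric, cv_indices=tuple(cv_indices))


def _lift(state: StringState, template: np.ndarray) -> np.ndarray:
    """Full-space walker coordinates: template with CV components replaced
    by the node positions."""
    x = np.array(template, float)
    x[:, list(state.cv_indices)] = state.nodes
    return x


def _circular_mean(samples: np.ndarray, periodic: np.ndarray) -> np.ndarray:
    """Mean over axis 0; circular mean (degrees) for periodic components."""
    mean = samples.mean(axis=0)
    if periodic.any():
        ang = np.deg2rad(samples[..., periodic])
        mean_ang = np.arctan2(np.sin(ang).mean(axis=0), np.cos(ang).mean(axis=0))
        mean[..., periodic] = np.rad2deg(mean_ang)
    return mean


def node_force_constants(state: StringState, temperature: float,
                         k_factor: float = 1.0) -> tuple[float, np.ndarray]:
    """Auto-tuned bias constants: scaled-space k = 2·kT·k_factor/h²."""
    scaled = state.metric.unwrap_sequence(state.nodes) / state.metric.scales
    seg = np.linalg.norm(np.diff(scaled, axis=0), axis=1)
    h = float(seg.mean())
    k_scaled = 2.0 * temperature * k_factor / max(h, 1e-9) ** 2
    return k_scaled, k_scaled / state.metric.scales**2


def max_scaled_stiffness(surface: EnergySurface, points: np.ndarray,
                         mass: np.ndarray, h: float = 1e-4) -> float:
    """Largest |curvature|/mass over the given points and coordinates, in
    the E = k·x² convention (i.e. half the bare second derivative), used to
    bound the integrator timestep."""
    points = np.atleast_2d(points)
    kmax = 0.0
    for coord in range(surface.dim):
        dx = np.zeros(surface.dim)
        dx[coord] = h
        g1 = surface.gradient(points + dx)[..., coord]
        g0 = surface.gradient(points - dx)[..., coord]
        curv = np.abs(g1 - g0).max() / (2 * h)
        kmax = max(kmax, 0.5 * curv / mass[coord])
    return kmax


def _relax_endpoint(surface: EnergySurface, x0: np.ndarray) -> np.ndarray:
    res = minimize(lambda p: float(surface.energy(p)), np.array(x0, float),
                   jac=lambda p: surface.gradient(p), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 200})
    return res.x


def iterate_string(state: StringState, surface: EnergySurface,
                   cfg: StringConfig, seed: int) -> StringState:
    """One string iteration: sample at the nodes, drift toward the sampled
    means, re-anchor the endpoints, reparameterize."""
    metric = state.metric
    idx = list(state.cv_indices)
    kt = cfg.temperature
    k_scaled, k_cv = node_force_constants(state, kt, cfg.k_factor)

    # full-space walkers: persist across iterations; on the first iteration
    # half start from the reactant structure, half from the product one
    if state.walker_x is not None:
        walkers = np.array(state.walker_x, float)
    else:
        walkers = _lift(state, np.broadcast_to(
            np.zeros(surface.dim), (state.n_nodes, surface.dim)).copy())

    biases = [
        CoordinateBias(coord, BiasSpec(k=k_cv[j], periodic=bool(metric.periodic[j])),
                       centers=state.nodes[:, j])
        for j, coord in enumerate(idx)
    ]
    mass = np.ones(surface.dim)
    for j, coord in enumerate(idx):
        mass[coord] = 1.0 / metric.scales[j] ** 2
    k_stiff = max(k_scaled, max_scaled_stiffness(surface, walkers, mass))
    dt = cfg.dt or stable_timestep(k_stiff)
    # near-critical damping of the bias mode keeps node means responsive
    friction = np.full(surface.dim,
                       cfg.friction if cfg.friction is not None
                       else np.sqrt(2.0 * k_scaled))
    schedule = RampSchedule(cfg.ramp_steps) if state.iteration == 0 else None
    n_steps = cfg.samples_per_node + (cfg.ramp_steps if schedule else 0)
    try:
        traj = run_langevin(surface, biases, walkers, n_steps=n_steps, dt=dt,
                            temperature=kt, friction=friction, seed=seed,
                            mass=mass, schedule=schedule)
    except FloatingPointError as exc:
        raise RuntimeError(
            f"string iteration {state.iteration}: sampler failed ({exc})"
        ) from exc
    samples = traj.positions[-cfg.samples_per_node:, :, :]
    mean_cv = _circular_mean(samples[..., idx], metric.periodic)

    drift = metric.diff(mean_cv, state.nodes)
    new_nodes = metric.wrap(state.nodes + cfg.eta * drift)

    # endpoints follow their basin minima rather than the sampled mean;
    # relaxation starts from the node (lifted to full space), not from the
    # diffused walker, so flat directions cannot random-walk the endpoints
    final_walkers = traj.positions[-1]
    for end, w in ((0, 0), (-1, state.n_nodes - 1)):
        x0 = np.array(final_walkers[w], float)
        x0[idx] = state.nodes[end]
        x_min = _relax_endpoint(surface, x0)
        new_nodes[end] = metric.wrap(x_min[idx])
    if (state.iteration + 1) % max(1, cfg.reparam_every) == 0:
        new_nodes = _reparameterize(new_nodes, metric)

    disp = float(np.mean(metric.distance(new_nodes, state.nodes)))
    return replace(
        state,
        nodes=new_nodes,
        walker_x=final_walkers,
        k_scaled=k_scaled,
        iteration=state.iteration + 1,
        displacement_history=state.displacement_history + (disp,),
    )


def string_converged(state: StringState, tol: float, window: int) -> bool:
    """True iff the mean per-node displacement over the last ``window``
    iterations fell below ``tol`` (scaled CV units)."""
    hist = state.displacement_history
    if len(hist) < window:
        return False
    return float(np.mean(hist[-window:])) < tol


def optimize_string(surface: EnergySurface, end_a, end_b,
                    metric: CVMetric | None = None,
                    cfg: StringConfig | None = None, seed: int = 0,
                    cv_indices=None, full_end_a=None, full_end_b=None,
                    snapshots: list | None = None) -> StringState:
    """Run string iterations until convergence or ``cfg.max_iter``.

    ``full_end_a`` / ``full_end_b`` supply complete surface coordinates for
    the two basins when the string lives in a CV subspace; walkers for the
    first half of the nodes start from the reactant structure and the rest
    from the product one.
    """
    cfg = cfg or StringConfig()
    state = initialize_string(end_a, end_b, cfg.n_nodes, metric, cv_indices)
    fa = np.asarray(full_end_a, float) if full_end_a is not None else None
    fb = np.asarray(full_end_b, float) if full_end_b is not None else None
    if fa is None:
        template = np.zeros((state.n_nodes, surface.dim))
    else:
        template = np.where(state.from_a[:, None], fa, fb)
    state = replace(state, walker_x=_lift(state, template))
    for it in range(cfg.max_iter):
        state = iterate_string(state, surface, cfg, seed=seed + it)
        if snapshots is not None:
            snapshots.append(state)
        if string_converged(state, cfg.tol, cfg.window):
            break
    # the node positions double as umbrella-window centers downstream, so
    # the returned string is always equidistant
    return replace(state, nodes=_reparameterize(state.nodes, state.metric))


def string_to_frame(state: StringState, cv_names=None):
    """Node table (node, s, CV columns) for CSV output."""
    return state.path().to_frame(cv_names)
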