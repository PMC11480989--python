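"""Path collective variable: progress coordinate s along a discretized
path in CV space and perpendicular tube distance z.

The path is the converged string polyline.  Mixing Å-valued and
degree-valued CVs requires a metric: each CV is divided by its
characteristic scale, and periodic CVs are unwrapped along the node
sequence so that arc lengths are well defined.  The projection is the
geometric (arc-length) one onto the piecewise-linear path: s is the
normalized arc-length of the closest path point and z the (scaled)
distance to it.  Ties between equidistant segments resolve toward the
smaller s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CVMetric", "PathCV", "path_rmsd", "frechet_distance"]


@dataclass(frozen=True)
class CVMetric:
    """Per-CV scale divisors and periodicity flags for CV-space geometry.

    Default scales follow the convention of 1 Å for distance-like CVs and
    30° for angular CVs; periodic CVs wrap on a 360° circle.
    """

    scales: np.ndarray
    periodic: np.ndarray

    def __post_init__(self):
        scales = np.atleast_1d(np.asarray(self.scales, float))
        periodic = np.atleast_1d(np.asarray(self.periodic, bool))
        if scales.shape != periodic.shape:
            raise ValueError("scales and periodic flags must align")
        if np.any(scales <= 0):
            raise ValueError("all CV scales must be > 0")
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "periodic", periodic)

    @classmethod
    def from_defs(cls, defs) -> "CVMetric":
        return cls(np.array([d.scale for d in defs]),
                   np.array([d.periodic for d in defs]))

    @property
    def dim(self) -> int:
        return len(self.scales)

    def wrap(self, values):
        """Wrap periodic components of raw CV values into (−180, 180]."""
        v = np.array(values, float)
        p = self.periodic
        w = v[..., p] % 360.0
        v[..., p] = np.where(w > 180.0, w - 360.0, w)
        return v

    def diff(self, a, b):
        """Raw-unit difference a − b with periodic wrapping."""
        d = np.asarray(a, float) - np.asarray(b, float)
        return self.wrap(d)

    def scaled_diff(self, a, b):
        return self.diff(a, b) / self.scales

    def distance(self, a, b):
        return np.linalg.norm(self.scaled_diff(a, b), axis=-1)

    def unwrap_sequence(self, nodes):
        """Unwrap periodic CVs along an ordered node sequence so that
        consecutive differences never jump across the period."""
        nodes = np.asarray(nodes, float)
        out = nodes.copy()
        p = self.periodic
        if p.any():
            steps = np.diff(nodes[:, p], axis=0)
            steps = (steps + 180.0) % 360.0 - 180.0
            out[1:, p] = nodes[0, p] + np.cumsum(steps, axis=0)
        return out


@dataclass(frozen=True)
class PathCV:
    """Arc-length parameterized polyline in scaled CV space."""

    nodes: np.ndarray          # raw CV units, wrapped
    metric: CVMetric
    scaled: np.ndarray = None  # unwrapped, divided by scales
    arcs: np.ndarray = None    # cumulative arc length, arcs[0] = 0

    def __post_init__(self):
        nodes = np.asarray(self.nodes, float)
        if nodes.ndim != 2 or nodes.shape[0] < 2:
            raise ValueError("a path needs at least two nodes")
        if nodes.shape[1] != self.metric.dim:
            raise ValueError("node dimension must match the metric")
        scaled = self.metric.unwrap_sequence(nodes) / self.metric.scales
        seg = np.linalg.norm(np.diff(scaled, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("degenerate path: repeated consecutive nodes")
        arcs = np.concatenate([[0.0], np.cumsum(seg)])
        object.__setattr__(self, "nodes", self.metric.wrap(nodes))
        object.__setattr__(self, "scaled", scaled)
        object.__setattr__(self, "arcs", arcs)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def length(self) -> float:
        return float(self.arcs[-1])

    def node_s(self) -> np.ndarray:
        """Normalized arc-length position of each node."""
        return self.arcs / self.length

    def project_full(self, points):
        """Project raw CV points (..., d) onto the path.

        Returns (s, z, seg, t, perp) where ``perp`` is the scaled-space
        displacement from the closest path point to the point (the z
        direction), ``seg`` the segment index and ``t`` the within-segment
        parameter.  Ties go to the smaller s.
        """
        pts = np.atleast_2d(np.asarray(points, float))
        y = pts / self.metric.scales
        a = self.scaled[:-1]            # (S, d)
        ab = np.diff(self.scaled, axis=0)
        seg_len = np.linalg.norm(ab, axis=1)
        diff = y[:, None, :] - a[None, :, :]
        p = self.metric.periodic
        if p.any():
            period = 360.0 / self.metric.scales[p]
            d = diff[..., p]
            diff[..., p] = d - np.round(d / period) * period
        t = np.einsum("nsd,sd->ns", diff, ab) / seg_len**2
        t = np.clip(t, 0.0, 1.0)
        perp = diff - t[..., None] * ab[None, :, :]
        dist = np.linalg.norm(perp, axis=-1)
        seg = np.argmin(dist, axis=1)  # first minimum -> smaller s
        n = np.arange(len(y))
        t_best = t[n, seg]
        z = dist[n, seg]
        s = (self.arcs[seg] + t_best * seg_len[seg]) / self.length
        perp_best = perp[n, seg]
        if np.ndim(points) == 1:
            return s[0], z[0], int(seg[0]), t_best[0], perp_best[0]
        return s, z, seg, t_best, perp_best

    def project(self, points):
        """(s, z) of raw CV points; s in [0, 1], z >= 0 in scaled units."""
        s, z, *_ = self.project_full(points)
        return s, z

    def point_at(self, s):
        """Raw CV coordinates of the path point at progress s (clamped)."""
        s = np.clip(np.asarray(s, float), 0.0, 1.0)
        target = s * self.length
        scaled = np.empty(np.shape(target) + (self.metric.dim,))
        for k in range(self.metric.dim):
            scaled[..., k] = np.interp(target, self.arcs, self.scaled[:, k])
        return self.metric.wrap(scaled * self.metric.scales)

    def resample(self, n: int) -> "PathCV":
        s = np.linspace(0.0, 1.0, n)
        return PathCV(self.point_at(s), self.metric)

    def smooth_resample(self, n: int = 1001, smoothing: float = 0.0) -> "PathCV":
        """Dense resampling through an interpolating cubic B-spline.

        A polyline's vertices are wedge regions where the projection s is
        locally constant; restrained sampling centered on a vertex then
        piles probability onto a single s value.  Resampling the curve
        densely through a spline makes every kink angle negligible, which
        the umbrella stage relies on.
        """
        from scipy.interpolate import splev, splprep

        u = self.arcs / self.length
        # deduplicate parameter values for splprep
        tck, _ = splprep(self.scaled.T, u=u, s=smoothing, k=min(3, self.n_nodes - 1))
        dense = np.array(splev(np.linspace(0.0, 1.0, n), tck)).T
        return PathCV(self.metric.wrap(dense * self.metric.scales), self.metric)

    def to_frame(self, cv_names=None):
        import pandas as pd

        names = cv_names or [f"cv{k}" for k in range(self.metric.dim)]
        df = pd.DataFrame(self.nodes, columns=names)
        df.insert(0, "node", np.arange(self.n_nodes))
        df["s"] = self.node_s()
        return df


def path_rmsd(path_a: PathCV, path_b: PathCV, n: int = 101) -> float:
    """Mean scaled-space distance between arc-length-matched resamplings.

    Orientation-aligned: the reversed pairing is also evaluated and the
    smaller mean is returned, so a path and its reverse compare as equal.
    """
    s = np.linspace(0.0, 1.0, n)
    a = np.atleast_2d(path_a.point_at(s))
    b = np.atleast_2d(path_b.point_at(s))
    m = path_a.metric
    forward = float(np.mean(np.linalg.norm((m.diff(a, b)) / m.scales, axis=1)))
    rev = float(np.mean(np.linalg.norm((m.diff(a, b[::-1])) / m.scales, axis=1)))
    return min(forward, rev)


def frechet_distance(poly_a: np.ndarray, poly_b: np.ndarray) -> float:
    """Discrete Fréchet distance between two polylines (same space)."""
    a = np.asarray(poly_a, float)
    b = np.asarray(poly_b, float)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    n, m = d.shape
    ca = np.full((n, m), np.inf)
    ca[0, 0] = d[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        for j in range(1, m):
            ca[i, j] = max(min(ca[i - 1, j], ca[i - 1, j - 1], ca[i, j - 1]),
                           d[i, j])
    return float(ca[-1, -1])
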