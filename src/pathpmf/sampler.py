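"""Seeded Langevin dynamics on an energy surface with CV biases.

The integrator is a BAOAB splitting with unit masses and per-coordinate
friction, which stays accurate for the stiff harmonic biases the string and
umbrella stages apply.  All bias energies use the MD-engine force-constant
convention E = k·(x − x0)² (no factor ½); a config switch restores the ½
convention where needed.

Walkers run as a vectorized ensemble: positions have shape (M, dim), bias
centers broadcast per walker, and one seeded generator drives the whole
ensemble, so a fixed seed reproduces every trajectory bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .surfaces import EnergySurface, KT_300K

__all__ = [
    "BiasSpec",
    "CoordinateBias",
    "RampSchedule",
    "Trajectory",
    "bias_energy",
    "bias_force",
    "ramp_bias",
    "run_langevin",
    "stable_timestep",
]


@dataclass(frozen=True)
class BiasSpec:
    """A restraint on one scalar CV.

    ``harmonic``: k·(x − center)².  ``one_sided_linear_tail``: zero below the
    onset ``d0``, harmonic k·(x − d0)² between ``d0`` and ``d_lin``, and a
    linear continuation with matched value and slope above ``d_lin`` (C1 at
    both switch points) — the flat-bottom distance restraint used to keep a
    substrate in a reactive pose without ever pulling it inward.
    """

    center: float = 0.0
    k: float = 1.0
    kind: str = "harmonic"
    d0: float = 0.0
    d_lin: float = np.inf
    half: bool = False  # True: E = (k/2)(x-x0)^2 convention
    periodic: bool = False

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("force constant must be >= 0")
        if self.kind not in ("harmonic", "one_sided_linear_tail"):
            raise ValueError(f"unknown bias kind {self.kind!r}")
        if self.kind == "one_sided_linear_tail" and not self.d_lin > self.d0:
            raise ValueError("one_sided bias requires d_lin > d0")


def _keff(b: BiasSpec) -> float:
    return 0.5 * b.k if b.half else b.k


def bias_energy(b: BiasSpec, value):
    """Bias energy at a CV value (vectorized)."""
    v = np.asarray(value, float)
    k = _keff(b)
    if b.kind == "harmonic":
        d = v - b.center
        if b.periodic:
            d = (d + 180.0) % 360.0 - 180.0
        return k * d**2
    out = np.zeros_like(v)
    mid = (v > b.d0) & (v <= b.d_lin)
    out = np.where(mid, k * (v - b.d0) ** 2, out)
    e_lin = k * (b.d_lin - b.d0) ** 2
    slope = 2 * k * (b.d_lin - b.d0)
    out = np.where(v > b.d_lin, e_lin + slope * (v - b.d_lin), out)
    return out if np.ndim(value) else float(out)


def bias_force(b: BiasSpec, value):
    """dE/dvalue of the bias (vectorized)."""
    v = np.asarray(value, float)
    k = _keff(b)
    if b.kind == "harmonic":
        d = v - b.center
        if b.periodic:
            d = (d + 180.0) % 360.0 - 180.0
        return 2 * k * d
    g = np.zeros_like(v)
    mid = (v > b.d0) & (v <= b.d_lin)
    g = np.where(mid, 2 * k * (v - b.d0), g)
    g = np.where(v > b.d_lin, 2 * k * (b.d_lin - b.d0), g)
    return g if np.ndim(value) else float(g)


class CoordinateBias:
    """A :class:`BiasSpec` applied to one surface coordinate, with bias
    centers broadcastable over the walker ensemble."""

    def __init__(self, coord: int, spec: BiasSpec, centers=None):
        self.coord = int(coord)
        self.spec = spec
        self.centers = None if centers is None else np.asarray(centers, float)

    def energy(self, x, scale: float = 1.0):
        v = x[..., self.coord]
        if self.centers is None:
            e = bias_energy(self.spec, v)
        else:
            d = v - self.centers
            if self.spec.periodic:
                d = (d + 180.0) % 360.0 - 180.0
            e = _keff(self.spec) * d**2
        return scale * e

    def gradient(self, x, scale: float = 1.0):
        g = np.zeros_like(x)
        v = x[..., self.coord]
        if self.centers is None:
            g[..., self.coord] = bias_force(self.spec, v)
        else:
            d = v - self.centers
            if self.spec.periodic:
                d = (d + 180.0) % 360.0 - 180.0
            g[..., self.coord] = 2 * _keff(self.spec) * d
        return scale * g


@dataclass(frozen=True)
class RampSchedule:
    """Linear force-constant ramp: scale 0 → 1 over ``n_ramp`` steps, then
    constant — the gradual bias switch-on used when dragging structures to
    their string nodes."""

    n_ramp: int

    def scale(self, step: int) -> float:
        if self.n_ramp <= 0:
            return 1.0
        return min(1.0, step / self.n_ramp)


def ramp_bias(biases, n_ramp_steps: int) -> RampSchedule:
    """Schedule ramping the given biases from zero to full strength."""
    del biases  # the schedule is a pure time course shared by all biases
    return RampSchedule(n_ramp=int(n_ramp_steps))


@dataclass
class Trajectory:
    """Sampled positions (n_samples, M, dim) with bias energies."""

    positions: np.ndarray
    bias_energy: np.ndarray
    steps: np.ndarray
    dt: float

    def coord(self, k: int) -> np.ndarray:
        return self.positions[..., k]


def stable_timestep(stiffness, mass=1.0) -> float:
    """dt = 1/50 of the period of the stiffest harmonic mode.

    ``stiffness`` is the largest force constant among surface curvature and
    biases under the no-½ convention (E = k·x² has angular frequency
    sqrt(2k/m)); per-coordinate arrays broadcast.
    """
    ratio = np.max(np.asarray(stiffness, float) / np.asarray(mass, float))
    omega = np.sqrt(2.0 * max(ratio, 1e-12))
    return float(2 * np.pi / omega / 50.0)


def run_langevin(surface: EnergySurface, biases: Sequence, init,
                 n_steps: int, dt: float, temperature: float = KT_300K,
                 friction=5.0, seed: int = 0, stride: int = 1,
                 mass: float = 1.0, schedule: RampSchedule | None = None,
                 rng: np.random.Generator | None = None) -> Trajectory:
    """BAOAB Langevin sampling of exp(−(E + bias)/kT).

    ``init`` has shape (dim,) for one walker or (M, dim) for an ensemble;
    ``friction`` is a scalar or per-coordinate vector (1/time units).
    ``temperature`` is kT in reduced energy units.  Positions of periodic
    coordinates are wrapped to (−180, 180].  A fixed ``seed`` makes the
    output bit-reproducible; ``schedule`` scales all bias force constants.
    """
    x = np.atleast_2d(np.asarray(init, float)).copy()
    if x.shape[-1] != surface.dim:
        raise ValueError("init dimension does not match surface")
    kt = float(temperature)
    gamma = np.broadcast_to(np.asarray(friction, float), (surface.dim,))
    mass = np.broadcast_to(np.asarray(mass, float), (surface.dim,))
    if rng is None:
        rng = np.random.default_rng(seed)
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kt * (1.0 - c1**2) / mass)
    periodic = np.asarray(surface.periodic)

    def total_gradient(pos, scale):
        g = surface.gradient(pos).copy()
        for b in biases:
            g += b.gradient(pos, scale)
        return g

    def total_bias_energy(pos, scale):
        e = np.zeros(pos.shape[:-1])
        for b in biases:
            e = e + b.energy(pos, scale)
        return e

    def wrap(pos):
        if periodic.any():
            p = pos[..., periodic]
            pos[..., periodic] = (p + 180.0) % 360.0 - 180.0
        return pos

    v = np.zeros_like(x)
    out_pos, out_bias, out_steps = [], [], []
    scale = schedule.scale(0) if schedule else 1.0
    g = total_gradient(x, scale)
    for step in range(1, n_steps + 1):
        v -= 0.5 * dt * g / mass
        x = wrap(x + 0.5 * dt * v)
        v = c1 * v + c2 * rng.standard_normal(x.shape)
        x = wrap(x + 0.5 * dt * v)
        scale = schedule.scale(step) if schedule else 1.0
        g = total_gradient(x, scale)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(
                f"energy overflow at step {step}: non-finite forces "
                f"(max |x| = {np.abs(x).max():.3g})")
        v -= 0.5 * dt * g / mass
        if step % stride == 0:
            out_pos.append(x.copy())
            out_bias.append(total_bias_energy(x, scale))
            out_steps.append(step)
    return Trajectory(np.array(out_pos), np.array(out_bias),
                      np.array(out_steps), dt)
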