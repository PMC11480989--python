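"""Free-energy profiles on a 1-D grid: stationary points, barriers and
one-step vs two-step classification.

A profile is classified *two-step* when at least one interior minimum
(the tetrahedral-intermediate candidate) survives a depth threshold: the
drop from the lower of its two flanking maxima must be at least
``min_depth``.  By default the threshold is tied to the local statistical
uncertainty (with a floor), so a dip shallower than its own error bar is
not called a real intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["StationaryPoint", "PMFProfile", "analyze_profile"]

DEPTH_FLOOR = 0.1


@dataclass(frozen=True)
class StationaryPoint:
    kind: str  # "min" or "max"
    s: float
    a: float
    index: int


@dataclass(frozen=True)
class PMFProfile:
    """Free energy A(s) on a grid, min-normalized, with 95% CI halfwidths."""

    s: np.ndarray
    a: np.ndarray
    ci: np.ndarray
    stationary_points: tuple[StationaryPoint, ...] = ()
    barriers: dict = field(default_factory=dict, compare=False)
    classification: str = "one_step"

    def __post_init__(self):
        s = np.asarray(self.s, float)
        a = np.asarray(self.a, float)
        ci = np.asarray(self.ci, float)
        if s.ndim != 1 or s.shape != a.shape or s.shape != ci.shape:
            raise ValueError("s, a, ci must be 1-D arrays of equal length")
        if np.any(np.diff(s) <= 0):
            raise ValueError("s grid must be strictly increasing")
        if np.any(ci < 0):
            raise ValueError("CI halfwidths must be >= 0")
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "ci", ci)

    @property
    def minima(self) -> list[StationaryPoint]:
        return [p for p in self.stationary_points if p.kind == "min"]

    @property
    def maxima(self) -> list[StationaryPoint]:
        return [p for p in self.stationary_points if p.kind == "max"]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"s": self.s, "A": self.a, "ci95": self.ci})

    def summary(self) -> dict:
        return {
            "classification": self.classification,
            "stationary_points": [
                {"kind": p.kind, "s": p.s, "A": p.a} for p in self.stationary_points
            ],
            "barriers": self.barriers,
        }


def _raw_extrema(a: np.ndarray) -> list[tuple[str, int]]:
    """Interior extrema by sign changes of the discrete slope, plus the two
    ends typed by their adjacent slope."""
    d = np.diff(a)
    sig = np.sign(d)
    # collapse zero slopes onto the following nonzero sign
    for i in range(len(sig) - 2, -1, -1):
        if sig[i] == 0:
            sig[i] = sig[i + 1]
    pts: list[tuple[str, int]] = []
    nz = sig[sig != 0]
    first = nz[0] if len(nz) else 0
    pts.append(("min" if first >= 0 else "max", 0))
    for i in range(1, len(a) - 1):
        left, right = sig[i - 1], sig[i]
        if left > 0 and right < 0:
            pts.append(("max", i))
        elif left < 0 and right > 0:
            pts.append(("min", i))
    last = nz[-1] if len(nz) else 0
    pts.append(("max" if last >= 0 else "min", len(a) - 1))
    return pts


def _prune(pts: list[tuple[str, int]], a: np.ndarray, depth: np.ndarray):
    """Remove adjacent min/max pairs whose prominence is below the local
    depth threshold, smallest first, keeping the profile ends."""
    pts = list(pts)
    while True:
        best, best_amp = None, np.inf
        for j in range(len(pts) - 1):
            (k1, i1), (k2, i2) = pts[j], pts[j + 1]
            if k1 == k2:
                amp = 0.0  # duplicate kinds: drop the weaker one
                best, best_amp = (j, j + 1), amp
                break
            amp = abs(a[i2] - a[i1])
            thr = max(depth[i1], depth[i2])
            interior = 0 < i1 and i2 < len(a) - 1
            if interior and amp < thr and amp < best_amp:
                best, best_amp = (j, j + 1), amp
        if best is None:
            return pts
        j1, j2 = best
        (k1, i1), (k2, i2) = pts[j1], pts[j2]
        if k1 == k2:
            # keep the more extreme of the duplicates
            if k1 == "min":
                drop = j1 if a[i1] > a[i2] else j2
            else:
                drop = j1 if a[i1] < a[i2] else j2
            del pts[drop]
        else:
            del pts[j2], pts[j1]


def analyze_profile(s, a, ci=None, min_depth: float | None = None,
                    depth_floor: float = DEPTH_FLOOR) -> PMFProfile:
    """Build a :class:`PMFProfile` from grid values.

    ``min_depth`` overrides the depth threshold everywhere; otherwise the
    threshold at a point is max(local CI, ``depth_floor``).  A(s) is shifted
    so its minimum is zero.
    """
    s = np.asarray(s, float)
    a = np.asarray(a, float)
    ci = np.zeros_like(a) if ci is None else np.asarray(ci, float)
    a = a - a.min()
    if min_depth is not None:
        depth = np.full_like(a, float(min_depth))
    else:
        depth = np.maximum(ci, depth_floor)
    pts = _prune(_raw_extrema(a), a, depth)
    stationary = tuple(
        StationaryPoint(kind, float(s[i]), float(a[i]), int(i)) for kind, i in pts
    )
    minima = [p for p in stationary if p.kind == "min"]
    maxima = [p for p in stationary if p.kind == "max"]
    interior_minima = [
        p for p in minima
        if any(m.s < p.s for m in maxima) and any(m.s > p.s for m in maxima)
    ]
    classification = "two_step" if interior_minima else "one_step"

    barriers: dict = {}
    # forward barriers: each maximum relative to the preceding minimum
    prev_min = None
    n_barrier = 0
    for p in stationary:
        if p.kind == "min":
            prev_min = p
        elif p.kind == "max" and prev_min is not None:
            n_barrier += 1
            barriers[f"ts{n_barrier}"] = {
                "s": p.s, "A": p.a, "height": p.a - prev_min.a,
            }
    if minima:
        barriers["reaction_free_energy"] = minima[-1].a - minima[0].a
    if interior_minima:
        ti = min(interior_minima, key=lambda p: p.a)
        lower_flank = min(
            max((m.a for m in maxima if m.s < ti.s), default=np.inf),
            max((m.a for m in maxima if m.s > ti.s), default=np.inf),
        )
        barriers["ti"] = {"s": ti.s, "A": ti.a, "depth": lower_flank - ti.a}
    return PMFProfile(s, a, ci, stationary, barriers, classification)


def reclassify(profile: PMFProfile, min_depth: float | None = None,
               depth_floor: float = DEPTH_FLOOR) -> PMFProfile:
    """Re-run stationary-point analysis on an existing profile."""
    return analyze_profile(profile.s, profile.a, profile.ci,
                           min_depth=min_depth, depth_floor=depth_floor)
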