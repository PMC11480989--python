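"""End-to-end free-energy pipeline: string optimization → path-CV umbrella
sampling → umbrella-integration PMF with CI convergence → optional
spline correction to a high-level surface — driven by one validated
configuration, with checkpointed, bit-reproducible stage outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path as FsPath

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import __version__
from .correction import build_correction, check_path_similarity, spline_correct
from .path_cv import CVMetric, PathCV
from .profiles import PMFProfile, analyze_profile
from .string_method import StringConfig, optimize_string
from .surfaces import (KT_300K, LowHighSurfacePair, TwoStepSurfaceParams,
                       exact_marginal_pmf, muller_brown, two_step_pair,
                       two_step_surface)
from .umbrella import UmbrellaConfig, converge_pmf, ui_confidence, ui_pmf

__all__ = ["RunConfig", "RunReport", "run_pipeline", "compare_runs"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _take(d: dict, cls, section: str):
    """Build a dataclass from a config dict, rejecting unknown keys."""
    known = {f.name for f in cls.__dataclass_fields__.values()} \
        if hasattr(cls, "__dataclass_fields__") else set()
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown keys in '{section}': {sorted(unknown)}")
    try:
        return cls(**d)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{section}' config: {exc}") from exc


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration.

    ``surface`` selects the energy model ("two_step" or "muller_brown");
    ``include_theta`` switches the angle CV in or out of the path space;
    ``windows_per_node`` densifies the umbrella centers between nodes.
    """

    surface: str = "two_step"
    surface_params: TwoStepSurfaceParams = field(default_factory=TwoStepSurfaceParams)
    include_theta: bool = True
    cv_scales: tuple[float, ...] | None = None
    string: StringConfig = field(default_factory=StringConfig)
    umbrella: UmbrellaConfig = field(default_factory=UmbrellaConfig)
    windows_per_node: int = 2
    grid_points: int = 201
    ci_threshold: float = 1.0
    max_rounds: int = 5
    n_boot: int = 200
    correction: bool = False
    correction_points: int = 13
    correction_relax: bool = True
    correction_convention: str = "add_high_minus_low"
    ti_deepening: float = 1.5
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sub = {}
        if "surface_params" in d:
            sub["surface_params"] = _take(d.pop("surface_params"),
                                          TwoStepSurfaceParams, "surface_params")
        if "string" in d:
            sub["string"] = _take(d.pop("string"), StringConfig, "string")
        if "umbrella" in d:
            sub["umbrella"] = _take(d.pop("umbrella"), UmbrellaConfig, "umbrella")
        if "cv_scales" in d and d["cv_scales"] is not None:
            d["cv_scales"] = tuple(d["cv_scales"])
        cfg = _take({**d, **sub}, cls, "run")
        if cfg.surface not in ("two_step", "muller_brown"):
            raise ConfigError(f"unknown surface {cfg.surface!r}")
        try:
            cfg.surface_params.validate()
        except ValueError as exc:
            raise ConfigError(f"invalid 'surface_params': {exc}") from exc
        if cfg.windows_per_node < 1 or cfg.grid_points < 10:
            raise ConfigError("windows_per_node >= 1 and grid_points >= 10 required")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Everything the pipeline measured, with provenance."""

    config_hash: str
    seed: int
    string_nodes: pd.DataFrame
    profile: PMFProfile
    corrected_profile: PMFProfile | None
    barrier_table: dict
    theta_of_s: pd.DataFrame | None
    classification: str
    classification_corrected: str | None
    rounds: int
    version: str = __version__

    def summary(self) -> dict:
        out = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "rounds": self.rounds,
            "classification": self.classification,
            "classification_corrected": self.classification_corrected,
            "barriers": self.barrier_table,
            "profile": self.profile.summary(),
        }
        if self.corrected_profile is not None:
            out["corrected"] = self.corrected_profile.summary()
        return out


def _interior_barriers(profile: PMFProfile, edge: float = 0.03) -> dict:
    """Barrier table from interior stationary points (UI end wiggles within
    ``edge`` of the boundary are not barriers)."""
    maxima = [p for p in profile.maxima if edge < p.s < 1 - edge]
    minima = profile.minima
    table: dict = {}
    maxima = sorted(maxima, key=lambda p: p.s)
    first_min = minima[0].a if minima else 0.0
    for i, p in enumerate(maxima, start=1):
        left = [m for m in minima if m.s < p.s]
        base = left[-1].a if left else first_min
        table[f"ts{i}"] = {"s": p.s, "A": p.a, "height": p.a - base,
                           "ci": float(profile.ci[p.index])}
    interior_minima = [m for m in minima if any(p.s < m.s for p in maxima)
                       and any(p.s > m.s for p in maxima)]
    if interior_minima:
        ti = min(interior_minima, key=lambda m: m.a)
        flank = min(max((p.a for p in maxima if p.s < ti.s), default=np.inf),
                    max((p.a for p in maxima if p.s > ti.s), default=np.inf))
        table["ti"] = {"s": ti.s, "A": ti.a, "depth": flank - ti.a,
                       "ci": float(profile.ci[ti.index])}
    if minima:
        table["reaction_free_energy"] = minima[-1].a - minima[0].a
    return table


def _fold_plane_angle(theta: np.ndarray) -> np.ndarray:
    """Surrogate ring-plane angle from the dihedral: θ = 0° is T-stacked
    (plane angle 90°), |θ| = 90° parallel (plane angle 0°)."""
    t = np.abs((np.asarray(theta) + 180.0) % 360.0 - 180.0)
    t = np.where(t > 90.0, 180.0 - t, t)
    return 90.0 - t


def run_pipeline(config: RunConfig, out_dir=None,
                 pair: LowHighSurfacePair | None = None) -> RunReport:
    """Execute the full analysis under one config and seed set.

    When ``out_dir`` is given every stage writes its CSV checkpoint there;
    re-running with the identical config and seed reproduces the files
    bit for bit (files from a previous identical run are overwritten, not
    trusted).  ``pair`` supplies the low/high surface pair when the
    correction stage is enabled (defaults to the built-in TI-deepening
    pair on the configured low-level surface).
    """
    cfg = config
    out = FsPath(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    tag = cfg.config_hash()

    # --- surface and endpoint basins -------------------------------------
    if cfg.surface == "muller_brown":
        surface = muller_brown()
        guess_a, guess_b = np.array([-0.55, 1.44]), np.array([0.62, 0.03])
        theta_idx = None
    else:
        cfg.surface_params.validate()
        if cfg.correction and pair is None:
            pair = two_step_pair(cfg.surface_params, ti_deepening=cfg.ti_deepening)
        surface = pair.low if (cfg.correction and pair is not None) \
            else two_step_surface(cfg.surface_params)
        p = cfg.surface_params
        guess_a = np.array([p.r_mc, p.theta_eq(p.r_mc)])
        guess_b = np.array([p.r_ae, p.theta_eq(p.r_ae)])
        theta_idx = 1

    def _basin(g):
        return minimize(lambda x: float(surface.energy(x)), g,
                        jac=lambda x: surface.gradient(x), method="BFGS",
                        options={"gtol": 1e-10}).x

    end_a, end_b = _basin(guess_a), _basin(guess_b)

    # --- CV space ---------------------------------------------------------
    if cfg.surface == "two_step" and not cfg.include_theta:
        cv_indices = (0,)
    else:
        cv_indices = tuple(range(surface.dim))
    default_scales = [30.0 if surface.periodic[c] else 1.0 for c in cv_indices]
    scales = np.asarray(cfg.cv_scales if cfg.cv_scales is not None
                        else default_scales, float)
    metric = CVMetric(scales, np.array([surface.periodic[c] for c in cv_indices]))

    # --- stage 1: string --------------------------------------------------
    state = optimize_string(surface, end_a[list(cv_indices)],
                            end_b[list(cv_indices)], metric=metric,
                            cfg=cfg.string, seed=cfg.seed,
                            cv_indices=cv_indices,
                            full_end_a=end_a, full_end_b=end_b)
    path = state.path()
    names = [surface.names[c] for c in cv_indices]
    string_df = path.to_frame(names)
    if out is not None:
        string_df.to_csv(out / f"string_{tag}.csv", index=False)

    # --- stage 2+3: umbrella sampling with CI convergence ------------------
    n_centers = cfg.windows_per_node * (state.n_nodes - 1) + 1
    grid = np.linspace(0.0, 1.0, cfg.grid_points)
    template = np.where(np.arange(n_centers)[:, None] < n_centers // 2,
                        end_a, end_b)
    ucfg = replace(cfg.umbrella)
    centers = np.linspace(0.0, 1.0, n_centers)

    from .umbrella import run_umbrella  # local import keeps module surface flat

    rounds = 0
    profile = None
    windows = None
    for rounds in range(1, cfg.max_rounds + 1):
        windows = run_umbrella(path, surface, ucfg, seed=cfg.seed + 100 + rounds,
                               cv_indices=cv_indices, init_template=template,
                               centers=centers)
        prof = ui_pmf(windows, grid, ucfg.temperature, ucfg.half_convention)
        ci = ui_confidence(windows, grid, n_boot=cfg.n_boot,
                           seed=cfg.seed + 7919,
                           temperature=ucfg.temperature,
                           half_convention=ucfg.half_convention)
        profile = analyze_profile(grid, prof.a, ci)
        tops = [p for p in profile.maxima if 0.03 < p.s < 0.97]
        if tops and ci[max(tops, key=lambda p: p.a).index] < cfg.ci_threshold:
            break
        ucfg = replace(ucfg, n_steps=ucfg.n_steps * 2)
    if out is not None:
        win_df = pd.DataFrame({
            "window": np.arange(len(windows)),
            "center": [w.center for w in windows],
            "k_s": [w.k for w in windows],
            "mean_s": [w.mean for w in windows],
            "var_s": [w.var for w in windows],
            "n": [w.n for w in windows],
        })
        win_df.to_csv(out / f"windows_{tag}.csv", index=False)
        profile.to_frame().to_csv(out / f"pmf_{tag}.csv", index=False)

    # --- angle tracking ----------------------------------------------------
    theta_df = None
    if theta_idx is not None:
        theta = np.array([w.mean_cv[theta_idx] for w in windows])
        theta_df = pd.DataFrame({
            "s": [w.center for w in windows],
            "theta": theta,
            "plane_angle": _fold_plane_angle(theta),
        })
        if out is not None:
            theta_df.to_csv(out / f"theta_{tag}.csv", index=False)

    # --- stage 4: spline correction ----------------------------------------
    corrected = None
    if cfg.correction and pair is not None:
        table = build_correction(pair, path, cfg.correction_points,
                                 local_relax=cfg.correction_relax)
        corrected = spline_correct(profile, table,
                                   convention=cfg.correction_convention)
        if out is not None:
            table.to_frame().to_csv(out / f"correction_{tag}.csv", index=False)
            corrected.to_frame().to_csv(out / f"pmf_corrected_{tag}.csv",
                                        index=False)

    final = corrected if corrected is not None else profile

    def _classify(p: PMFProfile) -> str:
        # classification from edge-trimmed stationary points, consistent
        # with the barrier table (UI end wiggles are not reaction steps)
        return "two_step" if "ti" in _interior_barriers(p) else "one_step"

    report = RunReport(
        config_hash=tag,
        seed=cfg.seed,
        string_nodes=string_df,
        profile=profile,
        corrected_profile=corrected,
        barrier_table=_interior_barriers(final),
        theta_of_s=theta_df,
        classification=_classify(profile),
        classification_corrected=None if corrected is None
        else _classify(corrected),
        rounds=rounds,
    )
    if out is not None:
        with open(out / f"report_{tag}.json", "w") as fh:
            json.dump(report.summary(), fh, indent=2, default=float)
    return report


def compare_runs(report_a: RunReport, report_b: RunReport) -> pd.DataFrame:
    """Per-barrier differences (B − A) with root-sum-square combined CI."""
    rows = []
    keys = sorted(set(report_a.barrier_table) & set(report_b.barrier_table))
    for key in keys:
        ba, bb = report_a.barrier_table[key], report_b.barrier_table[key]
        if not isinstance(ba, dict):
            rows.append({"quantity": key, "A": ba, "B": bb, "delta": bb - ba,
                         "ci": np.nan})
            continue
        metric = "height" if "height" in ba else "depth"
        ci = float(np.hypot(ba.get("ci", 0.0), bb.get("ci", 0.0)))
        rows.append({"quantity": f"{key}_{metric}", "A": ba[metric],
                     "B": bb[metric], "delta": bb[metric] - ba[metric],
                     "ci": ci})
    return pd.DataFrame(rows)
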