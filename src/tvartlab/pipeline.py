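"""Experiment orchestration: presets, config files, reproducible runs.

An :class:`ExperimentConfig` resolves a named preset plus overrides to a
fully concrete parameter set.  :func:`run_experiment` executes the
standard chain — simulate, enumerate fixed points, fit TVART, cluster,
score (and optionally sweep prediction delays) — writing plain CSV/JSON
artifacts plus a MANIFEST.json into a run directory.  Per-stage seeds
are derived deterministically from the master seed so identical configs
reproduce identical outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .attractors import (
    find_fixed_points,
    label_by_nearest_attractor,
    mean_transition_time,
    save_attractor_set,
    window_attractor_indices,
)
from .errors import delay_sweep, fit_error_curve
from .model import (
    ModelParameters,
    four_attractor_parameters,
    highdim_parameters,
    two_attractor_parameters,
)
from .regimes import (
    chance_level,
    cluster_temporal_modes_gmm,
    match_clusters_to_attractors,
)
from .simulate import (
    SimulationSettings,
    simulate_heun,
    surrogate_connectivity,
    write_trajectory,
)
from .tvart import TVARTConfig, build_windows, fit_tvart

__all__ = ["ExperimentConfig", "load_config", "validate_config", "run_experiment", "stage_seed"]

PRESETS = ("two_attractor", "four_attractor", "surrogate_highdim", "custom")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the master
    seed and the stage name."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class ExperimentConfig:
    preset: str = "two_attractor"
    model_overrides: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    tvart: dict = field(default_factory=dict)
    fit: bool = True
    cluster: bool = True
    n_components: int | None = None
    run_delay_sweep: bool = False
    delay_grid: list = field(default_factory=lambda: [1, 6, 11, 16, 21, 26, 31])
    surrogate_n: int = 12
    surrogate_density: float = 0.3
    output_dir: str = "runs/experiment"
    master_seed: int = 0

    def resolve_params(self) -> ModelParameters:
        ov = dict(self.model_overrides)
        if self.preset == "two_attractor":
            p = two_attractor_parameters()
        elif self.preset == "four_attractor":
            p = four_attractor_parameters()
        elif self.preset == "surrogate_highdim":
            C = surrogate_connectivity(
                self.surrogate_n, self.surrogate_density, stage_seed(self.master_seed, "connectivity")
            )
            p = highdim_parameters(C)
        elif self.preset == "custom":
            if "C" in ov:
                ov["C"] = np.asarray(ov["C"], dtype=float)
            return ModelParameters(**ov)
        else:
            raise ValueError(f"unknown preset {self.preset!r}")
        if "C" in ov:
            ov["C"] = np.asarray(ov["C"], dtype=float)
        return p.with_(**ov) if ov else p

    def resolve_settings(self) -> SimulationSettings:
        base = dict(
            dt_int=1e-4,
            duration=120.0,
            burn_in=0.0,
            downsample_period=2e-3,
            seed=stage_seed(self.master_seed, "simulate"),
        )
        if self.preset == "surrogate_highdim":
            base.update(burn_in=10.0, downsample_period=5e-3)
        base.update(self.simulation)
        return SimulationSettings(**base)

    def resolve_tvart(self) -> TVARTConfig:
        base = dict(window_M=100, rank_R=2, delay_steps=31, eta=0.5, beta=0.5,
                    regularization="spline", seed=stage_seed(self.master_seed, "tvart"))
        if self.preset == "surrogate_highdim":
            base.update(eta=10.0, beta=0.1)
        base.update(self.tvart)
        return TVARTConfig(**base)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


_FIELDS = {f.name: f for f in dataclasses.fields(ExperimentConfig)}


def validate_config(raw: dict) -> list[str]:
    """Strict schema check; returns a list of violations (empty = valid)."""
    problems = []
    for key in raw:
        if key not in _FIELDS:
            problems.append(f"unknown key: {key}")
    preset = raw.get("preset", "two_attractor")
    if preset not in PRESETS:
        problems.append(f"preset must be one of {PRESETS}, got {preset!r}")
    for key in ("model_overrides", "simulation", "tvart"):
        if key in raw and not isinstance(raw[key], dict):
            problems.append(f"{key} must be a mapping")
    tv = raw.get("tvart", {})
    if isinstance(tv, dict):
        if "window_M" in tv and (not isinstance(tv["window_M"], int) or tv["window_M"] < 2):
            problems.append("window_M must be an integer >= 2")
        if "delay_steps" in tv and (not isinstance(tv["delay_steps"], int) or tv["delay_steps"] < 1):
            problems.append("delay_steps must be an integer >= 1")
        if "eta" in tv and not (isinstance(tv["eta"], (int, float)) and tv["eta"] > 0):
            problems.append("eta must be > 0")
        if "beta" in tv and not (isinstance(tv["beta"], (int, float)) and tv["beta"] >= 0):
            problems.append("beta must be >= 0")
    if "master_seed" in raw and not isinstance(raw["master_seed"], int):
        problems.append("master_seed must be an integer")
    return problems


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment config; unknown keys are
    rejected and all defaults materialized.  Relative output paths are
    resolved against the config file's directory."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    problems = validate_config(raw)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    cfg = ExperimentConfig(**raw)
    out = Path(cfg.output_dir)
    if not out.is_absolute():
        cfg.output_dir = str((path.parent / out).resolve())
    return cfg


def save_config(path, cfg: ExperimentConfig) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute simulate -> fixed points -> fit -> cluster -> score.

    Returns the results bundle as a dict and writes artifacts (CSV/JSON)
    plus MANIFEST.json into ``config.output_dir``.  Re-running the same
    config reproduces identical outputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "artifacts": []}

    def _stage(name):
        manifest["stages"][name] = {"seed": stage_seed(config.master_seed, name)}

    def _emit(name, writer):
        writer(outdir / name)
        manifest["artifacts"].append(name)

    try:
        params = config.resolve_params()
        settings = config.resolve_settings()
        _stage("simulate")
        traj = simulate_heun(params, settings)
        _emit("trajectory.csv", lambda p: write_trajectory(p, traj, settings))

        _stage("fixed_points")
        aset = find_fixed_points(
            params, n_seeds=max(40, 10 * params.n_populations),
            seed=stage_seed(config.master_seed, "fixed_points"),
        )
        _emit("attractors.json", lambda p: save_attractor_set(p, aset))

        labels = label_by_nearest_attractor(traj, aset)
        interval, n_trans = mean_transition_time(labels)
        results: dict = {
            "n_stable_fixed_points": aset.n_stable,
            "mean_transition_interval_samples": interval,
            "n_transitions": n_trans,
        }

        tv_cfg = config.resolve_tvart()
        if config.fit:
            _stage("tvart")
            data = build_windows(traj, tv_cfg.window_M, tv_cfg.delay_steps)
            fit = fit_tvart(data, tv_cfg)
            results.update({"tvart_mse": fit.mse, "tvart_r2": fit.r2, "tvart_converged": fit.converged})
            _emit("temporal_modes.csv", lambda p: np.savetxt(
                p, fit.U3, delimiter=",",
                header=",".join(f"mode_{r}" for r in range(fit.U3.shape[1])), comments=""))

        if config.fit and config.cluster:
            _stage("cluster")
            k = config.n_components or aset.n_stable
            truth = window_attractor_indices(traj, aset, tv_cfg.window_M, n_windows=data.T)
            ca = cluster_temporal_modes_gmm(fit.U3, k, seed=stage_seed(config.master_seed, "cluster"))
            match = match_clusters_to_attractors(ca.labels, truth)
            chance = chance_level(truth, k, seed=stage_seed(config.master_seed, "chance"))
            results.update({
                "n_components": k,
                "accuracy_percent": match["accuracy"],
                "mean_posterior": ca.mean_posterior,
                "chance_median_percent": chance["median"],
            })
            _emit("cluster_assignment.csv", lambda p: np.savetxt(
                p, np.column_stack([truth, ca.labels, ca.posteriors]),
                delimiter=",", header="attractor_index,cluster_label,max_posterior", comments=""))

        if config.run_delay_sweep:
            _stage("delay_sweep")
            sweep = delay_sweep(traj, config.delay_grid, tv_cfg)
            law = fit_error_curve(sweep.delays_seconds, sweep.mse)
            results.update({
                "delay_sweep_r2": law["r2"],
                "delay_sweep_lambda": law["lambda"],
                "delay_sweep_model": law["model_choice"],
            })
            _emit("delay_sweep.csv", lambda p: np.savetxt(
                p, np.column_stack([sweep.delays_samples, sweep.delays_seconds, sweep.mse]),
                delimiter=",", header="delay_samples,delay_seconds,mse", comments=""))
    except Exception as exc:
        manifest["failed_stage"] = list(manifest["stages"])[-1] if manifest["stages"] else None
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(
            f"experiment failed in stage {manifest['failed_stage']!r}: {exc}"
        ) from exc

    manifest["results"] = results
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:16]
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))
    (outdir / "results.json").write_text(json.dumps(results, indent=1))
    return results
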