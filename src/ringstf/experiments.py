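"""Reproducible experiment driver tying the model layers together.

An :class:`ExperimentConfig` fully determines an experiment: which
model runs (full network, reduced system, or bare particle), the
schedule and target-generating law, sizes and the master seed.  The
master seed is expanded into named substreams (burn-in/noise, target
sampler, schedule durations) so that, e.g., growing the ensemble does
not perturb earlier draws.  ``run_experiment`` writes trial records as
CSV plus a JSON manifest of the fully resolved configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import analysis
from .neural_field import FieldParams, results_to_frame, run_trials, delay_ensemble
from .protocols import TargetSampler, TrialSchedule, build_schedule
from .reduction import ReducedParams, simulate_reduced
from .ring_dynamics import ParticleConfig, PotentialField, simulate_particle_ensemble

__all__ = ["ExperimentConfig", "run_experiment", "make_fixtures", "PRESETS"]

_SAMPLER_KEYS = {"mode", "mixture_weight", "concentration", "mu"}
_SCHEDULE_KEYS = {"n_trials", "delay_spec", "iti_spec"}


@dataclass
class ExperimentConfig:
    """Validated description of one experiment."""

    model: str = "network"  # network | reduced | particle
    fast: bool = True
    n_trials: int = 100
    delay_spec: object = 2000.0
    iti_spec: object = 1500.0
    sampler: dict = field(default_factory=lambda: {"mode": "uniform_pmf_20"})
    params: dict = field(default_factory=dict)  # overrides for FieldParams etc.
    ensemble: int = 0  # >0: delay-ensemble mode (variance time course)
    delay_ms: float = 3000.0  # ensemble delay length
    stf: bool = True
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self):
        if self.model not in ("network", "reduced", "particle"):
            raise ValueError(f"unknown model: {self.model!r}")
        unknown = set(self.sampler) - _SAMPLER_KEYS
        if unknown:
            raise ValueError(f"unknown sampler keys: {sorted(unknown)}")
        valid_params = {f.name for f in dataclasses.fields(FieldParams)} | {"sigma_theta"}
        unknown = set(self.params) - valid_params
        if unknown:
            raise ValueError(f"unknown params keys: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


PRESETS: dict[str, dict] = {
    # bias versus relative angle; network and reduced variants
    "fig5A": {
        "model": "network",
        "n_trials": 400,
        "delay_spec": 2000.0,
        "iti_spec": 1500.0,
        "sampler": {"mode": "uniform_pmf_20"},
    },
    "fig5B": {
        "model": "reduced",
        "n_trials": 4000,
        "delay_spec": 2000.0,
        "iti_spec": "ladder",
        "sampler": {"mode": "uniform_pmf_20"},
    },
    "fig5C": {
        "model": "reduced",
        "n_trials": 4000,
        "delay_spec": "ladder",
        "iti_spec": 1500.0,
        "sampler": {"mode": "uniform_pmf_20"},
    },
    # response-spread protocols
    "fig6A": {
        "model": "network",
        "n_trials": 800,
        "delay_spec": 2000.0,
        "iti_spec": 1500.0,
        "sampler": {"mode": "uniform_density"},
    },
    "fig6B": {
        "model": "network",
        "n_trials": 800,
        "delay_spec": 2000.0,
        "iti_spec": 1500.0,
        "sampler": {"mode": "correlated", "mu": 0.0},
    },
    "fig6C": {
        "model": "network",
        "n_trials": 800,
        "delay_spec": 2000.0,
        "iti_spec": 1500.0,
        "sampler": {"mode": "correlated", "mu": 90.0},
    },
    # delay-period diffusion ensembles
    "fig7stf": {"model": "network", "ensemble": 500, "delay_ms": 5000.0, "stf": True},
    "fig7static": {"model": "network", "ensemble": 500, "delay_ms": 3000.0, "stf": False},
}


def _field_params(cfg: ExperimentConfig) -> FieldParams:
    overrides = {k: v for k, v in cfg.params.items() if k != "sigma_theta"}
    return FieldParams.fast(**overrides) if cfg.fast else FieldParams(**overrides)


def _substreams(seed: int) -> dict:
    names = ("dynamics", "sampler", "durations")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: s for n, s in zip(names, children)}


def _build(cfg: ExperimentConfig) -> TrialSchedule:
    streams = _substreams(cfg.seed)
    sampler = TargetSampler(**cfg.sampler)
    # build_schedule spawns its own substreams from the sampler stream
    return build_schedule(
        cfg.n_trials,
        delay_spec=cfg.delay_spec,
        iti_spec=cfg.iti_spec,
        sampler=sampler,
        seed=streams["sampler"],
    )


def run_experiment(cfg: ExperimentConfig, out_dir=None) -> dict:
    """Execute the configured experiment and write results + manifest.

    Returns a summary dict (also written to the manifest) whose content
    depends on the model: response-spread statistics for trial runs,
    two-phase slopes for ensemble runs.
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    streams = _substreams(cfg.seed)
    dyn_seed = streams["dynamics"].generate_state(1)[0] % (2**31)
    summary: dict = {"model": cfg.model}

    if cfg.ensemble > 0:
        params = _field_params(cfg)
        times, pos = delay_ensemble(
            params, cfg.ensemble, cfg.delay_ms, seed=dyn_seed, stf=cfg.stf
        )
        course = analysis.variance_course(times, pos)
        course.to_frame().to_csv(out / "variance_course.csv", index=False)
        summary.update(
            early_slope=course.early_slope,
            late_slope=course.late_slope,
            slope_ratio=course.slope_ratio,
            ensemble=cfg.ensemble,
        )
    elif cfg.model == "particle":
        sigma_theta = float(cfg.params.get("sigma_theta", 1.0))
        from ._angles import angle_grid

        grid = angle_grid(2000)
        U = PotentialField(grid, np.zeros_like(grid))
        pc = ParticleConfig(sigma_theta=sigma_theta, dt=0.1, seed=dyn_seed)
        traj = simulate_particle_ensemble(
            U, pc, np.zeros(max(cfg.ensemble, 200)), cfg.delay_ms, record_every=100
        )
        course = analysis.variance_course(traj.times, traj.displacement)
        course.to_frame().to_csv(out / "variance_course.csv", index=False)
        summary.update(variance_slope=course.early_slope, sigma_theta=sigma_theta)
    else:
        schedule = _build(cfg)
        schedule.to_csv(out / "schedule.csv")
        params = _field_params(cfg)
        if cfg.model == "network":
            results = run_trials(schedule, params, seed=dyn_seed)
            frame = results_to_frame(results)
        else:
            rp = ReducedParams.from_field(params)
            results, states = simulate_reduced(schedule, rp, seed=dyn_seed, record=True)
            frame = results_to_frame(results)
            frame["theta_q_deg"] = [s.theta_q for s in states]
            frame["A_prev"] = [s.A_prev for s in states]
            frame["A_curr"] = [s.A_curr for s in states]
        frame.to_csv(out / "trials.csv", index=False)
        curve = analysis.bias_by_relative_angle(frame)
        curve.to_frame().to_csv(out / "bias_curve.csv", index=False)
        if frame["valid"].sum() >= 2:
            summary.update(analysis.response_sd(frame))
    import hashlib

    hashes = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.glob("*.csv"))
    }
    manifest = {"config": cfg.to_dict(), "summary": summary, "content_sha256": hashes}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return summary


def make_fixtures(kind: str, seed: int = 0, out_dir="fixtures") -> Path:
    """Write the tiny deterministic datasets used by the test-suite."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "schedules":
        sched = build_schedule(5, seed=seed)
        path = out / "schedule_5trials.csv"
        sched.to_csv(path)
    elif kind == "histories":
        from .protocols import sample_targets

        hist = sample_targets(TargetSampler("uniform_pmf_20"), 8, seed=seed)
        path = out / "history_8targets.csv"
        with open(path, "w") as fh:
            fh.write("theta_deg\n")
            fh.writelines(f"{a}\n" for a in hist.angles)
    elif kind == "trajectories":
        from ._angles import angle_grid

        grid = angle_grid(360)
        U = PotentialField(grid, np.zeros_like(grid))
        pc = ParticleConfig(sigma_theta=1.0, dt=1.0, seed=seed)
        traj = simulate_particle_ensemble(U, pc, np.zeros(20), 1000.0, record_every=10)
        import pandas as pd

        path = out / "brownian_20paths.csv"
        pd.DataFrame(
            traj.displacement, index=pd.Index(traj.times, name="time_ms")
        ).to_csv(path)
    else:
        raise ValueError(f"unknown fixture kind: {kind!r}")
    return path
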