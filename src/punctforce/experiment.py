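"""Reproducible end-to-end experiment runs.

One run executes the three-step evaluation pipeline on a phantom pair:

1. plan skin-to-target trajectories on the gold-standard model,
2. render reference (gold) and test (partial/perturbed) force signals by
   simulated needle steering along every accepted path,
3. compare the signals and the border crossings, and summarize the cohort.

A run is fully described by its :class:`RunConfig`; re-executing a saved
config reproduces every output byte-exactly. Every output file carries the
config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .evaluation import PathErrorReport, evaluate_path, reports_to_csv, summarize, summary_to_json
from .force_engine import EngineConfig, ForceSignal, render_insertion
from .path_planner import PlannedPath, PlannerConfig, paths_to_csv, plan_all
from .phantom import (
    PhantomModels,
    PhantomSpec,
    layered_phantom,
    spec_from_dict,
    spec_to_dict,
    two_fascia_phantom,
)
from .volumes import Trajectory, Volume3D

__all__ = ["RunConfig", "RunResult", "run_experiment", "extend_into_air"]

log = logging.getLogger("punctforce")


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of a full experiment run.

    ``air_margin_mm`` extends each planned path backwards from the skin into
    the air so the rendered signals include the skin puncture (planning
    starts at skin voxels; force evaluation needs the approach). The
    phantom's random seed is taken from ``seed``.
    """

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    planner: PlannerConfig = field(default_factory=PlannerConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)
    seed: int = 0
    air_margin_mm: float = 5.0
    two_fascia: bool = False

    def to_dict(self) -> dict:
        return {
            "phantom": spec_to_dict(self.phantom),
            "planner": dataclasses.asdict(self.planner),
            "engine": dataclasses.asdict(self.engine),
            "seed": self.seed,
            "air_margin_mm": self.air_margin_mm,
            "two_fascia": self.two_fascia,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        d = dict(data)
        kwargs = {}
        if "phantom" in d:
            kwargs["phantom"] = spec_from_dict(d.pop("phantom"))
        if "planner" in d:
            kwargs["planner"] = PlannerConfig(**d.pop("planner"))
        if "engine" in d:
            kwargs["engine"] = EngineConfig(**d.pop("engine"))
        kwargs.update(d)
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunResult:
    config: RunConfig
    models: PhantomModels
    paths: list[PlannedPath]
    reports: list[PathErrorReport]
    summary: dict
    signals: list[tuple[ForceSignal, ForceSignal]] | None = None


def extend_into_air(traj: Trajectory, margin_mm: float, vol: Volume3D, n_samples: int) -> Trajectory:
    """Shift a path's entry backwards by up to ``margin_mm``, staying inside.

    The planner's paths start at skin voxel centers; the force engine needs
    the approach through air to render the skin puncture. The extension is
    clipped so the new entry's nearest voxel still exists.
    """
    lo = vol.origin_arr
    hi = lo + (np.asarray(vol.shape) - 1) * vol.spacing_arr
    t_max = margin_mm
    for a in range(3):
        d = traj.direction[a]
        if d > 1e-12:
            t_max = min(t_max, (traj.entry[a] - lo[a]) / d)
        elif d < -1e-12:
            t_max = min(t_max, (traj.entry[a] - hi[a]) / d)
    t = max(0.0, t_max)
    length = traj.length + t
    return Trajectory(
        entry=traj.entry - t * traj.direction,
        direction=traj.direction,
        length=length,
        n_samples=n_samples,
        max_length=length,
    )


def run_experiment(cfg: RunConfig, out_dir=None) -> RunResult:
    """Execute phantom -> plan -> simulate ref/test -> evaluate.

    Writes ``paths.csv``, ``reports.csv``, ``summary.json`` and the resolved
    ``config.yaml`` into ``out_dir`` when given. Any stage failure aborts
    with the stage named in the exception.
    """
    chash = cfg.config_hash()
    header = [f"config_hash={chash}", f"seed={cfg.seed}"]
    stages: list[tuple[str, float]] = []

    def _stage(name):
        t0 = time.perf_counter()

        def done():
            dt = time.perf_counter() - t0
            stages.append((name, dt))
            log.info("stage %-10s %.2f s", name, dt)

        return done

    try:
        done = _stage("phantom")
        spec = replace(cfg.phantom, seed=cfg.seed)
        models = two_fascia_phantom(spec) if cfg.two_fascia else layered_phantom(spec)
        done()
    except Exception as exc:
        raise RuntimeError(f"stage 'phantom' failed: {exc}") from exc

    try:
        done = _stage("plan")
        paths = plan_all(models.gold, cfg.planner)
        done()
    except Exception as exc:
        raise RuntimeError(f"stage 'plan' failed: {exc}") from exc

    reports: list[PathErrorReport] = []
    try:
        done = _stage("simulate")
        # Keep the per-sample depth spacing of the planned-path convention
        # (max_length over n_samples) after the air-margin extension.
        target_spacing = cfg.planner.max_length / (cfg.engine.n_samples - 1)
        for p in paths:
            traj = extend_into_air(
                p.trajectory, cfg.air_margin_mm, models.gold.labels, cfg.engine.n_samples
            )
            n = max(cfg.engine.n_samples, int(np.ceil(traj.length / target_spacing)) + 1)
            if n != traj.n_samples:
                traj = replace(traj, n_samples=n)
            ref_sig = render_insertion(traj, models.gold, cfg.engine)
            test_sig = render_insertion(traj, models.test, cfg.engine)
            reports.append(
                evaluate_path(
                    traj,
                    ref_sig,
                    test_sig,
                    models.gold,
                    models.test,
                    tol=cfg.engine.identical_tol,
                )
            )
        done()
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    try:
        done = _stage("evaluate")
        summary = summarize(reports) if reports else {"n_paths": 0}
        done()
    except Exception as exc:
        raise RuntimeError(f"stage 'evaluate' failed: {exc}") from exc

    result = RunResult(
        config=cfg, models=models, paths=paths, reports=reports, summary=summary
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg.save(out / "config.yaml")
        paths_to_csv(paths, out / "paths.csv", header_lines=header)
        reports_to_csv(reports, out / "reports.csv", header_lines=header)
        summary_to_json(
            summary,
            out / "summary.json",
            extra={"config_hash": chash, "seed": cfg.seed},
        )
    return result
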