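"""End-to-end pipeline: simulate -> estimate -> analyze -> report.

A :class:`RunConfig` declares the surface, pull schedule, thermodynamic
parameters, ensemble sizes, estimator choices and output directory;
:func:`run_pipeline` executes the stages, writes every serialized artifact
with provenance (config hash, per-stage seeds, package/library versions) and
returns the in-memory :class:`ResultBundle`.  All randomness flows from one
master seed through counter-based child seeds, so individual stages are
independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import __version__
from .errors import ConfigError, PipelineStageError
from .estimators import (BinGrid, FreeEnergySeries, PMFProfile, bootstrap_sem,
                         minh_adib_pmf, hummer_szabo_pmf)
from .io import write_diagram, write_ensemble, write_free_energy_series, write_pmf
from .mechanism import (EnergyDiagram, compose_diagram, locate_stationary_points,
                        step_energetics)
from .steered import (DEFAULT_BIAS_K, DEFAULT_DT_FS, DEFAULT_N_STEPS,
                      LangevinParams, PullEnsemble, SteeringSchedule, run_msmd)
from .surfaces import surface_from_config

logger = logging.getLogger("halopath")

_KNOWN_ESTIMATORS = ("minh_adib", "hummer_szabo_forward", "hummer_szabo_reverse")


@dataclass
class RunConfig:
    """Declarative pipeline configuration (energies kcal/mol, lengths Å, time fs)."""

    surface: Dict = field(default_factory=lambda: {"name": "two_step", "params": {
        "levels": [0.0, 3.0, -2.4, 3.6, -22.8],
        "positions": [-4.1, -3.4, -3.0, 0.5, 0.8],
    }})
    lambda_start: float = -4.1
    lambda_end: float = 0.8
    n_steps: int = DEFAULT_N_STEPS
    dt: float = DEFAULT_DT_FS
    bias_k: float = DEFAULT_BIAS_K
    temperature: float = 300.0
    friction: float = 100.0
    n_forward: int = 15
    n_reverse: int = 15
    relax_steps: int = 1000
    estimators: List[str] = field(default_factory=lambda: list(_KNOWN_ESTIMATORS))
    n_bins: int = 50
    n_reaction_steps: Optional[int] = 2  # prominence filter for stationary points
    n_boot: int = 0
    seed: int = 0
    outdir: str = "halopath_run"

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> Dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def validate(self) -> None:
        for est in self.estimators:
            if est not in _KNOWN_ESTIMATORS:
                raise ConfigError(f"unknown estimator '{est}'; choose from {_KNOWN_ESTIMATORS}")
        if "minh_adib" in self.estimators and self.n_reverse < 1:
            raise ConfigError("minh_adib estimator requires n_reverse >= 1")
        if "hummer_szabo_reverse" in self.estimators and self.n_reverse < 1:
            raise ConfigError("hummer_szabo_reverse requires n_reverse >= 1")
        if self.n_forward < 1:
            raise ConfigError("n_forward must be >= 1")
        if self.n_bins < 2:
            raise ConfigError("n_bins must be >= 2")


@dataclass
class ResultBundle:
    """All pipeline products plus the provenance needed to re-run them."""

    config: RunConfig
    ensemble: PullEnsemble
    profiles: Dict[str, PMFProfile]
    series: Dict[str, FreeEnergySeries]
    diagram: Optional[EnergyDiagram]
    provenance: Dict
    outdir: Path


def _stage(name: str, provenance: Dict):
    """Context manager recording wall time per stage and re-raising with the stage name."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            provenance.setdefault("stage_seconds", {})[name] = round(dt, 3)
            if exc is not None:
                logger.error("stage %s failed after %.2fs: %s", name, dt, exc)
                raise PipelineStageError(name, exc) from exc
            logger.info("stage %s: done in %.2fs", name, dt)
            return False
    return _Ctx()


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute simulate -> estimate -> analyze -> report for one configuration."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance: Dict = {
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "versions": {
            "halopath": __version__,
            "numpy": np.__version__,
        },
    }
    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=2))

    with _stage("simulate", provenance):
        surface = surface_from_config(config.surface["name"],
                                      config.surface.get("params"))
        schedule = SteeringSchedule(config.lambda_start, config.lambda_end,
                                    n_steps=config.n_steps, dt=config.dt,
                                    k=config.bias_k)
        params = LangevinParams(temperature=config.temperature,
                                friction=config.friction, seed=config.seed)
        ensemble = run_msmd(surface, schedule, params,
                            n_forward=config.n_forward,
                            n_reverse=config.n_reverse,
                            relax_steps=config.relax_steps)
        write_ensemble(ensemble, outdir / "ensemble")
        provenance["trace_seeds"] = {
            "forward": [tr.seed for tr in ensemble.forward],
            "reverse": [tr.seed for tr in ensemble.reverse],
        }

    profiles: Dict[str, PMFProfile] = {}
    series: Dict[str, FreeEnergySeries] = {}
    with _stage("estimate", provenance):
        grid = BinGrid.from_schedule(schedule, config.n_bins)
        for est in config.estimators:
            if est == "minh_adib":
                prof, ser = minh_adib_pmf(ensemble, grid)
            elif est == "hummer_szabo_forward":
                prof, ser = hummer_szabo_pmf(ensemble, grid, direction="forward")
            else:
                prof, ser = hummer_szabo_pmf(ensemble, grid, direction="reverse")
            if config.n_boot >= 2 and est == "minh_adib":
                boot = bootstrap_sem(
                    ensemble,
                    lambda e: minh_adib_pmf(e, grid)[0],
                    n_boot=config.n_boot, seed=config.seed + 1,
                )
                prof.sem = boot.sem
            profiles[est] = prof
            series[est] = ser
            write_pmf(prof, outdir / f"pmf_{est}.csv", outdir / f"pmf_{est}.json",
                      config_hash=provenance["config_hash"])
            write_free_energy_series(ser, outdir / f"dft_{est}.csv")

    diagram: Optional[EnergyDiagram] = None
    with _stage("analyze", provenance):
        primary = profiles.get("minh_adib") or next(iter(profiles.values()))
        try:
            points = locate_stationary_points(primary, n_steps=config.n_reaction_steps)
            diagram = compose_diagram([step_energetics(p) for p in points])
            write_diagram(diagram, outdir / "diagram.json")
        except Exception as exc:  # a featureless profile is not a pipeline failure
            logger.warning("stationary-point analysis skipped: %s", exc)
            provenance["analysis_note"] = str(exc)

    with _stage("report", provenance):
        (outdir / "provenance.json").write_text(
            json.dumps(provenance, indent=2, default=str))

    return ResultBundle(config=config, ensemble=ensemble, profiles=profiles,
                        series=series, diagram=diagram, provenance=provenance,
                        outdir=outdir)


def demo_config(outdir: str = "halopath_demo", seed: int = 0,
                scaled: bool = True) -> RunConfig:
    """Default two-step demonstration configuration.

    ``scaled=True`` shrinks the ensemble and schedule for a seconds-scale run
    while keeping the surface, temperature and bias stiffness; ``scaled=False``
    uses the full study conditions (15+15 pulls of 3000 steps).
    """
    cfg = RunConfig(outdir=outdir, seed=seed)
    if scaled:
        cfg.n_forward = 6
        cfg.n_reverse = 6
        cfg.n_steps = 1500
        cfg.relax_steps = 200
        cfg.n_bins = 98
    else:
        cfg.n_bins = 245  # 0.02 RC-unit bins over the full axis
        cfg.n_boot = 30
    return cfg
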