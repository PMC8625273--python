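"""Run configuration: schema, validation, and experiment dispatch.

A run is described by one YAML mapping.  Required key: ``experiment`` (one
of ``simulate-cell``, ``simulate-population``, ``scan``, ``stability-map``,
``analyze``).  All other keys have defaults; the resolved configuration
(every default materialized) is written next to the outputs, and all
randomness flows from the single ``seed`` key, so a run directory can be
regenerated bit-exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .params import ModelParameters, default_parameters, VARIANTS
from .meanfield import integrate_mean_field
from .analysis import find_stationary_points, scan_parameter, stability_map
from .ssa import simulate_cell, ENGINES
from .population import PopulationEnsemble, simulate_population
from .stats import kaplan_meier, summarize_pools, oscillation_metrics

EXPERIMENTS = (
    "simulate-cell",
    "simulate-population",
    "scan",
    "stability-map",
    "analyze",
)


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending keys."""


@dataclass
class RunConfig:
    experiment: str
    variant: str = "basic"
    params: dict = field(default_factory=dict)  # overrides by rate-constant symbol
    e: float | None = None  # energy level for energy/mixed variants
    init: list = field(default_factory=lambda: [250, 250, 100])
    generations: int = 700
    n_cells: int = 3000
    buffer: int = 100
    seed: int = 0
    engine: str = "exact"
    tau: float = 0.01
    reduced: bool = False
    # scan / stability-map grids: [start, stop, num]
    parameter: str = "k_r"
    grid: list = field(default_factory=lambda: [100.0, 210.0, 111])
    k_r_grid: list = field(default_factory=lambda: [120.0, 210.0, 19])
    e_grid: list = field(default_factory=lambda: [6.0, 30.0, 13])
    # analyze
    ensemble_csv: str | None = None
    window: list | None = None
    frame: int = 100
    step: int = 10

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError("configuration must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {unknown}")
        if "experiment" not in data:
            raise ConfigError("missing required key: experiment")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)

    def validate(self) -> None:
        errors = []
        if self.experiment not in EXPERIMENTS:
            errors.append(f"experiment must be one of {EXPERIMENTS}")
        if self.variant not in VARIANTS:
            errors.append(f"variant must be one of {VARIANTS}")
        if self.engine not in ENGINES:
            errors.append(f"engine must be one of {ENGINES}")
        if self.generations < 1:
            errors.append("generations must be >= 1")
        if self.n_cells < 1:
            errors.append("n_cells must be >= 1")
        if not 0 <= self.buffer < self.generations:
            errors.append("buffer must satisfy 0 <= buffer < generations")
        if not 0 <= int(self.seed) < 2**32:
            errors.append("seed must fit in 32 bits")
        if self.parameter not in ("k_r", "e"):
            errors.append("parameter must be 'k_r' or 'e'")
        for name in ("grid", "k_r_grid", "e_grid"):
            g = getattr(self, name)
            if not (isinstance(g, (list, tuple)) and len(g) == 3 and g[2] >= 1):
                errors.append(f"{name} must be [start, stop, num] with num >= 1")
        if errors:
            raise ConfigError("invalid configuration: " + "; ".join(errors))
        try:
            self.model_parameters()
        except ValueError as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc

    def model_parameters(self) -> ModelParameters:
        base = default_parameters(
            self.variant,
            e=self.e if self.variant in ("energy", "mixed") else None,
        )
        if self.params:
            base = base.with_updates(**self.params)
        return base

    def resolved(self) -> dict:
        d = asdict(self)
        d["package_version"] = __version__
        return d


def _grid(spec) -> np.ndarray:
    start, stop, num = spec
    return np.linspace(float(start), float(stop), int(num))


def run(config: RunConfig, out_dir) -> dict:
    """Execute a configured experiment and write its outputs.

    Writes the resolved config, the experiment's CSV/JSON outputs and a
    manifest listing them; identical config and seed give byte-identical
    CSV and JSON outputs (timing goes to a separate log).  Returns the
    manifest as a dict.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    params = config.model_parameters()
    (out / "config.yaml").write_text(yaml.safe_dump(config.resolved(), sort_keys=True))
    outputs: list[str] = []
    manifest: dict = {
        "experiment": config.experiment,
        "package_version": __version__,
        "seed": int(config.seed),
        "engine": config.engine,
        "parameters": params.to_dict(),
    }
    failure_marker = out / "FAILED"
    try:
        if config.experiment == "simulate-cell":
            traj = simulate_cell(
                params,
                config.init,
                config.generations,
                config.seed,
                engine=config.engine,
                tau=config.tau,
            )
            traj.to_frame().to_csv(out / "trajectory.csv", index=False)
            outputs.append("trajectory.csv")
            mf = integrate_mean_field(
                params,
                np.asarray(config.init, dtype=float)[: traj.counts.shape[1]]
                / params.V,
                config.generations,
            )
            mf.to_frame().to_csv(out / "mean_field.csv", index=False)
            outputs.append("mean_field.csv")
            manifest["n_events"] = traj.n_events
            stable = [p for p in find_stationary_points(params) if p.stable]
            if stable:
                manifest["predicted_period"] = stable[0].period
        elif config.experiment == "simulate-population":
            ens = simulate_population(
                params,
                config.n_cells,
                config.generations,
                config.buffer,
                config.init,
                config.seed,
                engine=config.engine,
                tau=config.tau,
            )
            ens.to_frame().to_csv(out / "ensemble.csv", index=False)
            outputs.append("ensemble.csv")
            manifest["n_retained"] = ens.n_cells
            manifest["n_excluded"] = ens.n_excluded
            manifest["cell_seeds"] = ens.cell_seeds.tolist()
            _analyze(ens, config, out, outputs)
        elif config.experiment == "scan":
            scan = scan_parameter(
                params, config.parameter, _grid(config.grid), reduced=config.reduced
            )
            scan.to_frame().to_csv(out / "scan.csv", index=False)
            outputs.append("scan.csv")
            summary = scan.summary()
            (out / "scan_summary.json").write_text(json.dumps(summary, indent=2))
            outputs.append("scan_summary.json")
            manifest["bifurcations"] = summary["bifurcations"]
        elif config.experiment == "stability-map":
            m = stability_map(params, _grid(config.k_r_grid), _grid(config.e_grid))
            rows = []
            for i, e in enumerate(m["e"]):
                for j, kr in enumerate(m["k_r"]):
                    rows.append(
                        {
                            "k_r": kr,
                            "e": e,
                            "coexistence_exists": bool(m["coexistence_exists"][i, j]),
                            "coexistence_stable": bool(m["coexistence_stable"][i, j]),
                            "trivial_stable": bool(m["trivial_stable"][i, j]),
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "stability_map.csv", index=False)
            outputs.append("stability_map.csv")
        elif config.experiment == "analyze":
            if config.ensemble_csv is None:
                raise ConfigError("analyze requires ensemble_csv")
            df = pd.read_csv(config.ensemble_csv)
            ens = PopulationEnsemble.from_frame(df, params, config.buffer)
            _analyze(ens, config, out, outputs)
    except Exception:
        failure_marker.write_text("run failed; see traceback")
        raise
    manifest["outputs"] = outputs
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "run.log").write_text(
        f"experiment={config.experiment} wall_time_s={time.perf_counter() - t0:.2f}\n"
    )
    return manifest


def _analyze(ens: PopulationEnsemble, config: RunConfig, out: Path, outputs) -> None:
    window = tuple(config.window) if config.window else None
    for species in ("L1", "Alu"):
        curve = kaplan_meier(ens, species)
        name = f"survival_{species}"
        curve.to_frame().to_csv(out / f"{name}.csv", index=False)
        (out / f"{name}.json").write_text(json.dumps(curve.to_json_dict()))
        outputs += [f"{name}.csv", f"{name}.json"]
    summarize_pools(ens, window).to_csv(out / "pool_summary.csv", index=False)
    outputs.append("pool_summary.csv")
    ens.pool_sizes().to_csv(out / "pool_sizes.csv", index=False)
    outputs.append("pool_sizes.csv")
    span = (
        ens.n_generations - ens.analysis_start + 1 if window is None
        else window[1] - window[0] + 1
    )
    if span >= config.frame:
        osc = [
            oscillation_metrics(
                ens, pool, species=sp, frame=config.frame, step=config.step,
                window=window,
            ).to_json_dict()
            for pool in (1, 2)
            for sp in ("L", "S")
        ]
        (out / "oscillations.json").write_text(json.dumps(osc, indent=2))
        outputs.append("oscillations.json")


# ---------------------------------------------------------------------------
# Packaged demonstration configurations
# ---------------------------------------------------------------------------


def demo_fixtures() -> dict[str, RunConfig]:
    """Ready-made small experiments, each feasible in minutes on one CPU."""
    return {
        "single-cell-basic": RunConfig(
            experiment="simulate-cell", variant="basic", generations=700, seed=1
        ),
        "ribosome-kr-scan": RunConfig(
            experiment="scan",
            variant="ribosome",
            parameter="k_r",
            grid=[100.0, 210.0, 111],
        ),
        "survival-scaled": RunConfig(
            experiment="simulate-population",
            variant="ribosome",
            params={"k_r": 190.0},
            n_cells=300,
            generations=700,
            buffer=100,
            seed=1,
        ),
        "energy-scan": RunConfig(
            experiment="scan",
            variant="energy",
            e=10.0,
            parameter="e",
            grid=[6.0, 30.0, 97],
        ),
        "two-predator": RunConfig(
            experiment="simulate-population",
            variant="two_predator",
            init=[250, 250, 100, 250],
            n_cells=100,
            generations=700,
            buffer=100,
            seed=1,
        ),
    }
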