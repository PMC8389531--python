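"""End-to-end campaign orchestration and persistence.

A campaign configuration (YAML or JSON) fully specifies a run: the input
space, the replica seed list, the simulator budget, and the analysis options.
``run_all`` executes the stages in order —

    simulate (adaptive sampling or a fixed sampling plan)
    -> Sobol sensitivity of the surrogate
    -> p-box / confidence intervals
    -> per-configuration shape statistics
    -> CVR robustness report

— writing every product under one output directory (plan.json, table.csv,
nodes.csv, sobol.json, pbox.json, shapes.json, cvr.json, manifest.json).
All randomness flows through explicit integer seeds recorded in the
manifest, so a rerun from the manifest reproduces every artifact.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adaptive import run_campaign
from .aleatoric import pbox, pbox_interval, per_seed_intervals, shape_report
from .quadrature import SparseGridPlan
from .robustness import cvr_ensemble, cvr_per_seed
from .sensitivity import sobol_indices, to_orthogonal_expansion
from .synthetic import (
    DEFAULT_SEEDS,
    InputSpace,
    MockConfig,
    default_input_space,
    make_mock_model,
)
from .tables import EvaluationTable

log = logging.getLogger("uqmd")

__all__ = ["CampaignConfig", "RunManifest", "run_all", "rerun_manifest"]


@dataclass
class CampaignConfig:
    """Validated campaign configuration with study-condition defaults."""

    seeds: tuple = DEFAULT_SEEDS
    budget: int = 600
    quantity: str = "ensemble_mean"
    tolerance: float = 0.0
    max_level: Optional[int] = None
    explore: bool = False
    explore_rtol: float = 0.1
    model: str = "mock"  # "mock" | "csv"
    table_path: Optional[str] = None
    mock_overrides: Optional[dict] = None
    fixed_configurations: Optional[int] = None
    sampling_seed: int = 42
    pbox_level: float = 0.95
    n_boot: int = 2000
    bootstrap_seed: int = 42
    shape_bias: bool = True
    assume_pm15: bool = False
    input_space: Optional[InputSpace] = None

    def __post_init__(self) -> None:
        if self.quantity not in ("ensemble_mean", "single_seed"):
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if self.model not in ("mock", "csv"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "csv" and not self.table_path:
            raise ValueError("model 'csv' requires table_path")
        if self.input_space is None:
            self.input_space = default_input_space()

    @classmethod
    def from_file(cls, path) -> "CampaignConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(payload or {})

    @classmethod
    def from_dict(cls, payload: dict) -> "CampaignConfig":
        payload = dict(payload)
        if "seeds" in payload:
            payload["seeds"] = tuple(int(s) for s in payload["seeds"])
        elif "n_seeds" in payload:
            payload["seeds"] = tuple(range(1, int(payload.pop("n_seeds")) + 1))
        if "input_space" in payload and payload["input_space"] is not None:
            payload["input_space"] = InputSpace.from_dict(payload["input_space"])
        return cls(**payload)

    def to_dict(self) -> dict:
        return {
            "seeds": list(self.seeds),
            "budget": self.budget,
            "quantity": self.quantity,
            "tolerance": self.tolerance,
            "max_level": self.max_level,
            "explore": self.explore,
            "explore_rtol": self.explore_rtol,
            "model": self.model,
            "table_path": self.table_path,
            "mock_overrides": self.mock_overrides,
            "fixed_configurations": self.fixed_configurations,
            "sampling_seed": self.sampling_seed,
            "pbox_level": self.pbox_level,
            "n_boot": self.n_boot,
            "bootstrap_seed": self.bootstrap_seed,
            "shape_bias": self.shape_bias,
            "assume_pm15": self.assume_pm15,
            "input_space": self.input_space.to_dict(),
        }

    def build_mock(self) -> MockConfig:
        overrides = dict(self.mock_overrides or {})
        for key in ("linear_coeffs", "quad_coeffs"):
            if key in overrides:
                overrides[key] = tuple(tuple(x) for x in overrides[key])
        return MockConfig(input_space=self.input_space, seeds=self.seeds, **overrides)


@dataclass
class RunManifest:
    """Record of a finished run: config snapshot, stage outputs, wall log."""

    config: dict
    outputs: Dict[str, str]
    versions: Dict[str, str]
    wall_log: list

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "outputs": self.outputs,
             "versions": self.versions, "wall_log": self.wall_log},
            indent=1,
        )

    @classmethod
    def from_file(cls, path) -> "RunManifest":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def _simulate_fixed_plan(cfg: CampaignConfig, model):
    """Evaluate a fixed number of randomly drawn configurations per seed."""
    rng = np.random.default_rng(cfg.sampling_seed)
    space = cfg.input_space
    n = int(cfg.fixed_configurations)
    unit = rng.uniform(size=(n, space.dimension))
    rows = []
    for cid in range(n):
        physical = space.to_physical(unit[cid])
        for s in cfg.seeds:
            rows.append(
                {"config_id": cid,
                 **dict(zip(space.names, physical)),
                 "seed": int(s), "energy": float(model(tuple(physical), int(s)))}
            )
    return pd.DataFrame(rows, columns=["config_id", *space.names, "seed", "energy"])


def run_all(config, out_dir) -> RunManifest:
    """Run every pipeline stage and persist its products under ``out_dir``.

    ``config`` may be a path to a YAML/JSON file, a dict, or a
    :class:`CampaignConfig`.  Stage failures leave earlier products on disk
    and re-raise after logging the offending stage.
    """
    if isinstance(config, (str, Path)):
        cfg = CampaignConfig.from_file(config)
    elif isinstance(config, dict):
        cfg = CampaignConfig.from_dict(config)
    else:
        cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, str] = {}
    wall: list = []
    stage = "simulate"

    def tick(name: str) -> None:
        wall.append({"stage": name, "time": time.strftime("%Y-%m-%dT%H:%M:%S")})

    try:
        tick(stage)
        plan = None
        node_values = None
        if cfg.model == "csv":
            table = EvaluationTable.from_csv(cfg.table_path)
        elif cfg.fixed_configurations is not None:
            model = make_mock_model(cfg.build_mock())
            table = EvaluationTable(_simulate_fixed_plan(cfg, model))
        else:
            model = make_mock_model(cfg.build_mock())
            result = run_campaign(
                model,
                cfg.input_space,
                seeds=cfg.seeds,
                budget=cfg.budget,
                quantity=cfg.quantity,
                tolerance=cfg.tolerance,
                max_level=cfg.max_level,
                explore=cfg.explore,
                explore_rtol=cfg.explore_rtol,
            )
            plan = result.plan
            node_values = result.node_values
            table = EvaluationTable(result.evaluation_table)
            (out / "history.csv").write_text(result.history.to_csv(index=False))
            outputs["history"] = "history.csv"
        table.to_csv(out / "table.csv")
        outputs["table"] = "table.csv"
        if plan is not None:
            (out / "plan.json").write_text(plan.to_json())
            outputs["plan"] = "plan.json"
            nodes = pd.DataFrame(
                [(*p, node_values[p]) for p in plan.unique_points],
                columns=[*(f"u_{n}" for n in cfg.input_space.names), "qoi"],
            )
            nodes.to_csv(out / "nodes.csv", index=False)
            outputs["nodes"] = "nodes.csv"

        stage = "sobol"
        tick(stage)
        if plan is not None:
            expansion = to_orthogonal_expansion(plan, node_values)
            report = sobol_indices(expansion)
            payload = report.to_dict()
            payload["input_names"] = cfg.input_space.names
            (out / "sobol.json").write_text(json.dumps(payload, indent=1))
            outputs["sobol"] = "sobol.json"
        else:
            log.info("no sparse plan (fixed-plan or csv mode); Sobol stage skipped")

        stage = "pbox"
        tick(stage)
        if table.n_configs < 2:
            log.info("fewer than 2 configurations; p-box stage skipped")
        else:
            box = pbox(table)
            lo, hi, width = pbox_interval(box, cfg.pbox_level)
            per_seed = per_seed_intervals(box, cfg.pbox_level)
            (out / "pbox.json").write_text(json.dumps({
                "level": cfg.pbox_level,
                "lo": lo, "hi": hi, "width": width,
                "per_seed_widths": {str(s): float(w)
                                    for s, w in per_seed["width"].items()},
                "max_individual_width": float(per_seed["width"].max()),
                "min_individual_width": float(per_seed["width"].min()),
            }, indent=1))
            outputs["pbox"] = "pbox.json"

        stage = "shapes"
        tick(stage)
        if table.n_seeds < 3:
            log.info("fewer than 3 replicas; shape stage skipped")
        else:
            shapes = shape_report(table, n_boot=cfg.n_boot,
                                  seed=cfg.bootstrap_seed, bias=cfg.shape_bias)
            (out / "shapes.json").write_text(json.dumps(shapes.to_dict(), indent=1))
            outputs["shapes"] = "shapes.json"

        stage = "cvr"
        tick(stage)
        if table.n_configs < 2:
            log.info("fewer than 2 configurations; CVR stage skipped")
        else:
            rep_e = cvr_ensemble(table, cfg.input_space, assume_pm15=cfg.assume_pm15)
            rep_s = cvr_per_seed(table, cfg.input_space, assume_pm15=cfg.assume_pm15)
            (out / "cvr.json").write_text(json.dumps(
                {"ensemble": rep_e.to_dict(), "per_seed": rep_s.to_dict()}, indent=1))
            outputs["cvr"] = "cvr.json"
    except Exception:
        log.error("stage %r failed; earlier outputs preserved under %s", stage, out)
        raise

    tick("done")
    manifest = RunManifest(
        config=cfg.to_dict(),
        outputs=outputs,
        versions={"uqmd": __version__, "numpy": np.__version__,
                  "pandas": pd.__version__},
        wall_log=wall,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def rerun_manifest(manifest_path, out_dir) -> RunManifest:
    """Re-execute a run from its manifest's configuration snapshot."""
    manifest = RunManifest.from_file(manifest_path)
    return run_all(manifest.config, out_dir)
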