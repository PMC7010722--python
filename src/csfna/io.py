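"""Run configuration, deterministic result serialization and manifests.

Configs are YAML. Concentrations are written in mM everywhere a user sees
them; conversion to the internal mol/cm^3 happens exactly once, in the
parameter loader. A run manifest records every input needed to regenerate
the result files (resolved parameters, grid, seed, multipliers) plus a
content hash over those inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .params import (
    MM_TO_MOL_PER_CM3,
    PARAMETER_UNITS,
    InvalidParameterError,
    PhysiologicalParameterSet,
    _parse_entries,
    nominal_parameters,
)
from .solver import SolverGrid

__all__ = ["RunConfig", "load_config", "config_hash", "write_results"]

log = logging.getLogger("csfna")

_TOP_LEVEL_KEYS = {"parameters", "grid", "seed", "output_dir", "log_level"}


@dataclass
class RunConfig:
    """Validated run configuration with nominal-fixture defaults filled in."""

    parameters: PhysiologicalParameterSet
    grid: SolverGrid
    seed: Optional[int] = None
    output_dir: str = "results"
    log_level: str = "INFO"
    overrides: dict = field(default_factory=dict)

    def resolved(self) -> dict:
        """All inputs in canonical (JSON-stable) form; basis of the hash."""
        p = asdict(self.parameters)
        return {
            "parameters": {k: float(v) for k, v in sorted(p.items())},
            "grid": {"n_r": self.grid.n_r, "dt": self.grid.dt,
                     "t_max": self.grid.t_max},
            "seed": self.seed,
        }


def load_config(path) -> RunConfig:
    """Parse and validate a YAML config; an empty file is the nominal run."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InvalidParameterError("config root must be a mapping")
    unknown = set(raw) - _TOP_LEVEL_KEYS
    if unknown:
        raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")

    overrides = _parse_entries(raw.get("parameters") or {})
    parameters = nominal_parameters(**overrides)
    parameters.check_scale_separation()

    grid_raw = raw.get("grid") or {}
    bad = set(grid_raw) - {"n_r", "dt", "t_max"}
    if bad:
        raise InvalidParameterError(f"unknown grid keys: {sorted(bad)}")
    grid = SolverGrid(n_r=int(grid_raw.get("n_r", 61)),
                      dt=float(grid_raw.get("dt", 1.0)),
                      t_max=float(grid_raw.get("t_max", 7200.0)))

    seed = raw.get("seed")
    if seed is not None:
        seed = int(seed)
    return RunConfig(parameters=parameters, grid=grid, seed=seed,
                     output_dir=str(raw.get("output_dir", "results")),
                     log_level=str(raw.get("log_level", "INFO")),
                     overrides=overrides)


def config_hash(config: RunConfig, extra: Optional[dict] = None) -> str:
    """Library-independent sha256 over the resolved inputs."""
    payload = config.resolved()
    if extra:
        payload = {**payload, "extra": extra}
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


def write_results(output_dir, tables: dict, manifest: dict) -> dict:
    """Write named DataFrames as CSV plus a manifest.json; returns the paths.

    Output is deterministic: identical inputs give byte-identical files.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n")
        paths[name] = str(path)
    manifest = dict(manifest)
    manifest.setdefault("written_files", sorted(paths))
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = str(mpath)
    return paths


class StageTimer:
    """Logs per-stage wall time; used by the CLI."""

    def __init__(self) -> None:
        self.stages: dict = {}

    def __call__(self, name: str):
        return _Stage(self, name)


class _Stage:
    def __init__(self, timer: StageTimer, name: str):
        self.timer, self.name = timer, name

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        dt = time.perf_counter() - self.t0
        self.timer.stages[self.name] = round(dt, 3)
        log.info("stage %s finished in %.2f s", self.name, dt)
        return False
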