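"""Configuration, parameter files, seeds, and the pipeline driver.

Parameter tables travel as CSV with columns (name, value, unit, group) or
as an equivalent JSON document; names are the canonical kinetic inventory
plus diffusion, geometry, and initial-value entries.  Every pipeline output
directory gets a manifest recording the configuration hash, the global
seed, the per-stage child seeds, input file hashes, and wall times, so a
run can be reproduced bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .calibration import CalibrationDataset, fit_parameters
from .moa import BaselineModel, FoldChangeProfile, MoAConfig, estimate_moa
from .parameters import (
    DIFFUSION_NAMES,
    ENZYME_PARAM_NAMES,
    GEOMETRY_NAMES,
    CellGeometry,
    DEFAULT_INITIAL_STATE,
    KineticParameterSet,
    PARAM_NAMES,
    TRANSPORT_NAMES,
)
from .sensitivity import auc_ranking, scan_2d, sensitivity_heatmap
from .simulate import simulate
from .synth import SynthSpec, generate_timecourse, make_inhibitor_panel


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

def _unit_of(name: str) -> str:
    if name.startswith("Km"):
        return "nmol/L"
    if name.startswith("Vmax"):
        return "nmol/L/h"
    if name.startswith("kdiff_"):
        return "mL/h"
    if name in ("cell_volume_0_mL", "medium_volume_mL"):
        return "mL"
    if name == "cell_count_0":
        return "cells"
    if name in DEFAULT_INITIAL_STATE:
        return "nmol/L"
    return "1/h"


def _group_of(name: str) -> str:
    if name in TRANSPORT_NAMES:
        return "transport"
    if name in ENZYME_PARAM_NAMES:
        return "enzyme"
    if name in DIFFUSION_NAMES:
        return "diffusion"
    if name in GEOMETRY_NAMES:
        return "geometry"
    return "initial"


def parameters_to_frame(params: KineticParameterSet,
                        initial_state: dict[str, float] | None = None
                        ) -> pd.DataFrame:
    rows = [{"name": n, "value": params[n], "unit": _unit_of(n),
             "group": _group_of(n)} for n in PARAM_NAMES]
    rows += [{"name": n, "value": getattr(params.geometry, n),
              "unit": _unit_of(n), "group": "geometry"}
             for n in GEOMETRY_NAMES]
    for n, v in (initial_state or DEFAULT_INITIAL_STATE).items():
        rows.append({"name": n, "value": v, "unit": "nmol/L",
                     "group": "initial"})
    return pd.DataFrame(rows)


def save_parameters(params: KineticParameterSet, path,
                    initial_state: dict[str, float] | None = None) -> None:
    """Write a parameter table as CSV or JSON (by file suffix)."""
    path = Path(path)
    frame = parameters_to_frame(params, initial_state)
    if path.suffix == ".json":
        doc = {"parameters": dict(zip(frame["name"], frame["value"])),
               "dilution": params.dilution}
        path.write_text(json.dumps(doc, indent=2))
    else:
        frame.to_csv(path, index=False)


def load_parameters(path) -> tuple[KineticParameterSet, dict[str, float]]:
    """Read and validate a parameter table (CSV or JSON).

    Returns the parameter set and the initial-value table.  Unknown names
    are rejected with the expected inventory; a wrong unit column raises
    with a conversion hint.
    """
    path = Path(path)
    if path.suffix == ".json":
        doc = json.loads(path.read_text())
        entries = {str(k): float(v) for k, v in doc["parameters"].items()}
        units = None
        dilution = bool(doc.get("dilution", True))
    else:
        frame = pd.read_csv(path)
        required = {"name", "value"}
        if not required <= set(frame.columns):
            raise ValueError("parameter CSV needs 'name' and 'value' columns")
        entries = dict(zip(frame["name"].astype(str),
                           frame["value"].astype(float)))
        units = (dict(zip(frame["name"], frame["unit"]))
                 if "unit" in frame.columns else None)
        dilution = True
    known = set(PARAM_NAMES) | set(GEOMETRY_NAMES) | set(DEFAULT_INITIAL_STATE)
    unknown = set(entries) - known
    if unknown:
        raise KeyError(f"unknown parameter names {sorted(unknown)}; expected "
                       f"names from the kinetic inventory: {list(PARAM_NAMES)}"
                       f" + {list(GEOMETRY_NAMES)} + initial values")
    missing = set(PARAM_NAMES) - set(entries)
    if missing:
        raise KeyError(f"parameter file missing {sorted(missing)}")
    if units is not None:
        for name, unit in units.items():
            expected = _unit_of(name)
            if str(unit) != expected:
                raise ValueError(
                    f"unit mismatch for {name}: file says {unit!r} but the "
                    f"model uses {expected!r}; convert the value to "
                    f"{expected!r} before loading")
    geometry = CellGeometry(**{n: entries[n] for n in GEOMETRY_NAMES
                               if n in entries})
    kinetic = {n: entries[n] for n in PARAM_NAMES}
    initial = {n: entries[n] for n in DEFAULT_INITIAL_STATE if n in entries}
    return (KineticParameterSet(kinetic, geometry=geometry,
                                dilution=dilution), initial)


# ---------------------------------------------------------------------------
# Run configuration and seed fan-out
# ---------------------------------------------------------------------------


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed (< 2**31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2 ** 31)


@dataclass
class RunConfig:
    """Declarative description of a pipeline run."""

    stages: list[str] = field(default_factory=list)
    out_dir: str = "results"
    seed: int = 0
    parameters_path: str | None = None
    dataset_path: str | None = None
    profile_path: str | None = None
    fit_free: list[str] = field(default_factory=list)
    moa: dict = field(default_factory=dict)
    scan_theta: float = 0.01
    verbosity: int = 1

    KNOWN_STAGES = ("synth", "simulate", "fit", "moa", "sensitivity", "scan")

    def __post_init__(self):
        unknown = set(self.stages) - set(self.KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        for p in (self.parameters_path, self.dataset_path, self.profile_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        doc = (json.loads(text) if str(path).endswith(".json")
               else yaml.safe_load(text))
        return cls(**doc)

    def canonical(self) -> str:
        doc = {k: v for k, v in self.__dict__.items()}
        return json.dumps(doc, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and write a manifest.

    Every output file is accompanied by manifest entries carrying the
    configuration hash and the seeds used, so deterministic outputs can be
    reproduced bit-exactly from the manifest alone.  A stage failure is
    recorded and re-raised after the manifest is written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.parameters_path:
        params, _ = load_parameters(config.parameters_path)
    else:
        params = KineticParameterSet()
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "inputs": {p: _file_hash(p)
                   for p in (config.parameters_path, config.dataset_path,
                             config.profile_path) if p},
    }
    failure: Exception | None = None
    for stage in config.stages:
        seed = child_seed(config.seed, stage)
        entry: dict = {"seed": seed, "outputs": []}
        t0 = time.perf_counter()
        try:
            entry["outputs"] = _run_stage(stage, config, params, seed, out,
                                          entry)
            entry["status"] = "ok"
        except Exception as exc:  # noqa: BLE001 - reported in manifest
            entry["status"] = f"failed: {exc}"
            failure = exc
        entry["wall_s"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][stage] = entry
        if failure is not None:
            break
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if failure is not None:
        raise failure
    return manifest


def _run_stage(stage: str, config: RunConfig, params: KineticParameterSet,
               seed: int, out: Path, entry: dict) -> list[str]:
    if stage == "synth":
        spec = SynthSpec(params=params, seed=seed)
        dataset, _ = generate_timecourse(spec)
        path = out / "synthetic_timecourse.csv"
        dataset.write_csv(path)
        panel = make_inhibitor_panel(seed=seed, spec=spec)
        ppath = out / "synthetic_panel.csv"
        pd.concat([prof.to_frame(c, d)
                   for (c, d), prof in panel.profiles.items()]
                  ).to_csv(ppath, index=False)
        tpath = out / "synthetic_panel_truth.csv"
        panel.truth.to_csv(tpath, index=False)
        return [str(path), str(ppath), str(tpath)]
    if stage == "simulate":
        traj = simulate(params)
        path = out / "trajectory.csv"
        traj.write_csv(path)
        return [str(path)]
    if stage == "fit":
        if not config.dataset_path:
            raise ValueError("fit stage needs dataset_path")
        dataset = CalibrationDataset.read_csv(config.dataset_path)
        free = config.fit_free or ["Vmax_CYP11A1"]
        result = fit_parameters(dataset, params, free)
        entry["final_nlsd"] = result.final_nlsd
        path = out / "fit_result.json"
        path.write_text(json.dumps({
            "free": list(result.free_names),
            "values": {n: result.params[n] for n in result.free_names},
            "initial_nlsd": result.initial_nlsd,
            "final_nlsd": result.final_nlsd,
        }, indent=2))
        return [str(path)]
    if stage == "moa":
        if not config.profile_path:
            raise ValueError("moa stage needs profile_path")
        frame = pd.read_csv(config.profile_path)
        profile = FoldChangeProfile.from_frame(frame)
        model = BaselineModel(params)
        moa_cfg = MoAConfig(seed=seed, **config.moa)
        result = estimate_moa(profile, model, moa_cfg)
        entry["fitness"] = result.fitness
        path = out / "moa_estimate.json"
        doc = {"activities": result.activities.to_dict(),
               "fitness": result.fitness,
               "generations": result.generations,
               "converged": result.converged}
        if result.duplicate is not None:
            doc["duplicate"] = {
                "activities": result.duplicate.activities.to_dict(),
                "fitness": result.duplicate.fitness,
            }
        path.write_text(json.dumps(doc, indent=2))
        return [str(path)]
    if stage == "sensitivity":
        matrix = sensitivity_heatmap(params)
        path = out / "sensitivity.csv"
        matrix.to_frame().to_csv(path, index=False)
        rpath = out / "sensitivity_auc_ranking.csv"
        auc_ranking(matrix).to_csv(rpath, index=False)
        return [str(path), str(rpath)]
    if stage == "scan":
        grid = scan_2d(params, theta=config.scan_theta)
        path = out / "scan_2d.csv"
        grid.to_frame().to_csv(path, index=False)
        return [str(path)]
    raise ValueError(f"unknown stage {stage!r}")
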