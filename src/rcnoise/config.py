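"""Config-file-driven experiment runner.

Experiments are described by a flat JSON (or YAML) document validated
against :class:`ExperimentConfig`; unknown keys are rejected.  Each run
writes tidy CSV tables plus a ``manifest.json`` recording the config hash,
seed schedule, and package version, so identical config+seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .bifurcation import bifurcation_1d, bifurcation_2d, find_steady_states, sensitivity_sn
from .fdt import noise_curves
from .params import CircuitParams, ResourceMode
from .ssa import clamped_mean_run, dose_sweep, gillespie_run
from .stats import noise_dose_curves

__all__ = ["ExperimentConfig", "run_experiment", "load_config"]

ExperimentKind = Literal[
    "dose_response_det",
    "bifurcation_1d",
    "bifurcation_2d",
    "sensitivity",
    "ssa_single",
    "ssa_sweep",
    "fdt_curves",
    "clamped_compare",
]


class ExperimentConfig(BaseModel):
    """Validated description of one figure-level analysis."""

    model_config = ConfigDict(extra="forbid")

    kind: ExperimentKind
    mode: str = "shared"
    params: dict[str, float] = Field(default_factory=dict)  # overrides only
    parameter: str = "I1"  # swept parameter where applicable
    lo: float = 0.0
    hi: float = 2.0
    resolution: int = 400
    y_parameter: str = "1/Jp2"
    y_lo: float = 0.0
    y_hi: float = 1.0
    y_resolution: int = 21
    doses: Optional[list[float]] = None
    reps: int = 10
    t_end: float = 5000.0
    dt_sample: float = 0.1
    burn_in_frac: float = 0.2
    seed: int = 0
    clamp_reference: str = "empirical"
    branch: Optional[str] = None
    out_dir: str = "results"

    def circuit_params(self) -> CircuitParams:
        return CircuitParams().replace(**self.params)

    def resource_mode(self) -> ResourceMode:
        return ResourceMode.coerce(self.mode)

    def content_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: "str | Path") -> ExperimentConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        data: Any = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return ExperimentConfig.model_validate(data)


def _dose_grid(cfg: ExperimentConfig) -> list[float]:
    if cfg.doses is not None:
        return list(cfg.doses)
    return list(np.linspace(cfg.lo, cfg.hi, 21))


def run_experiment(cfg: ExperimentConfig, out_dir: "str | Path | None" = None) -> Path:
    """Dispatch a config to the owning module; write tables + manifest.

    Returns the output directory.
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = cfg.circuit_params()
    mode = cfg.resource_mode()

    if cfg.kind == "dose_response_det":
        from .model import steady_state_closed_form

        rows = []
        for dose in _dose_grid(cfg):
            p = params.replace(**{cfg.parameter: dose})
            if mode is ResourceMode.SHARED:
                pts = find_steady_states(p, mode)
                for pt in pts:
                    s = pt.state
                    rows.append({cfg.parameter: dose, "m1": s.m1, "p1": s.p1,
                                 "m2": s.m2, "p2": s.p2, "stable": pt.stable})
            else:
                s = steady_state_closed_form(p, mode)
                rows.append({cfg.parameter: dose, "m1": s.m1, "p1": s.p1,
                             "m2": s.m2, "p2": s.p2, "stable": True})
        pd.DataFrame(rows).to_csv(out / "dose_response.csv", index=False)

    elif cfg.kind == "bifurcation_1d":
        diag = bifurcation_1d(params, mode, cfg.parameter, cfg.lo, cfg.hi,
                              resolution=cfg.resolution)
        diag.to_csv(out / "branches.csv")
        diag.sn_to_json(out / "sn_points.json")

    elif cfg.kind == "bifurcation_2d":
        res = bifurcation_2d(
            params, mode, p_x=(cfg.lo, cfg.hi), p_y=(cfg.y_lo, cfg.y_hi),
            x_name=cfg.parameter, y_name=cfg.y_parameter,
            resolution_x=cfg.resolution, resolution_y=cfg.y_resolution,
        )
        rows = [
            {"y": r["y"], "sn_index": i, "x": x}
            for r in res["rows"]
            for i, x in enumerate(r["sn"])
        ]
        pd.DataFrame(rows).to_csv(out / "sn_curves.csv", index=False)
        (out / "cusp.json").write_text(json.dumps({"cusp": res["cusp"]}) + "\n")

    elif cfg.kind == "sensitivity":
        rep = sensitivity_sn(params, mode, sweep=(cfg.parameter, cfg.lo, cfg.hi),
                             resolution=max(cfg.resolution, 100))
        rep.to_frame().to_csv(out / "sensitivity.csv", index=False)
        (out / "baseline_sn.json").write_text(
            json.dumps({"sn1": rep.baseline_sn[0], "sn2": rep.baseline_sn[1]}) + "\n"
        )

    elif cfg.kind == "ssa_single":
        traj = gillespie_run(params, mode, cfg.t_end, cfg.seed,
                             dt_sample=cfg.dt_sample, burn_in_frac=cfg.burn_in_frac)
        traj.to_csv(out / "trajectory.csv")

    elif cfg.kind == "ssa_sweep":
        doses = _dose_grid(cfg)
        sweep = dose_sweep(params, mode, doses, cfg.reps, cfg.t_end, cfg.seed,
                           dose_parameter=cfg.parameter, dt_sample=cfg.dt_sample,
                           burn_in_frac=cfg.burn_in_frac)
        noise_dose_curves(sweep, doses, cfg.parameter).to_csv(
            out / "noise_curves.csv", index=False
        )

    elif cfg.kind == "fdt_curves":
        noise_curves(params, mode, np.asarray(_dose_grid(cfg)), cfg.parameter).to_csv(
            out / "fdt_curves.csv", index=False
        )

    elif cfg.kind == "clamped_compare":
        doses = _dose_grid(cfg)
        free = dose_sweep(params, ResourceMode.SHARED, doses, cfg.reps, cfg.t_end,
                          cfg.seed, dose_parameter=cfg.parameter,
                          dt_sample=cfg.dt_sample, burn_in_frac=cfg.burn_in_frac)
        clamped = dose_sweep(params, ResourceMode.SHARED, doses, cfg.reps, cfg.t_end,
                             cfg.seed, dose_parameter=cfg.parameter, clamped=True,
                             clamp_reference=cfg.clamp_reference,
                             dt_sample=cfg.dt_sample, burn_in_frac=cfg.burn_in_frac)
        a = noise_dose_curves(free, doses, cfg.parameter).assign(variant="free")
        b = noise_dose_curves(clamped, doses, cfg.parameter).assign(variant="clamped")
        pd.concat([a, b], ignore_index=True).to_csv(
            out / "clamped_compare.csv", index=False
        )

    else:  # pragma: no cover - guarded by pydantic Literal
        raise ValueError(f"unknown experiment kind {cfg.kind}")

    manifest = {
        "kind": cfg.kind,
        "config": cfg.model_dump(),
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
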