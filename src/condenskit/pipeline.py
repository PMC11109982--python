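"""Run configuration and end-to-end pipeline execution.

A :class:`RunConfig` (JSON-serializable, unknown keys rejected) selects one
or more stages -- ``frap``, ``smt``, ``dwell``, ``stack``, ``dynamics`` --
each of which simulates its modality with the configured parameters, writes
the synthetic inputs, runs the corresponding analysis, and writes result
tables plus a machine-readable provenance record (config hash, seed, package
versions, QC exclusions).  Reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .errors import AnalysisError, InputError, SchemaError
from . import dynamics as dyn
from . import frap as frap_mod
from . import io as ckio
from . import morphology as morph
from . import simulate as sim
from . import smt as smt_mod

__all__ = ["RunConfig", "run_pipeline", "derive_seed"]


def derive_seed(base: int, index: int) -> int:
    """Deterministic per-item seed below 2**31."""
    return (base * 100003 + 7919 * index + 1) % (2**31)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FrapStage(_Strict):
    n_traces: int = 12
    sim: dict = {}
    normalization: str = "double"
    model: str = "two_component"


class SmtStage(_Strict):
    sim: dict = {}
    min_points: int = 7
    n_states: int = 2
    logd_threshold: float = -0.5


class DwellStage(_Strict):
    n_events: int = 2000
    frac_long: float = 0.1
    tau_long: float = 10.0
    tau_short: float = 0.9
    frame_interval: float = 0.5
    max_obs_time: float = 250.0
    threshold: float = 1.0


class StackStage(_Strict):
    sim: dict = {}
    detection: dict = {}


class DynamicsStage(_Strict):
    sim: dict = {}
    detection: dict = {}
    max_disp: float = 0.5
    alpha: float = 0.6


class RunConfig(_Strict):
    """Single source of truth for a reproducible pipeline run."""

    seed: int = 0
    out_dir: str = "run"
    version: str = __version__
    frap: FrapStage | None = None
    smt: SmtStage | None = None
    dwell: DwellStage | None = None
    stack: StackStage | None = None
    dynamics: DynamicsStage | None = None

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]

    @classmethod
    def from_json_file(cls, path: str | Path) -> "RunConfig":
        try:
            return cls.model_validate_json(Path(path).read_text())
        except Exception as exc:
            raise SchemaError(f"invalid run config {path}: {exc}") from exc


def _params(cls, overrides: dict, **fixed):
    try:
        return cls(**{**overrides, **fixed})
    except TypeError as exc:
        raise SchemaError(f"unknown parameter for {cls.__name__}: {exc}") from exc


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(sim._jsonable(obj), sort_keys=True, indent=1))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _run_frap(cfg: FrapStage, seed: int, out: Path) -> dict:
    traces = []
    for i in range(cfg.n_traces):
        p = _params(sim.FrapSimParams, cfg.sim, seed=derive_seed(seed, i))
        trace, truth = sim.simulate_frap(p)
        trace.condition = cfg.sim.get("condition", "sim")
        ckio.write_frap_csv(trace, out / f"trace_{i:03d}.csv")
        ckio.write_ground_truth(truth, out / f"trace_{i:03d}.truth.json")
        traces.append(trace)
    result = frap_mod.frap_batch(
        traces, normalization=cfg.normalization, model=cfg.model
    )
    ckio.write_table(result["fits"], out / "fits.csv")
    ckio.write_table(result["summary"], out / "summary.csv")
    excluded = result["fits"].loc[
        result["fits"]["qc_pass"] == False, ["trace", "qc_reasons"]  # noqa: E712
    ]
    return {"n_traces": cfg.n_traces,
            "qc_excluded": excluded.to_dict(orient="records")}


def _run_smt(cfg: SmtStage, seed: int, out: Path) -> dict:
    p = _params(sim.SmtSimParams, cfg.sim, seed=derive_seed(seed, 0))
    tracks, truth = sim.simulate_trajectories(p)
    ckio.write_trajectories_csv(tracks, out / "tracks.csv")
    ckio.write_ground_truth(truth, out / "tracks.truth.json")
    filtered, n_removed = smt_mod.filter_tracks(tracks, cfg.min_points)
    diffusion = smt_mod.track_diffusion(filtered)
    ckio.write_table(diffusion, out / "diffusion.csv")
    mobility = smt_mod.classify_mobility(diffusion, cfg.logd_threshold)
    fit = smt_mod.fit_jump_length_model(filtered, n_states=cfg.n_states)
    results = {
        "n_tracks": tracks.n_tracks,
        "n_removed_short": n_removed,
        "fraction_mobile": mobility.fraction_mobile,
        "fraction_immobile": mobility.fraction_immobile,
        "jump_model": {
            "D_states": fit.D_states_.tolist(),
            "fractions": fit.fractions_.tolist(),
            "sigma": fit.sigma_,
            "loss": fit.loss_,
        },
    }
    _write_json(results, out / "smt_results.json")
    return {"n_removed_short": n_removed}


def _run_dwell(cfg: DwellStage, seed: int, out: Path) -> dict:
    sample, truth = sim.simulate_dwell_events(
        cfg.n_events, cfg.frac_long, cfg.tau_long, cfg.tau_short,
        cfg.frame_interval, cfg.max_obs_time, seed=derive_seed(seed, 0),
    )
    ckio.write_dwell_csv(sample, out / "dwell.csv")
    ckio.write_ground_truth(truth, out / "dwell.truth.json")
    fit = smt_mod.dwell_time_analysis(sample, threshold=cfg.threshold)
    _write_json(
        {
            "f_long": fit.f_long, "tau_long": fit.tau_long,
            "tau_short": fit.tau_short, "n_long": fit.n_long_events,
            "n_short": fit.n_short_events, "ratio": fit.long_to_short_ratio,
            "status": fit.status, "flags": list(fit.flags),
        },
        out / "dwell_results.json",
    )
    return {"status": fit.status}


def _run_stack(cfg: StackStage, seed: int, out: Path) -> dict:
    p = _params(sim.StackSimParams, cfg.sim, seed=derive_seed(seed, 0))
    stack, truth = sim.simulate_stack(p)
    ckio.write_stack_tiff(stack, out / "stack.tiff")
    ckio.write_ground_truth(truth, out / "stack.truth.json")
    frame = stack.frame(0)
    nucleus = morph.segment_nucleus(frame)
    det_cfg = _params(morph.DetectionConfig, cfg.detection)
    table, labels = morph.detect_condensates(frame, nucleus, det_cfg)
    ckio.write_table(table, out / "condensates.csv")
    partition = morph.partition_3d(frame, nucleus)
    ratio, status = morph.diffuse_total_ratio(frame, nucleus, labels)
    _write_json(
        {
            "n_condensates": int(len(table)),
            "nuclear_fraction": partition.nuclear_fraction,
            "cytoplasmic_fraction": partition.cytoplasmic_fraction,
            "diffuse_total_ratio": ratio,
            "diffuse_total_status": status,
        },
        out / "morphometry.json",
    )
    return {"n_condensates": int(len(table))}


def _run_dynamics(cfg: DynamicsStage, seed: int, out: Path) -> dict:
    p = _params(sim.StackSimParams, cfg.sim, seed=derive_seed(seed, 0))
    if p.n_timepoints < 2:
        raise SchemaError("dynamics stage needs n_timepoints >= 2")
    stack, truth = sim.simulate_stack(p)
    ckio.write_ground_truth(truth, out / "movie.truth.json")
    det_cfg = _params(morph.DetectionConfig, cfg.detection)
    tables = []
    for t in range(stack.n_timepoints):
        frame = stack.frame(t)
        nucleus = morph.segment_nucleus(frame)
        table, _ = morph.detect_condensates(frame, nucleus, det_cfg)
        tables.append(table)
    tracks = dyn.link_condensates(tables, max_disp=cfg.max_disp,
                                  frame_interval=40.0)
    ckio.write_table(tracks.df, out / "condensate_tracks.csv")
    speeds = dyn.track_speed(tracks)
    ckio.write_table(speeds, out / "track_speeds.csv")
    events = dyn.detect_events(tracks, alpha=cfg.alpha)
    ev_df = pd.DataFrame(
        [
            {"type": e.type, "time": e.time,
             "parent_ids": ";".join(map(str, e.parent_ids)),
             "child_ids": ";".join(map(str, e.child_ids)),
             "mass_balance": e.mass_balance}
            for e in events
        ],
        columns=["type", "time", "parent_ids", "child_ids", "mass_balance"],
    )
    ckio.write_table(ev_df, out / "events.csv")
    return {"n_events_detected": int(len(ev_df))}


_STAGES = {
    "frap": _run_frap,
    "smt": _run_smt,
    "dwell": _run_dwell,
    "stack": _run_stack,
    "dynamics": _run_dynamics,
}


def run_pipeline(config: RunConfig) -> Path:
    """Execute all configured stages and write a provenance log.

    Returns the run directory.  A stage failure aborts the run with the
    failing stage named; outputs of completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config": json.loads(config.canonical_json()),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"condenskit": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": {},
        "outputs": {},
    }
    for name, runner in _STAGES.items():
        cfg = getattr(config, name)
        if cfg is None:
            continue
        stage_dir = out / name
        stage_dir.mkdir(exist_ok=True)
        try:
            info = runner(cfg, config.seed, stage_dir)
        except (InputError, AnalysisError) as exc:
            provenance["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "provenance.json").write_text(
                json.dumps(provenance, sort_keys=True, indent=1)
            )
            raise AnalysisError(f"stage '{name}' failed: {exc}") from exc
        provenance["stages"][name] = {"status": "ok", **info}
        provenance["outputs"][name] = sorted(
            str(f.relative_to(out)) for f in stage_dir.iterdir()
        )
    (out / "provenance.json").write_text(
        json.dumps(provenance, sort_keys=True, indent=1)
    )
    return out
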