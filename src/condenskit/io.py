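"""Readers and writers for the package's tabular and image formats.

Schemas
-------
FRAP trace CSV: ``time_s, bleach, reference, background, phase`` with
``phase`` in {pre, bleach, post}.  Trajectory CSV: ``track_id, frame, x_um,
y_um``.  Stacks: multi-page TIFF in TZCYX order with a JSON metadata sidecar
(``<stem>.meta.json``) carrying voxel sizes and channel names.  Ground truth:
JSON.  All table round trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import SchemaError
from .frap import FrapTrace
from .morphology import LabeledStack
from .simulate import GroundTruth
from .smt import DwellTimeSample, TrajectorySet

__all__ = [
    "write_frap_csv", "read_frap_csv",
    "write_trajectories_csv", "read_trajectories_csv",
    "write_dwell_csv", "read_dwell_csv",
    "write_stack_tiff", "read_stack_tiff",
    "write_ground_truth", "read_ground_truth",
    "write_table", "read_table",
]

# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------


def write_frap_csv(trace: FrapTrace, path: str | Path) -> None:
    n = trace.time.size
    phase = np.array(
        ["pre"] * trace.n_prebleach
        + ["bleach"] * trace.bleach_frame_span
        + ["post"] * (n - trace.post_start)
    )
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "bleach": trace.bleach,
            "reference": trace.reference,
            "background": trace.background,
            "phase": phase,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_frap_csv(path: str | Path, condition: str = "") -> FrapTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"time_s", "bleach", "reference", "background", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["phase"].unique()) - {"pre", "bleach", "post"}
    if bad:
        raise SchemaError(f"{path}: unknown phase values {sorted(bad)}")
    n_pre = int((df["phase"] == "pre").sum())
    n_span = int((df["phase"] == "bleach").sum())
    return FrapTrace(
        time=df["time_s"].to_numpy(),
        bleach=df["bleach"].to_numpy(),
        reference=df["reference"].to_numpy(),
        background=df["background"].to_numpy(),
        n_prebleach=n_pre,
        bleach_frame_span=n_span,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# trajectories and dwell samples
# ---------------------------------------------------------------------------


def write_trajectories_csv(tracks: TrajectorySet, path: str | Path) -> None:
    df = tracks.df.rename(columns={"x": "x_um", "y": "y_um"})
    df.to_csv(path, index=False, float_format="%.17g")


def read_trajectories_csv(
    path: str | Path, frame_interval: float,
    localization_error_prior: float | None = None,
) -> TrajectorySet:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"track_id", "frame", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    df = df.rename(columns={"x_um": "x", "y_um": "y"})
    return TrajectorySet(df, frame_interval=frame_interval,
                         localization_error_prior=localization_error_prior)


def write_dwell_csv(sample: DwellTimeSample, path: str | Path) -> None:
    pd.DataFrame(
        {"duration_s": sample.durations, "censored": sample.censored.astype(int)}
    ).to_csv(path, index=False, float_format="%.17g")


def read_dwell_csv(path: str | Path, frame_interval: float) -> DwellTimeSample:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"duration_s", "censored"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return DwellTimeSample(
        df["duration_s"].to_numpy(), df["censored"].to_numpy(dtype=bool),
        frame_interval,
    )


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_stack_tiff(stack: LabeledStack, path: str | Path) -> None:
    """Write a two-channel stack as TZCYX TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    cond = stack.condensate
    nuc = stack.nuclear
    if cond.ndim == 3:
        cond = cond[None]
        nuc = nuc[None]
    data = np.stack([cond, nuc], axis=2).astype(np.float32)  # T,Z,C,Y,X
    tifffile.imwrite(path, data, metadata={"axes": "TZCYX"})
    meta = {
        "axes": "TZCYX",
        "channels": ["condensate", "nuclear"],
        "voxel_size_zyx_um": list(stack.voxel_size_zyx),
        "n_timepoints": int(data.shape[0]),
    }
    _sidecar(path).write_text(json.dumps(meta, sort_keys=True))


def read_stack_tiff(
    path: str | Path, voxel_size_zyx: tuple[float, float, float] | None = None
) -> LabeledStack:
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = _sidecar(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if voxel_size_zyx is None:
        if "voxel_size_zyx_um" not in meta:
            raise SchemaError(
                f"{path}: no voxel-size metadata found; pass voxel_size_zyx "
                "explicitly (CLI: --voxel)"
            )
        voxel_size_zyx = tuple(meta["voxel_size_zyx_um"])
    if data.ndim == 4:  # single timepoint written as ZCYX or squeezed TZCYX
        data = data[None] if data.shape[1] == 2 and data.ndim == 4 else data
    if data.ndim == 5:
        cond, nuc = data[:, :, 0], data[:, :, 1]
    elif data.ndim == 4 and data.shape[1] == 2:
        cond, nuc = data[:, 0], data[:, 1]
    else:
        raise SchemaError(f"{path}: expected TZCYX or ZCYX with 2 channels, "
                          f"got shape {data.shape}")
    if cond.shape[0] == 1:
        cond, nuc = cond[0], nuc[0]
    return LabeledStack(np.asarray(cond, float), np.asarray(nuc, float),
                        tuple(voxel_size_zyx))


# ---------------------------------------------------------------------------
# ground truth and result tables
# ---------------------------------------------------------------------------


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
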