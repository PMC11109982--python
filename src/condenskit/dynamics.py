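"""Time-lapse condensate tracking and fusion/fission event detection.

Detections from successive timepoints are linked by globally greedy
nearest-neighbour assignment under a maximum displacement, with a
deterministic tie-break (distance, then lower detection label).  Track speeds
are path length over elapsed time.  Fusion and fission are detected from
track terminations/births adjacent to a detection that approximately
conserves integrated object volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "CondensateTrackSet",
    "EventRecord",
    "link_condensates",
    "track_speed",
    "detect_events",
    "match_events",
]


@dataclass
class CondensateTrackSet:
    """Linked condensate tracks.

    ``df`` has columns ``track_id, frame, z, y, x, volume, mean_intensity,
    det_label`` (one detection per track per frame).
    """

    df: pd.DataFrame
    frame_interval: float
    max_disp: float

    @property
    def n_tracks(self) -> int:
        return int(self.df["track_id"].nunique())


@dataclass
class EventRecord:
    type: str  # "fusion" | "fission"
    time: int  # frame index at which the child/children first exist
    parent_ids: tuple[int, ...]
    child_ids: tuple[int, ...]
    mass_balance: float  # child volume / alpha-weighted parent volume ratio


_REQUIRED = ("label", "centroid_z", "centroid_y", "centroid_x", "volume")


def _detection_array(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ParameterError(f"detection table missing columns {missing}")
    out = table.rename(
        columns={"centroid_z": "z", "centroid_y": "y", "centroid_x": "x"}
    ).copy()
    if "mean_intensity" not in out.columns:
        out["mean_intensity"] = np.nan
    # conserved mass proxy, in order of preference: background-corrected
    # integrated intensity, raw integrated intensity, thresholded volume
    if "corrected_mass" in out.columns:
        out["mass"] = out["corrected_mass"]
    elif "integrated_intensity" in out.columns:
        out["mass"] = out["integrated_intensity"]
    else:
        out["mass"] = out["volume"]
    return out[["label", "z", "y", "x", "volume", "mean_intensity", "mass"]]


def link_condensates(
    tables: list[pd.DataFrame], max_disp: float, frame_interval: float = 1.0
) -> CondensateTrackSet:
    """Greedy nearest-neighbour linking of per-frame detection tables.

    All candidate (track end, detection) pairs within ``max_disp`` are sorted
    by (distance, detection label) and assigned greedily; unmatched detections
    start new tracks, unmatched tracks end.  The tie rule makes linking
    deterministic and permutation-invariant to detection order within a frame.
    """
    if len(tables) < 2:
        raise ParameterError("linking requires at least two frames")
    frames = [_detection_array(t) for t in tables]

    next_track = 0
    rows = []
    active: dict[int, np.ndarray] = {}  # track_id -> last position
    for _, det in frames[0].iterrows():
        rows.append(dict(track_id=next_track, frame=0, **det.to_dict()))
        active[next_track] = det[["z", "y", "x"]].to_numpy(dtype=float)
        next_track += 1

    for t in range(1, len(frames)):
        det = frames[t].sort_values("label").reset_index(drop=True)
        pos = det[["z", "y", "x"]].to_numpy(dtype=float)
        candidates = []
        for tid, last in active.items():
            if pos.size:
                dists = np.linalg.norm(pos - last, axis=1)
                for j in np.nonzero(dists <= max_disp)[0]:
                    candidates.append((float(dists[j]), int(det.loc[j, "label"]),
                                       tid, int(j)))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        assignment: dict[int, int] = {}
        for dist, _, tid, j in candidates:
            if tid in used_tracks or j in used_dets:
                continue
            assignment[j] = tid
            used_tracks.add(tid)
            used_dets.add(j)
        new_active: dict[int, np.ndarray] = {}
        for j in range(len(det)):
            rec = det.loc[j].to_dict()
            tid = assignment.get(j)
            if tid is None:
                tid = next_track
                next_track += 1
            rows.append(dict(track_id=tid, frame=t, **rec))
            new_active[tid] = pos[j]
        active = new_active

    df = pd.DataFrame(rows).rename(columns={"label": "det_label"})
    df = df[["track_id", "frame", "z", "y", "x", "volume", "mean_intensity",
             "mass", "det_label"]]
    return CondensateTrackSet(df=df.sort_values(["track_id", "frame"]).
                              reset_index(drop=True),
                              frame_interval=frame_interval, max_disp=max_disp)


def track_speed(tracks: CondensateTrackSet) -> pd.DataFrame:
    """Mean speed per track in nm/s: total path length over elapsed time."""
    dt = tracks.frame_interval
    rows = []
    for tid, grp in tracks.df.groupby("track_id", sort=False):
        if len(grp) < 2:
            continue
        xyz = grp[["z", "y", "x"]].to_numpy(dtype=float)
        path = float(np.sum(np.linalg.norm(np.diff(xyz, axis=0), axis=1)))
        elapsed = (grp["frame"].iloc[-1] - grp["frame"].iloc[0]) * dt
        rows.append({"track_id": tid, "n_frames": len(grp),
                     "mean_speed_nm_s": 1000.0 * path / elapsed})
    return pd.DataFrame(rows, columns=["track_id", "n_frames", "mean_speed_nm_s"])


def detect_events(
    tracks: CondensateTrackSet,
    alpha: float = 0.6,
    boundary_margin: int = 1,
    transient_frames: int = 2,
) -> list[EventRecord]:
    """Detect fusion and fission events from linked tracks.

    Fusion at frame t+1: at least two detections at frame t (at least one of
    them a terminating track) lie within ``max_disp`` of a detection at t+1
    whose mass is within ``[alpha, 1/alpha]`` of their summed mass.  Fission
    is symmetric (one parent at t, >=2 children at t+1, at least one newly
    born, combined child mass within the same band of the parent mass).  Mass is the integrated
    intensity of the detection (volume when intensities are unavailable),
    which is conserved across merge/split, unlike the thresholded volume.
    Events within ``boundary_margin`` frames of the movie boundaries are
    suppressed as indistinguishable from track birth/death, and a fusion
    undone by a fission of the same track within ``transient_frames`` (or
    vice versa) is treated as a transient detection merge/split and dropped.
    """
    df = tracks.df
    max_disp = tracks.max_disp
    t_max = int(df["frame"].max())
    first = df.groupby("track_id")["frame"].min()
    last = df.groupby("track_id")["frame"].max()
    by_frame = {t: grp for t, grp in df.groupby("frame")}

    events: list[EventRecord] = []
    for t in range(boundary_margin, t_max - boundary_margin):
        cur = by_frame.get(t)
        nxt = by_frame.get(t + 1)
        if cur is None or nxt is None:
            continue
        cur_pos = cur[["z", "y", "x"]].to_numpy(dtype=float)
        nxt_pos = nxt[["z", "y", "x"]].to_numpy(dtype=float)
        ended = set(cur.loc[cur["track_id"].map(last).eq(t), "track_id"])
        born = set(nxt.loc[nxt["track_id"].map(first).eq(t + 1), "track_id"])

        consumed_parents: set[int] = set()
        # fusion: child detections at t+1 gathering >=2 nearby parents
        for j in range(len(nxt)):
            child = nxt.iloc[j]
            dists = np.linalg.norm(cur_pos - nxt_pos[j], axis=1)
            near = cur.iloc[np.nonzero(dists <= max_disp)[0]]
            parents = near[
                near["track_id"].isin(ended - consumed_parents)
                | (near["track_id"] == child["track_id"])
            ]
            ended_parents = parents[parents["track_id"].isin(ended)]
            if len(parents) < 2 or len(ended_parents) < 1:
                continue
            mass_sum = float(parents["mass"].sum())
            if mass_sum <= 0 or not (
                alpha * mass_sum <= child["mass"] <= mass_sum / alpha
            ):
                continue
            events.append(
                EventRecord(
                    type="fusion",
                    time=t + 1,
                    parent_ids=tuple(int(i) for i in parents["track_id"]),
                    child_ids=(int(child["track_id"]),),
                    mass_balance=float(child["mass"] / mass_sum),
                )
            )
            consumed_parents.update(int(i) for i in ended_parents["track_id"])

        consumed_children: set[int] = set()
        # fission: parent detections at t scattering >=2 nearby children
        for i in range(len(cur)):
            parent = cur.iloc[i]
            dists = np.linalg.norm(nxt_pos - cur_pos[i], axis=1)
            near = nxt.iloc[np.nonzero(dists <= max_disp)[0]]
            children = near[
                near["track_id"].isin(born - consumed_children)
                | (near["track_id"] == parent["track_id"])
            ]
            born_children = children[children["track_id"].isin(born)]
            if len(children) < 2 or len(born_children) < 1:
                continue
            parent_mass = float(parent["mass"])
            if parent_mass <= 0:
                continue
            mass_sum = float(children["mass"].sum())
            if not (alpha * parent_mass <= mass_sum <= parent_mass / alpha):
                continue
            events.append(
                EventRecord(
                    type="fission",
                    time=t + 1,
                    parent_ids=(int(parent["track_id"]),),
                    child_ids=tuple(int(i) for i in children["track_id"]),
                    mass_balance=float(mass_sum / parent_mass),
                )
            )
            consumed_children.update(int(i) for i in born_children["track_id"])
    return _suppress_transients(events, transient_frames)


def _suppress_transients(
    events: list[EventRecord], transient_frames: int
) -> list[EventRecord]:
    if transient_frames <= 0:
        return events
    drop: set[int] = set()
    for i, fu in enumerate(events):
        if fu.type != "fusion" or i in drop:
            continue
        for j, fi in enumerate(events):
            if fi.type != "fission" or j in drop:
                continue
            dt_frames = fi.time - fu.time
            if 0 < dt_frames <= transient_frames and set(fi.parent_ids) & set(
                fu.child_ids
            ):
                drop.update((i, j))  # merge immediately undone: not an event
                break
            if 0 < -dt_frames <= transient_frames and set(fu.parent_ids) & set(
                fi.child_ids
            ):
                drop.update((i, j))  # split immediately undone
                break
    return [e for k, e in enumerate(events) if k not in drop]


def match_events(
    detected: list[EventRecord],
    truth: list[dict],
    time_tolerance: int = 1,
) -> tuple[int, int, int]:
    """Match detected events to ground-truth events by type and time.

    Returns ``(n_matched, n_detected, n_truth)``; precision is
    matched/detected and recall matched/truth.
    """
    used = [False] * len(detected)
    matched = 0
    for ev in truth:
        for k, det in enumerate(detected):
            if used[k]:
                continue
            if det.type == ev["type"] and abs(det.time - ev["time"]) <= time_tolerance:
                used[k] = True
                matched += 1
                break
    return matched, len(detected), len(truth)
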