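"""Seeded synthetic-data generators with ground truth.

Every analysis stage in the package is exercised against data produced here:
FRAP recovery traces, multi-state Brownian single-molecule trajectories,
two-exponential dwell-time samples, and two-channel 3D/4D image stacks of
nuclear condensates with optional scripted fusion/fission events.  Each
``simulate_*`` call uses one seeded ``numpy.random.Generator`` (PCG64) and
returns the dataset together with a :class:`GroundTruth` record of every
generating parameter and per-object truth, enabling parameter-recovery tests
without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.optimize import brentq

import pandas as pd

from .errors import AnalysisError, ParameterError
from .frap import FrapTrace
from .morphology import LabeledStack
from .smt import DwellTimeSample, TrajectorySet

__all__ = [
    "FrapSimParams",
    "SmtSimParams",
    "StackSimParams",
    "GroundTruth",
    "simulate_frap",
    "simulate_trajectories",
    "simulate_dwell_events",
    "simulate_stack",
    "frap_params_for_t_half",
]

RNG_ALGORITHM = "numpy.random.Generator(PCG64)"


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class GroundTruth:
    """Generator-side record of parameters and per-object truth."""

    modality: str  # frap | smt | dwell | stack
    params: dict
    truth: dict
    seed: int
    rng_algorithm: str = RNG_ALGORITHM

    def to_json(self) -> str:
        return json.dumps(_jsonable(asdict(self)), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        data = json.loads(text)
        return cls(**data)


def _check_fraction(value: float, name: str) -> None:
    if not (np.isfinite(value) and 0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must be a fraction in [0, 1], got {value!r}")


def _check_positive(value: float, name: str) -> None:
    if not (np.isfinite(value) and value > 0):
        raise ParameterError(f"{name} must be positive and finite, got {value!r}")


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrapSimParams:
    """FRAP acquisition model.

    The bleached-droplet expectation follows the plateau model

        M(t) = depth + mobile (1 - depth) [s (1-e^{-t/tau1}) + (1-s)(1-e^{-t/tau2})]

    (t from the first post-bleach frame), multiplied by whole-cell
    mono-exponential acquisition photobleaching; the bleach pulse destroys
    ``gap_loss`` of the whole-cell (reference) fluorescence as a step.
    Defaults follow a confocal droplet-FRAP protocol: 5 s frame interval over
    415 s of recovery, a small bleach ROI (per-pulse whole-cell loss of ~2%),
    gentle acquisition bleaching (~19% over the full series) and 2% Gaussian
    intensity noise.
    """

    n_prebleach: int = 10
    n_postbleach: int = 83
    frame_interval: float = 5.0
    mobile_fraction_true: float = 0.8
    tau1: float = 20.0
    tau2: float = 80.0
    amp_split: float = 0.5
    bleach_depth: float = 0.25
    acq_bleach_rate: float = 5e-4
    background_level: float = 50.0
    noise_sd: float = 0.02
    gap_loss: float = 0.02
    seed: int = 0
    intensity_scale: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("mobile_fraction_true", "amp_split", "bleach_depth", "gap_loss"):
            _check_fraction(getattr(self, name), name)
        for name in ("frame_interval", "tau1", "tau2", "intensity_scale"):
            _check_positive(getattr(self, name), name)
        for name in ("acq_bleach_rate", "background_level", "noise_sd"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ParameterError(f"{name} must be non-negative, got {v!r}")
        if self.n_prebleach < 1 or self.n_postbleach < 2:
            raise ParameterError("need >=1 pre-bleach and >=2 post-bleach frames")
        if self.amp_split < 1.0 and not self.tau1 < self.tau2:
            raise ParameterError("tau1 must be smaller than tau2")


def _frap_recovery(t: np.ndarray, p: FrapSimParams) -> np.ndarray:
    rec = p.amp_split * (1 - np.exp(-t / p.tau1)) + (1 - p.amp_split) * (
        1 - np.exp(-t / p.tau2)
    )
    return p.bleach_depth + p.mobile_fraction_true * (1 - p.bleach_depth) * rec


def _frap_true_t_half(p: FrapSimParams) -> float:
    def g(t):
        return (
            p.amp_split * (1 - np.exp(-t / p.tau1))
            + (1 - p.amp_split) * (1 - np.exp(-t / p.tau2))
            - 0.5
        )

    return float(brentq(g, 1e-9, 100 * max(p.tau1, p.tau2)))


def frap_params_for_t_half(
    t_half: float,
    mobile_fraction: float,
    tau_ratio: float = 4.0,
    amp_split: float = 0.5,
    **overrides,
) -> FrapSimParams:
    """Parameters whose true recovery half-time equals ``t_half``.

    The two recovery time constants keep a fixed ratio, so the half-time
    scales linearly with ``tau1``; the scale factor is solved once.
    """

    def g(u):
        return amp_split * (1 - np.exp(-u)) + (1 - amp_split) * (
            1 - np.exp(-u / tau_ratio)
        ) - 0.5

    u_star = brentq(g, 1e-9, 1e4)
    tau1 = t_half / u_star
    return FrapSimParams(
        mobile_fraction_true=mobile_fraction,
        tau1=tau1,
        tau2=tau_ratio * tau1,
        amp_split=amp_split,
        **overrides,
    )


def simulate_frap(params: FrapSimParams) -> tuple[FrapTrace, GroundTruth]:
    """Simulate a three-ROI FRAP trace with known recovery kinetics."""
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_prebleach + p.n_postbleach
    t_abs = np.arange(n) * p.frame_interval
    t_post = np.arange(p.n_postbleach) * p.frame_interval

    decay = np.exp(-p.acq_bleach_rate * t_abs)
    bl = np.concatenate([np.ones(p.n_prebleach), _frap_recovery(t_post, p)]) * decay
    ref = (
        np.concatenate([np.ones(p.n_prebleach),
                        (1.0 - p.gap_loss) * np.ones(p.n_postbleach)])
        * decay
    )
    scale = p.intensity_scale

    def noisy(clean: np.ndarray) -> np.ndarray:
        # noise_sd is relative: each sample carries Gaussian noise
        # proportional to its expected intensity
        return clean * (1.0 + p.noise_sd * rng.normal(size=clean.shape))

    bleach = noisy(scale * bl + p.background_level)
    reference = noisy(scale * ref + p.background_level)
    background = noisy(np.full(n, p.background_level))

    trace = FrapTrace(
        time=t_abs,
        bleach=bleach,
        reference=reference,
        background=background,
        n_prebleach=p.n_prebleach,
    )
    plateau_true = float(_frap_recovery(np.array([np.inf]), p)[0])
    truth = GroundTruth(
        modality="frap",
        params=asdict(p),
        truth={
            "t_half": _frap_true_t_half(p),
            "mobile_fraction": p.mobile_fraction_true,
            "plateau": plateau_true,
            "f0": p.bleach_depth,
        },
        seed=p.seed,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# single-molecule trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SmtSimParams:
    """Multi-state Brownian trajectory generator.

    ``states`` lists (diffusion coefficient um^2/s, occupancy); occupancies
    must sum to 1.  ``switch_rates`` is an optional per-second rate matrix
    (off-diagonal entries used); ``None`` keeps each molecule in its initial
    state.  Localization error is added to reported positions only; tracks
    end by photobleaching with a per-frame probability.  Defaults emulate a
    fast acquisition (20 ms frames) of a nuclear protein with a bound and a
    freely diffusing population.
    """

    n_molecules: int = 2000
    frame_interval: float = 0.02
    n_frames: int = 200
    states: tuple[tuple[float, float], ...] = ((0.01, 0.46), (2.0, 0.54))
    switch_rates: tuple[tuple[float, ...], ...] | None = None
    loc_error_sd: float = 0.03
    bleach_prob_per_frame: float = 0.05
    fov_size: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        occ = [s[1] for s in self.states]
        if abs(sum(occ) - 1.0) > 1e-9:
            raise ParameterError(f"state occupancies must sum to 1, got {sum(occ)}")
        for d, f in self.states:
            if d < 0 or not np.isfinite(d):
                raise ParameterError("diffusion coefficients must be >= 0")
            _check_fraction(f, "occupancy")
        if self.switch_rates is not None:
            q = np.asarray(self.switch_rates, dtype=float)
            if q.shape != (len(self.states), len(self.states)):
                raise ParameterError("switch_rates must be k x k for k states")
            off = q[~np.eye(len(self.states), dtype=bool)]
            if np.any(off < 0):
                raise ParameterError("off-diagonal switch rates must be >= 0")
        _check_positive(self.frame_interval, "frame_interval")
        _check_fraction(self.bleach_prob_per_frame, "bleach_prob_per_frame")
        if self.loc_error_sd < 0:
            raise ParameterError("loc_error_sd must be >= 0")
        if self.n_molecules < 1 or self.n_frames < 2:
            raise ParameterError("need >=1 molecule and >=2 frames")


def simulate_trajectories(params: SmtSimParams) -> tuple[TrajectorySet, GroundTruth]:
    """Simulate multi-state Brownian tracks observed with localization noise."""
    p = params
    rng = np.random.default_rng(p.seed)
    k = len(p.states)
    d_states = np.array([s[0] for s in p.states])
    occ = np.array([s[1] for s in p.states])
    dt = p.frame_interval

    if p.switch_rates is not None:
        q = np.asarray(p.switch_rates, dtype=float).copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        trans = expm(q * dt)
        trans = np.clip(trans, 0, None)
        trans /= trans.sum(axis=1, keepdims=True)
    else:
        trans = None

    if p.bleach_prob_per_frame > 0:
        lengths = 1 + rng.geometric(p.bleach_prob_per_frame, size=p.n_molecules)
        lengths = np.minimum(lengths, p.n_frames)
    else:
        lengths = np.full(p.n_molecules, p.n_frames)

    records = []
    state_sequences = []
    init_states = rng.choice(k, size=p.n_molecules, p=occ)
    for m in range(p.n_molecules):
        L = int(lengths[m])
        states = np.empty(L, dtype=int)
        states[0] = init_states[m]
        if trans is not None:
            for i in range(1, L):
                states[i] = rng.choice(k, p=trans[states[i - 1]])
        else:
            states[:] = states[0]
        sd_step = np.sqrt(2.0 * d_states[states[:-1]] * dt)
        steps = rng.normal(size=(L - 1, 2)) * sd_step[:, None]
        pos = np.empty((L, 2))
        pos[0] = rng.uniform(0, p.fov_size, size=2)
        np.cumsum(steps, axis=0, out=pos[1:])
        pos[1:] += pos[0]
        obs = pos + rng.normal(0, p.loc_error_sd, size=pos.shape) * (
            p.loc_error_sd > 0
        )
        for i in range(L):
            records.append((m, i, obs[i, 0], obs[i, 1]))
        state_sequences.append(states.tolist())

    df = pd.DataFrame(records, columns=["track_id", "frame", "x", "y"])
    tracks = TrajectorySet(df, frame_interval=dt,
                           localization_error_prior=p.loc_error_sd)
    truth = GroundTruth(
        modality="smt",
        params=asdict(p),
        truth={
            "d_states": d_states.tolist(),
            "occupancies": occ.tolist(),
            "state_sequences": state_sequences,
            "track_lengths": lengths.tolist(),
        },
        seed=p.seed,
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# dwell times
# ---------------------------------------------------------------------------


def simulate_dwell_events(
    n_events: int,
    frac_long: float,
    tau_long: float,
    tau_short: float,
    frame_interval: float,
    max_obs_time: float,
    seed: int = 0,
) -> tuple[DwellTimeSample, GroundTruth]:
    """Two-exponential residence-time mixture, frame-discretized and censored.

    Durations are drawn from ``frac_long Exp(tau_long) + (1-frac_long)
    Exp(tau_short)``, rounded up to whole frames, and right-censored at
    ``max_obs_time`` (never discarded), mirroring a finite acquisition.
    """
    _check_fraction(frac_long, "frac_long")
    _check_positive(frame_interval, "frame_interval")
    _check_positive(max_obs_time, "max_obs_time")
    if frac_long > 0 and not tau_long > tau_short > 0:
        raise ParameterError("need tau_long > tau_short > 0")
    if frac_long == 0 and tau_short <= 0:
        raise ParameterError("tau_short must be positive")
    if n_events < 1:
        raise ParameterError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    is_long = rng.random(n_events) < frac_long
    raw = np.where(
        is_long,
        rng.exponential(tau_long, n_events),
        rng.exponential(tau_short, n_events),
    )
    frames = np.maximum(np.ceil(raw / frame_interval), 1)
    durations = frames * frame_interval
    censored = durations >= max_obs_time
    durations = np.minimum(durations, max_obs_time)
    sample = DwellTimeSample(durations, censored, frame_interval)
    truth = GroundTruth(
        modality="dwell",
        params={
            "n_events": n_events, "frac_long": frac_long, "tau_long": tau_long,
            "tau_short": tau_short, "frame_interval": frame_interval,
            "max_obs_time": max_obs_time,
        },
        truth={
            "raw_durations": raw.tolist(),
            "is_long_component": is_long.tolist(),
        },
        seed=seed,
    )
    return sample, truth


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StackSimParams:
    """Two-channel nuclear-condensate stack generator.

    A cell (outer ellipsoid) contains an ellipsoidal nucleus; the nuclear
    marker fills the nucleus, while the condensate channel combines a diffuse
    nucleoplasmic level, a dimmer cytoplasmic level, and per-condensate
    isotropic Gaussian intensity profiles (or radial Gaussian shells in
    ``shell_mode``, emulating anisosomes).  The scene is blurred with a
    Gaussian PSF and corrupted with Poisson-Gaussian noise.  For time-lapse
    stacks, condensate centres take Gaussian random steps and scripted
    fusion/fission events replace parents by children at stated frames.
    """

    shape_zyx: tuple[int, int, int] = (20, 80, 80)
    voxel_size_zyx: tuple[float, float, float] = (0.3, 0.1, 0.1)
    nucleus_semiaxes: tuple[float, float, float] = (1.8, 2.5, 2.5)
    cell_scale: float = 1.4
    n_condensates: int = 20
    condensate_radius: float | tuple[float, float] = 0.2
    condensate_amplitude: float = 400.0
    shell_mode: bool = False
    diffuse_nuclear_level: float = 100.0
    cytoplasm_level: float = 40.0
    background_level: float = 5.0
    nuclear_marker_level: float = 300.0
    psf_sigma_zyx: tuple[float, float, float] = (0.2, 0.1, 0.1)
    poisson_gain: float = 0.0  # photons per count; 0 disables shot noise
    gaussian_noise_sd: float = 0.0
    n_timepoints: int = 1
    motion_sd: float = 0.05
    min_separation: float = 0.8
    pair_separation: float = 0.72
    scripted_events: tuple[dict, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 4 for s in self.shape_zyx):
            raise ParameterError("stack shape too small")
        if any(v <= 0 for v in self.voxel_size_zyx):
            raise ParameterError("voxel sizes must be positive")
        if any(a <= 0 for a in self.nucleus_semiaxes):
            raise ParameterError("nucleus semiaxes must be positive")
        if self.n_condensates < 0:
            raise ParameterError("n_condensates must be >= 0")
        if self.condensate_amplitude <= self.diffuse_nuclear_level and (
            self.n_condensates > 0
        ):
            raise ParameterError(
                "condensate amplitude must exceed the diffuse nuclear level"
            )
        if self.n_timepoints < 1:
            raise ParameterError("n_timepoints must be >= 1")
        for ev in self.scripted_events:
            if ev.get("type") not in ("fusion", "fission"):
                raise ParameterError(f"unknown scripted event type: {ev!r}")
            t = int(ev.get("time", -1))
            if not (2 <= t <= self.n_timepoints - 2):
                raise ParameterError(
                    "scripted event time must lie at least 2 frames from the "
                    "movie boundaries"
                )


@dataclass
class _Blob:
    ident: int
    center: np.ndarray  # um, (z, y, x)
    sigma: float  # um, isotropic
    amplitude: float
    born: int
    died: int  # exclusive; n_timepoints if alive at the end
    partner_of: int | None = None  # rigid-pair follower (pre-fusion)
    offset: np.ndarray | None = None


def _ellipsoid_mask(shape, voxel, center_um, semiaxes) -> np.ndarray:
    grids = [np.arange(n) * v for n, v in zip(shape, voxel)]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij")
    return (
        ((zz - center_um[0]) / semiaxes[0]) ** 2
        + ((yy - center_um[1]) / semiaxes[1]) ** 2
        + ((xx - center_um[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def _inside_ellipsoid(pt, center, semiaxes) -> bool:
    return float(np.sum(((pt - center) / np.asarray(semiaxes)) ** 2)) <= 1.0


def _blob_integral_counts(sigma: float, amplitude: float, shell: bool,
                          voxel_volume: float) -> float:
    """Total counts contributed by one blob (PSF conserves this)."""
    if not shell:
        return amplitude * (2 * np.pi) ** 1.5 * sigma**3 / voxel_volume
    r0, s = sigma * 2.0, sigma / 2.0  # shell radius and thickness (see render)
    val, _ = quad(lambda r: 4 * np.pi * r**2 * np.exp(-((r - r0) ** 2) / (2 * s**2)),
                  0, r0 + 8 * s)
    return amplitude * val / voxel_volume


def simulate_stack(params: StackSimParams) -> tuple[LabeledStack, GroundTruth]:
    """Render a two-channel condensate stack (or time-lapse) with truth."""
    p = params
    rng = np.random.default_rng(p.seed)
    shape = tuple(p.shape_zyx)
    voxel = tuple(p.voxel_size_zyx)
    extent = np.array([s * v for s, v in zip(shape, voxel)])
    center = extent / 2.0
    nuc_ax = np.asarray(p.nucleus_semiaxes, dtype=float)
    cell_ax = nuc_ax * p.cell_scale
    if np.any(cell_ax >= extent / 2.0):
        raise ParameterError("cell ellipsoid does not fit in the field of view")

    nucleus = _ellipsoid_mask(shape, voxel, center, nuc_ax)
    cell = _ellipsoid_mask(shape, voxel, center, cell_ax)
    voxel_volume = float(np.prod(voxel))

    # ---- placement ------------------------------------------------------
    def radius_of(i: int) -> float:
        if isinstance(p.condensate_radius, tuple):
            lo, hi = p.condensate_radius
            return float(rng.uniform(lo, hi))
        return float(p.condensate_radius)

    radii = [radius_of(i) for i in range(p.n_condensates)]
    margin = max(radii, default=0.0) + 0.3
    placement_ax = np.maximum(nuc_ax - margin, 0.1)

    def sample_point() -> np.ndarray:
        for _ in range(200):
            pt = center + (rng.uniform(-1, 1, 3) * placement_ax)
            if _inside_ellipsoid(pt, center, placement_ax):
                return pt
        raise AnalysisError("could not sample a point inside the nucleus")

    fusion_partners = {}
    for ev in p.scripted_events:
        if ev["type"] == "fusion":
            a, b = ev["participants"]
            fusion_partners[b] = a

    blobs: list[_Blob] = []
    failures = 0
    for i in range(p.n_condensates):
        if i in fusion_partners:
            continue  # placed relative to its partner below
        while True:
            pt = sample_point()
            if all(
                np.linalg.norm(pt - b.center) >= p.min_separation for b in blobs
            ):
                break
            failures += 1
            if failures > 5000:
                raise AnalysisError(
                    "condensate placement failed after bounded retries; "
                    "reduce n_condensates or min_separation"
                )
        blobs.append(
            _Blob(ident=i, center=pt, sigma=radii[i] / 2.0,
                  amplitude=p.condensate_amplitude, born=0, died=p.n_timepoints)
        )
    for b_id, a_id in fusion_partners.items():
        anchor = next(bl for bl in blobs if bl.ident == a_id)
        for _ in range(200):
            direction = rng.normal(size=3)
            direction[0] = 0.0  # keep the pair in-plane for stable detection
            direction /= np.linalg.norm(direction)
            offset = direction * p.pair_separation
            pos = anchor.center + offset
            clear = all(
                bl.ident == a_id
                or np.linalg.norm(pos - bl.center) >= p.min_separation
                for bl in blobs
            ) and _inside_ellipsoid(pos, center, placement_ax)
            if clear:
                break
        else:
            raise AnalysisError("could not place fusion partner clear of "
                                "other condensates")
        blobs.append(
            _Blob(ident=b_id, center=pos,
                  sigma=radii[b_id] / 2.0, amplitude=p.condensate_amplitude,
                  born=0, died=p.n_timepoints, partner_of=a_id, offset=offset)
        )

    # ---- trajectories and scripted events -------------------------------
    next_id = p.n_condensates
    events_truth: list[dict] = []
    by_frame_events: dict[int, list[dict]] = {}
    for ev in p.scripted_events:
        by_frame_events.setdefault(int(ev["time"]), []).append(ev)

    # positions[t] maps blob ident -> (center, sigma, amplitude)
    registry = {b.ident: b for b in blobs}
    frames_state: list[dict[int, tuple[np.ndarray, float, float]]] = []
    for t in range(p.n_timepoints):
        for ev in by_frame_events.get(t, []):
            if ev["type"] == "fusion":
                a_id, b_id = ev["participants"]
                a, b = registry[a_id], registry[b_id]
                a.died = t
                b.died = t
                sig = (a.sigma**3 + b.sigma**3) ** (1.0 / 3.0)
                amp = (a.amplitude * a.sigma**3 + b.amplitude * b.sigma**3) / sig**3
                child = _Blob(ident=next_id,
                              center=(a.center + b.center) / 2.0,
                              sigma=sig, amplitude=amp, born=t,
                              died=p.n_timepoints)
                registry[next_id] = child
                events_truth.append({"type": "fusion", "time": t,
                                     "parents": [a_id, b_id],
                                     "children": [next_id]})
                next_id += 1
            else:  # fission
                (a_id,) = ev["participants"]
                a = registry[a_id]
                a.died = t
                direction = rng.normal(size=3)
                direction[0] = 0.0
                direction /= np.linalg.norm(direction)
                offset = direction * (p.pair_separation / 2.0)
                sig = a.sigma / 2.0 ** (1.0 / 3.0)
                kids = []
                lead_id = next_id
                for sgn in (+1.0, -1.0):
                    child = _Blob(ident=next_id, center=a.center + sgn * offset,
                                  sigma=sig, amplitude=a.amplitude, born=t,
                                  died=p.n_timepoints)
                    if sgn < 0:
                        # children separate as a rigid pair so the scripted
                        # split stays resolvable in later frames
                        child.partner_of = lead_id
                        child.offset = -2.0 * offset
                    registry[next_id] = child
                    kids.append(next_id)
                    next_id += 1
                events_truth.append({"type": "fission", "time": t,
                                     "parents": [a_id], "children": kids})

        state = {}
        for b in registry.values():
            if b.born <= t < b.died:
                state[b.ident] = (b.center.copy(), b.sigma, b.amplitude)
        frames_state.append(state)

        # random-walk step into the next frame (rigid pre-fusion pairs move
        # with their anchor so the scripted separation is preserved)
        if t + 1 < p.n_timepoints and p.motion_sd > 0:
            sep = 0.9 * p.min_separation
            for b in registry.values():
                if not (b.born <= t + 1 < b.died) or b.partner_of is not None:
                    continue
                others = [
                    o for o in registry.values()
                    if o.ident != b.ident and o.partner_of != b.ident
                    and b.partner_of != o.ident and (o.born <= t + 1 < o.died)
                ]
                partner = next(
                    (o for o in registry.values()
                     if o.partner_of == b.ident and o.born <= t + 1 < o.died),
                    None,
                )
                for _ in range(20):
                    step = rng.normal(0, p.motion_sd, 3)
                    cand = b.center + step
                    # stay in the nucleus and clear of other condensates so
                    # only scripted events change the object count; a rigid
                    # partner's implied position must stay clear as well
                    ok = _inside_ellipsoid(cand, center, placement_ax) and all(
                        np.linalg.norm(cand - o.center) >= sep for o in others
                    )
                    if ok and partner is not None:
                        ppos = cand + partner.offset
                        ok = _inside_ellipsoid(ppos, center, placement_ax) and all(
                            np.linalg.norm(ppos - o.center) >= sep
                            for o in others
                        )
                    if ok:
                        b.center = cand
                        break
            for b in registry.values():
                if b.partner_of is not None and b.born <= t + 1 < b.died:
                    anchor = registry[b.partner_of]
                    b.center = anchor.center + b.offset

    # ---- rendering -------------------------------------------------------
    grids = [np.arange(n) * v for n, v in zip(shape, voxel)]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij")
    psf_vox = [s / v for s, v in zip(p.psf_sigma_zyx, voxel)]
    from scipy.ndimage import gaussian_filter

    def render(state: dict) -> tuple[np.ndarray, np.ndarray]:
        cond = np.full(shape, p.background_level, dtype=float)
        cond[cell] = p.background_level + p.cytoplasm_level
        cond[nucleus] = p.background_level + p.diffuse_nuclear_level
        for ident, (c, sig, amp) in state.items():
            d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
            if p.shell_mode:
                r0, s = sig * 2.0, sig / 2.0
                cond += amp * np.exp(-((np.sqrt(d2) - r0) ** 2) / (2 * s**2))
            else:
                cond += amp * np.exp(-d2 / (2 * sig**2))
        nuc = np.full(shape, p.background_level, dtype=float)
        nuc[nucleus] += p.nuclear_marker_level
        if any(s > 0 for s in psf_vox):
            cond = gaussian_filter(cond, sigma=psf_vox)
            nuc = gaussian_filter(nuc, sigma=psf_vox)
        if p.poisson_gain > 0:
            cond = rng.poisson(cond / p.poisson_gain) * p.poisson_gain
            nuc = rng.poisson(nuc / p.poisson_gain) * p.poisson_gain
        if p.gaussian_noise_sd > 0:
            cond = cond + rng.normal(0, p.gaussian_noise_sd, shape)
            nuc = nuc + rng.normal(0, p.gaussian_noise_sd, shape)
        return np.clip(cond, 0, None), np.clip(nuc, 0, None)

    cond_frames, nuc_frames = [], []
    for state in frames_state:
        c, nch = render(state)
        cond_frames.append(c)
        nuc_frames.append(nch)
    if p.n_timepoints == 1:
        stack = LabeledStack(cond_frames[0], nuc_frames[0], voxel)
    else:
        stack = LabeledStack(np.stack(cond_frames), np.stack(nuc_frames), voxel)

    # ---- truth -----------------------------------------------------------
    center_records = []
    for t, state in enumerate(frames_state):
        for ident, (c, sig, amp) in state.items():
            center_records.append(
                {"id": ident, "frame": t, "z": c[0], "y": c[1], "x": c[2],
                 "sigma": sig, "amplitude": amp,
                 "volume": 4.0 / 3.0 * np.pi * (2.0 * sig) ** 3}
            )
    blob_counts = sum(
        _blob_integral_counts(sig, amp, p.shell_mode, voxel_volume)
        for _, (c, sig, amp) in frames_state[0].items()
    )
    n_nuc = int(nucleus.sum())
    n_cell = int(cell.sum())
    nuclear_signal = p.diffuse_nuclear_level * n_nuc + blob_counts
    cyto_signal = p.cytoplasm_level * (n_cell - n_nuc)
    truth = GroundTruth(
        modality="stack",
        params=_jsonable(asdict(p)),
        truth={
            "nucleus_center_um": center.tolist(),
            "nucleus_semiaxes_um": nuc_ax.tolist(),
            "cell_semiaxes_um": cell_ax.tolist(),
            "n_nucleus_voxels": n_nuc,
            "n_cell_voxels": n_cell,
            "condensates": center_records,
            "events": events_truth,
            "blob_total_counts_t0": blob_counts,
            "nuclear_fraction": nuclear_signal / (nuclear_signal + cyto_signal)
            if (nuclear_signal + cyto_signal) > 0
            else float("nan"),
        },
        seed=p.seed,
    )
    return stack, truth
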