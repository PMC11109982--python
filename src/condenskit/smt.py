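"""Single-molecule trajectory analytics.

Operates on trajectory tables (track id, frame, x, y in micrometres) at a
stated frame interval -- the output of an upstream localization/linking step.
Provides track filtering, per-track diffusion coefficients from the short-lag
mean squared displacement, mobile/immobile classification on log10(D),
jump-length (displacement distribution) mixture fitting for 2- or 3-state
kinetic models, and censoring-aware dwell-time (residence time) analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import least_squares
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator
from lifelines import KaplanMeierFitter

from .errors import FitError, ParameterError, SchemaError

__all__ = [
    "TrajectorySet",
    "DwellTimeSample",
    "DwellTimeFit",
    "MobilityResult",
    "JumpLengthMixture",
    "DwellTimeMixture",
    "filter_tracks",
    "track_diffusion",
    "classify_mobility",
    "find_inflection_threshold",
    "collect_displacements",
    "fit_jump_length_model",
    "jump_length_pdf",
    "dwell_time_analysis",
]

D_FLOOR = 1e-4  # um^2/s floor applied before taking log10


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class TrajectorySet:
    """Trajectory table with columns ``track_id, frame, x, y`` (um).

    Frames within a track must be strictly increasing; single-frame gaps
    (fluorophore blinking) are permitted and flagged in ``tracks_with_gaps``.
    """

    df: pd.DataFrame
    frame_interval: float
    localization_error_prior: float | None = None
    tracks_with_gaps: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        required = {"track_id", "frame", "x", "y"}
        missing = required - set(self.df.columns)
        if missing:
            raise SchemaError(f"trajectory table missing columns {sorted(missing)}")
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be positive")
        gaps = set()
        for tid, grp in self.df.groupby("track_id", sort=False):
            d = np.diff(grp["frame"].to_numpy())
            if np.any(d <= 0):
                raise SchemaError(f"track {tid}: frames not strictly increasing")
            if np.any(d > 2):
                raise SchemaError(f"track {tid}: gap longer than one frame")
            if np.any(d == 2):
                gaps.add(tid)
        df = self.df.sort_values(["track_id", "frame"],
                                 kind="stable").reset_index(drop=True)
        object.__setattr__(self, "df", df)
        object.__setattr__(self, "tracks_with_gaps", frozenset(gaps))

    @property
    def n_tracks(self) -> int:
        return int(self.df["track_id"].nunique())

    def track_lengths(self) -> pd.Series:
        return self.df.groupby("track_id").size()


@dataclass
class DwellTimeSample:
    """Residence-time sample (seconds) with right-censoring flags."""

    durations: np.ndarray
    censored: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.durations.size != self.censored.size:
            raise ParameterError("durations and censored flags differ in length")


@dataclass
class MobilityResult:
    threshold: float
    n_mobile: int
    n_immobile: int
    fraction_mobile: float
    fraction_immobile: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    status: str = "ok"


@dataclass
class DwellTimeFit:
    f_long: float
    tau_long: float
    tau_short: float
    n_events: int
    n_long_events: int
    n_short_events: int
    long_to_short_ratio: float
    threshold: float
    status: str = "ok"
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# filtering and per-track diffusion
# ---------------------------------------------------------------------------


def filter_tracks(
    tracks: TrajectorySet, min_points: int = 7
) -> tuple[TrajectorySet, int]:
    """Drop tracks with fewer than ``min_points`` localizations.

    Returns the filtered set and the number of removed tracks; input order is
    preserved.
    """
    sizes = tracks.track_lengths()
    keep = sizes[sizes >= min_points].index
    removed = int(tracks.n_tracks - keep.size)
    out = TrajectorySet(
        tracks.df[tracks.df["track_id"].isin(keep)].copy(),
        tracks.frame_interval,
        tracks.localization_error_prior,
    )
    return out, removed


def _msd_first_positions(frames, xy, n_positions=4, max_lag=3):
    """MSD per frame-lag from the first ``n_positions`` localizations."""
    frames = frames[:n_positions]
    xy = xy[:n_positions]
    msd = np.full(max_lag, np.nan)
    n_pairs = np.zeros(max_lag, dtype=int)
    for i in range(len(frames)):
        for j in range(i + 1, len(frames)):
            lag = int(frames[j] - frames[i])
            if 1 <= lag <= max_lag:
                sq = float(np.sum((xy[j] - xy[i]) ** 2))
                k = lag - 1
                if n_pairs[k] == 0:
                    msd[k] = sq
                else:
                    msd[k] = (msd[k] * n_pairs[k] + sq) / (n_pairs[k] + 1)
                n_pairs[k] += 1
    return msd, n_pairs


def track_diffusion(
    tracks: TrajectorySet, n_positions: int = 4, max_lag: int = 3,
    d_floor: float = D_FLOOR, loc_error: float | None = None,
) -> pd.DataFrame:
    """Per-track diffusion coefficient from the short-lag MSD.

    The first ``n_positions`` localizations of each track define MSD values
    at frame-lags 1..``max_lag``, fitted with ``MSD = 4 D (lag dt) + offset``
    where the offset absorbs static localization error (offset >= 0).  When
    the localization error is known (``loc_error`` argument or the trajectory
    set's prior), the offset is fixed at ``4 sigma^2`` and the slope is
    estimated through it with approximately inverse-variance weights
    ``n_pairs / lag^2``: with only three short-lag MSD points a free
    intercept makes the per-track slope extremely noisy.  Without a prior the
    intercept is fitted freely and clamped at zero.  Negative or zero slopes
    are floored at ``d_floor``.  Tracks with fewer than ``n_positions``
    usable points are skipped with a reason.
    """
    dt = tracks.frame_interval
    if loc_error is None:
        loc_error = tracks.localization_error_prior
    rows = []
    for tid, grp in tracks.df.groupby("track_id", sort=False):
        frames = grp["frame"].to_numpy()
        xy = grp[["x", "y"]].to_numpy()
        if len(frames) < n_positions:
            rows.append({"track_id": tid, "n_points": len(frames),
                         "skipped": "too_few_points"})
            continue
        msd, n_pairs = _msd_first_positions(frames, xy, n_positions, max_lag)
        ok = n_pairs > 0
        lags_t = (np.arange(1, max_lag + 1) * dt)[ok]
        y = msd[ok]
        if lags_t.size < 2:
            rows.append({"track_id": tid, "n_points": len(frames),
                         "skipped": "too_few_lags"})
            continue
        if loc_error is not None:
            offset = 4.0 * loc_error**2
            w = n_pairs[ok] / (np.arange(1, max_lag + 1)[ok]) ** 2
            slope = float(np.sum(w * lags_t * (y - offset))
                          / np.sum(w * lags_t**2))
            intercept = offset
        else:
            w = n_pairs[ok].astype(float)
            W = np.sqrt(w)
            A = np.vstack([lags_t * W, W]).T
            slope, intercept = np.linalg.lstsq(A, y * W, rcond=None)[0]
            if intercept < 0:  # refit through the origin: offset >= 0
                slope = float(np.sum(w * lags_t * y) / np.sum(w * lags_t**2))
                intercept = 0.0
        D = max(slope / 4.0, d_floor)
        flags = []
        if slope <= 0:
            flags.append("floored")
        # positive curvature across the three lags suggests directed motion
        if np.all(ok) and msd[2] - 2 * msd[1] + msd[0] > 0.5 * max(msd[0], 1e-12):
            flags.append("superdiffusive")
        row = {"track_id": tid, "n_points": int(len(frames)),
               "D": float(D), "logD": float(np.log10(D)),
               "offset": float(intercept), "skipped": "",
               "flags": ";".join(flags)}
        for k in range(max_lag):
            row[f"msd_lag{k + 1}"] = float(msd[k]) if n_pairs[k] else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mobility classification
# ---------------------------------------------------------------------------


def classify_mobility(
    diffusion: pd.DataFrame,
    logd_threshold: float = -0.5,
    bins: int = 60,
    hist_range: tuple[float, float] = (-4.0, 2.0),
) -> MobilityResult:
    """Mobile/immobile fractions from per-track log10 diffusion coefficients."""
    if "logD" not in diffusion.columns or diffusion.empty:
        return MobilityResult(logd_threshold, 0, 0, float("nan"), float("nan"),
                              np.zeros(bins), np.linspace(*hist_range, bins + 1),
                              status="empty")
    logd = diffusion["logD"].dropna().to_numpy()
    if logd.size == 0:
        return MobilityResult(logd_threshold, 0, 0, float("nan"), float("nan"),
                              np.zeros(bins), np.linspace(*hist_range, bins + 1),
                              status="empty")
    n_mobile = int(np.sum(logd > logd_threshold))
    n_immobile = int(logd.size - n_mobile)
    counts, edges = np.histogram(logd, bins=bins, range=hist_range)
    return MobilityResult(
        threshold=logd_threshold,
        n_mobile=n_mobile,
        n_immobile=n_immobile,
        fraction_mobile=n_mobile / logd.size,
        fraction_immobile=n_immobile / logd.size,
        hist_counts=counts,
        hist_edges=edges,
    )


def find_inflection_threshold(
    hist_counts: np.ndarray,
    hist_edges: np.ndarray,
    fallback: float = -0.5,
    smooth_sigma_bins: float = 2.0,
) -> tuple[float, bool]:
    """Antimode between the two largest modes of a smoothed logD histogram.

    Returns ``(threshold, used_fallback)``.  A unimodal profile falls back to
    the configured threshold with a flag.
    """
    counts = np.asarray(hist_counts, dtype=float)
    if counts.size < 10:
        raise ParameterError("histogram needs at least 10 bins")
    centers = 0.5 * (np.asarray(hist_edges)[:-1] + np.asarray(hist_edges)[1:])
    smooth = gaussian_filter1d(counts, smooth_sigma_bins)
    peaks, props = find_peaks(smooth, prominence=0.05 * smooth.max())
    if peaks.size < 2:
        return fallback, True
    order = np.argsort(props["prominences"])[::-1]
    p1, p2 = sorted(peaks[order[:2]])
    valley = p1 + int(np.argmin(smooth[p1 : p2 + 1]))
    return float(centers[valley]), False


# ---------------------------------------------------------------------------
# jump-length mixture model
# ---------------------------------------------------------------------------


def jump_length_pdf(
    r: np.ndarray, D: float, sigma: float, delta_t: float
) -> np.ndarray:
    """Displacement-magnitude PDF for 2D Brownian motion observed with
    localization error ``sigma`` (per localization): a Rayleigh density with
    per-axis variance ``2 (D dt + sigma^2)``."""
    s2 = 2.0 * (D * delta_t + sigma**2)
    return (r / s2) * np.exp(-(r**2) / (2.0 * s2))


def collect_displacements(
    tracks: TrajectorySet, max_lags: int = 4
) -> dict[int, np.ndarray]:
    """Displacement magnitudes per frame-lag 1..max_lags.

    Pairs spanning blink gaps are excluded: only localizations exactly
    ``lag`` frames apart contribute at that lag.
    """
    out: dict[int, list] = {lag: [] for lag in range(1, max_lags + 1)}
    for _, grp in tracks.df.groupby("track_id", sort=False):
        frames = grp["frame"].to_numpy()
        xy = grp[["x", "y"]].to_numpy()
        idx = {int(f): i for i, f in enumerate(frames)}
        for lag in range(1, max_lags + 1):
            for f, i in idx.items():
                j = idx.get(f + lag)
                if j is not None:
                    out[lag].append(float(np.hypot(*(xy[j] - xy[i]))))
    return {lag: np.asarray(v) for lag, v in out.items() if len(v)}


class JumpLengthMixture(BaseEstimator):
    """Kinetic mixture model fitted to binned displacement histograms.

    Displacement histograms at lag times dt, 2dt, ... are jointly fitted with

        p(r | dt) = sum_s f_s * r / (2 (D_s dt + sigma^2))
                     * exp(-r^2 / (4 (D_s dt + sigma^2)))

    by least squares on the binned PDFs, with multi-start initialization over
    log-spaced diffusion coefficients.  ``sigma`` (localization error, um) is
    fitted unless fixed.  Fitted attributes: ``D_states_`` (ascending),
    ``fractions_``, ``sigma_``, ``loss_``, ``delta_ts_used_``.
    """

    def __init__(
        self,
        n_states: int = 2,
        sigma: float | None = None,
        max_lags: int = 4,
        n_bins: int = 80,
        bin_range: tuple[float, float] = (0.002, 1.0),
        d_bounds: tuple[float, float] = (1e-4, 10.0),
        n_starts: int = 6,
    ) -> None:
        self.n_states = n_states
        self.sigma = sigma
        self.max_lags = max_lags
        self.n_bins = n_bins
        self.bin_range = bin_range
        self.d_bounds = d_bounds
        self.n_starts = n_starts

    # stick-breaking: q in [0,1]^(k-1) -> fractions summing to 1
    @staticmethod
    def _fractions(q: np.ndarray) -> np.ndarray:
        fr = []
        rest = 1.0
        for qi in q:
            fr.append(rest * qi)
            rest *= 1.0 - qi
        fr.append(rest)
        return np.asarray(fr)

    def _model(self, params, r, delta_t):
        k = self.n_states
        logD = params[:k]
        q = params[k : 2 * k - 1]
        sigma = self.sigma if self.sigma is not None else params[-1]
        fr = self._fractions(q)
        D = 10.0**logD
        out = np.zeros_like(r)
        for f_s, D_s in zip(fr, D):
            out += f_s * jump_length_pdf(r, D_s, sigma, delta_t)
        return out

    def fit(self, displacements: dict[int, np.ndarray], frame_interval: float
            ) -> "JumpLengthMixture":
        """Fit the mixture to displacement magnitudes keyed by frame lag."""
        if not displacements:
            raise ParameterError("no displacements supplied")
        k = self.n_states
        if k not in (2, 3):
            raise ParameterError("n_states must be 2 or 3")
        edges = np.geomspace(*self.bin_range, self.n_bins + 1)
        centers = np.sqrt(edges[:-1] * edges[1:])
        widths = np.diff(edges)

        data = []  # (centers, density, weight, delta_t)
        self.delta_ts_used_ = []
        for lag in sorted(displacements):
            if lag > self.max_lags:
                continue
            r = displacements[lag]
            counts, _ = np.histogram(r, bins=edges)
            dens = counts / (max(r.size, 1) * widths)
            data.append((dens, float(r.size), lag * frame_interval))
            self.delta_ts_used_.append(lag * frame_interval)

        def residuals(params):
            res = []
            for dens, n, dtl in data:
                model = self._model(params, centers, dtl)
                res.append(np.sqrt(widths * n) * (model - dens))
            return np.concatenate(res)

        lo_d, hi_d = np.log10(self.d_bounds[0]), np.log10(self.d_bounds[1])
        lo = [lo_d] * k + [0.001] * (k - 1)
        hi = [hi_d] * k + [0.999] * (k - 1)
        if self.sigma is None:
            lo.append(0.0)
            hi.append(0.2)

        rng_starts = []
        grid = np.linspace(lo_d + 0.5, hi_d - 0.5, max(3, self.n_starts))
        if k == 2:
            combos = [(a, b) for a in grid for b in grid if a < b]
        else:
            combos = [(a, (a + b) / 2, b) for a in grid for b in grid if a < b - 1]
        step = max(1, len(combos) // max(1, 3 * self.n_starts))
        for combo in combos[::step]:
            x0 = list(combo) + [1.0 / k] * (k - 1)
            if self.sigma is None:
                x0.append(0.03)
            rng_starts.append(np.clip(np.asarray(x0), lo, hi))

        best = None
        for x0 in rng_starts:
            try:
                res = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise FitError("jump-length mixture fit failed from every start")

        params = best.x
        D = 10.0 ** params[:k]
        fr = self._fractions(params[k : 2 * k - 1])
        order = np.argsort(D)
        self.D_states_ = D[order]
        self.fractions_ = fr[order]
        self.sigma_ = float(self.sigma if self.sigma is not None else params[-1])
        self.loss_ = float(best.cost)
        self.flags_ = tuple(
            ["degenerate_states"]
            if np.any(np.diff(np.log10(np.maximum(self.D_states_, 1e-12))) < 0.1)
            else []
        )
        return self

    def evaluate_loss(self, params_logD, fractions, sigma,
                      displacements, frame_interval) -> float:
        """Loss of an explicit parameter set on the same binned objective
        (used as an independent grid-search oracle in tests)."""
        k = self.n_states
        q = []
        rest = 1.0
        for f_s in fractions[:-1]:
            q.append(f_s / rest if rest > 0 else 0.0)
            rest -= f_s
        params = np.concatenate([params_logD, q, [] if self.sigma is not None
                                 else [sigma]])
        edges = np.geomspace(*self.bin_range, self.n_bins + 1)
        centers = np.sqrt(edges[:-1] * edges[1:])
        widths = np.diff(edges)
        total = 0.0
        for lag in sorted(displacements):
            if lag > self.max_lags:
                continue
            r = displacements[lag]
            counts, _ = np.histogram(r, bins=edges)
            dens = counts / (max(r.size, 1) * widths)
            model = self._model(params, centers, lag * frame_interval)
            total += 0.5 * float(np.sum(widths * r.size * (model - dens) ** 2))
        return total


def fit_jump_length_model(
    tracks: TrajectorySet,
    n_states: int = 2,
    max_lags: int = 4,
    min_displacements: int = 500,
    **kwargs,
) -> JumpLengthMixture:
    """Fit a 2- or 3-state jump-length kinetic model to a trajectory set."""
    disp = collect_displacements(tracks, max_lags=max_lags)
    n_total = sum(v.size for v in disp.values())
    if n_total < min_displacements:
        raise ParameterError(
            f"need >= {min_displacements} displacements, got {n_total}"
        )
    est = JumpLengthMixture(n_states=n_states, max_lags=max_lags, **kwargs)
    return est.fit(disp, tracks.frame_interval)


# ---------------------------------------------------------------------------
# dwell times
# ---------------------------------------------------------------------------


class DwellTimeMixture(BaseEstimator):
    """Two-exponential residence-time model fitted to the survival curve.

    The Kaplan-Meier estimator (censoring-aware) provides the empirical
    survival function; the model

        S(t) = f exp(-t / tau_long) + (1 - f) exp(-t / tau_short)

    is fitted to it by least squares on log-survival, weighted by the number
    of events at each time.  Fitted attributes: ``f_long_``, ``tau_long_``,
    ``tau_short_``, ``flags_``.
    """

    def __init__(self, n_starts: int = 6, tau_bounds: tuple[float, float] | None = None
                 ) -> None:
        self.n_starts = n_starts
        self.tau_bounds = tau_bounds

    def fit(self, durations: np.ndarray, censored: np.ndarray | None = None
            ) -> "DwellTimeMixture":
        durations = np.asarray(durations, dtype=float)
        if censored is None:
            censored = np.zeros(durations.size, dtype=bool)
        censored = np.asarray(censored, dtype=bool)
        kmf = KaplanMeierFitter()
        kmf.fit(durations, event_observed=~censored)
        sf = kmf.survival_function_
        t = sf.index.to_numpy(dtype=float)
        S = sf.iloc[:, 0].to_numpy(dtype=float)
        keep = (t > 0) & (S > 0)
        t, S = t[keep], S[keep]
        if t.size < 3:
            raise FitError("too few distinct event times for a survival fit")
        # weight by the number of events contributing at each time
        uniq, counts = np.unique(durations[~censored], return_counts=True)
        w = np.interp(t, uniq, counts, left=1.0, right=1.0)
        logS = np.log(S)

        lo_t, hi_t = self.tau_bounds or (t.min() / 10.0, t.max() * 10.0)

        def residuals(params):
            f, lt, ls = params
            model = f * np.exp(-t / lt) + (1 - f) * np.exp(-t / ls)
            return np.sqrt(w) * (np.log(np.maximum(model, 1e-300)) - logS)

        taus = np.geomspace(lo_t * 1.5, hi_t / 1.5, max(3, self.n_starts))
        best = None
        for i, ts_ in enumerate(taus):
            for tl in taus[i + 1 :]:
                try:
                    res = least_squares(
                        residuals, x0=[0.2, tl, ts_],
                        bounds=([0.0, lo_t, lo_t], [1.0, hi_t, hi_t]),
                    )
                except Exception:
                    continue
                if best is None or res.cost < best.cost:
                    best = res
        if best is None:
            raise FitError("dwell-time survival fit failed from every start")
        f, t1, t2 = best.x
        if t1 < t2:  # enforce tau_long > tau_short by ordering
            t1, t2, f = t2, t1, 1 - f
        flags = []
        if abs(np.log(t1 / max(t2, 1e-12))) < 0.1:
            flags.append("degenerate_single_exponential")
        self.f_long_ = float(f)
        self.tau_long_ = float(t1)
        self.tau_short_ = float(t2)
        self.loss_ = float(best.cost)
        self.flags_ = tuple(flags)
        return self


def _track_dwell_sample(tracks: TrajectorySet,
                        max_jump: float | None = None) -> DwellTimeSample:
    """Track lifetimes at the slow frame rate as residence-time durations.

    A track's duration is the frame span it was observed for; tracks still
    present in the movie's final frame are right-censored.  ``max_jump``
    optionally drops tracks that ever move farther than the slow-tracking
    confinement radius in one frame.
    """
    dt = tracks.frame_interval
    last_frame = int(tracks.df["frame"].max())
    durations, cens = [], []
    for _, grp in tracks.df.groupby("track_id", sort=False):
        frames = grp["frame"].to_numpy()
        if max_jump is not None:
            xy = grp[["x", "y"]].to_numpy()
            steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
            d = np.diff(frames)
            if np.any(steps / np.maximum(d, 1) > max_jump):
                continue
        durations.append((frames[-1] - frames[0] + 1) * dt)
        cens.append(frames[-1] >= last_frame)
    return DwellTimeSample(np.asarray(durations), np.asarray(cens, dtype=bool), dt)


def dwell_time_analysis(
    data: TrajectorySet | DwellTimeSample,
    threshold: float = 1.0,
    min_events: int = 50,
    max_jump: float | None = None,
    bleach_correction_factor: float | None = None,
) -> DwellTimeFit:
    """Dwell-time survival analysis with long/short event counting.

    Events longer than ``threshold`` seconds count as long dwells, the rest
    as short dwells; ``long_to_short_ratio`` is their count ratio.  With fewer
    than ``min_events`` events the fit is refused but the counts are still
    reported.  ``bleach_correction_factor`` optionally divides the fitted
    long residence rate to compensate photobleaching when an independent
    calibration is available (no default is assumed).
    """
    sample = (
        data if isinstance(data, DwellTimeSample)
        else _track_dwell_sample(data, max_jump=max_jump)
    )
    durations, censored = sample.durations, sample.censored
    n = int(durations.size)
    n_long = int(np.sum(durations > threshold))
    n_short = n - n_long
    if threshold <= 0 or n_short == 0:
        ratio, ratio_status = float("nan"), "ratio_undefined"
    else:
        ratio, ratio_status = n_long / n_short, "ok"

    flags: list[str] = []
    if n < min_events:
        return DwellTimeFit(
            f_long=float("nan"), tau_long=float("nan"), tau_short=float("nan"),
            n_events=n, n_long_events=n_long, n_short_events=n_short,
            long_to_short_ratio=ratio, threshold=threshold,
            status="fit_refused_too_few_events", flags=("fit_refused",),
        )
    frac_censored = float(np.mean(censored)) if n else 0.0
    if frac_censored > 0.8 or np.unique(durations[~censored]).size < 5:
        flags.append("unreliable_censoring")
    try:
        est = DwellTimeMixture().fit(durations, censored)
        f_long, tau_long, tau_short = est.f_long_, est.tau_long_, est.tau_short_
        flags.extend(est.flags_)
        status = "ok" if ratio_status == "ok" else ratio_status
    except FitError:
        f_long = tau_long = tau_short = float("nan")
        flags.append("fit_failed")
        status = ratio_status if ratio_status != "ok" else "fit_failed"
    if bleach_correction_factor is not None and np.isfinite(tau_long):
        tau_long = tau_long / bleach_correction_factor
        flags.append("bleach_corrected")
    return DwellTimeFit(
        f_long=f_long, tau_long=tau_long, tau_short=tau_short,
        n_events=n, n_long_events=n_long, n_short_events=n_short,
        long_to_short_ratio=ratio, threshold=threshold,
        status=status, flags=tuple(flags),
    )
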