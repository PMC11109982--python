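"""FRAP curve normalization, quality control and recovery-model fitting.

The workflow mirrors standard confocal FRAP practice on biomolecular
condensates: three regions of interest are recorded over time -- the bleached
droplet (``bleach``), a whole-cell reference (``reference``) and an
extracellular background (``background``).  Background-corrected intensities
are normalized (simple or double normalization), gated by quality-control
criteria (bleach efficacy, gap ratio, goodness of fit), and the post-bleach
recovery is fitted with a one- or two-component exponential model

    f(t) = f0 + a (1 - exp(-b t)) [+ c (1 - exp(-d t))]

from which the half-time of recovery ``t_half`` and the mobile fraction
``(plateau - f0) / (1 - f0)`` are extracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, brentq
from sklearn.base import BaseEstimator

from .errors import FitError, NormalizationError, ParameterError

__all__ = [
    "FrapTrace",
    "FrapNormalized",
    "FrapQc",
    "FrapFit",
    "FrapRecoveryModel",
    "normalize_simple",
    "normalize_double",
    "compute_qc",
    "fit_recovery",
    "extract_kinetics",
    "frap_batch",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class FrapTrace:
    """Raw three-ROI FRAP time series.

    ``time`` is the acquisition time of every frame in seconds (strictly
    increasing).  The first ``n_prebleach`` frames precede the bleach pulse;
    ``bleach_frame_span`` frames acquired during the pulse itself (if any)
    follow and are excluded from normalization and fitting.
    """

    time: np.ndarray
    bleach: np.ndarray
    reference: np.ndarray
    background: np.ndarray
    n_prebleach: int
    bleach_frame_span: int = 0
    condition: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.bleach = np.asarray(self.bleach, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        n = self.time.size
        for name in ("bleach", "reference", "background"):
            if getattr(self, name).size != n:
                raise ParameterError(f"series '{name}' length differs from time axis")
        if n < self.n_prebleach + 2:
            raise ParameterError("trace needs at least two post-bleach frames")
        if self.n_prebleach < 1:
            raise ParameterError("at least one pre-bleach frame required")
        if np.any(np.diff(self.time) <= 0):
            raise ParameterError("time must be strictly increasing")

    @property
    def post_start(self) -> int:
        return self.n_prebleach + self.bleach_frame_span

    @property
    def n_post(self) -> int:
        return self.time.size - self.post_start


@dataclass
class FrapNormalized:
    """Normalized FRAP trace (pre-bleach mean is 1 in both modes)."""

    time_post: np.ndarray  # seconds since first post-bleach frame
    f_post: np.ndarray
    f_pre: np.ndarray
    normalization_mode: str  # "simple" | "double"


@dataclass
class FrapQc:
    """Per-gate quality control record.

    ``r_squared`` is filled after fitting; until then the r-squared gate is
    reported as ``None`` (pending) and ``passed`` treats it as failing only
    when a value is available and below threshold.
    """

    bleach_efficacy: float
    gap_ratio: float
    r_squared: float | None = None
    efficacy_threshold: float = 0.60
    gap_threshold: float = 0.60
    r2_threshold: float = 0.70

    @property
    def gates(self) -> dict[str, bool | None]:
        return {
            "bleach_efficacy": bool(self.bleach_efficacy > self.efficacy_threshold),
            "gap_ratio": bool(self.gap_ratio > self.gap_threshold),
            "r_squared": None
            if self.r_squared is None
            else bool(self.r_squared > self.r2_threshold),
        }

    @property
    def passed(self) -> bool:
        return all(v is not False for v in self.gates.values()) and (
            self.r_squared is not None
        )

    @property
    def failure_reasons(self) -> list[str]:
        return [k for k, v in self.gates.items() if v is False]


@dataclass
class FrapFit:
    """Fitted recovery model and derived kinetic quantities."""

    model: str  # "one_component" | "two_component"
    f0: float
    a: float
    b: float
    c: float  # 0 for one-component
    d: float  # nan for one-component
    plateau: float
    mobile_fraction: float
    t_half: float
    r_squared: float
    mobile_fraction_sd: float = float("nan")
    t_half_sd: float = float("nan")
    covariance: np.ndarray | None = None
    flags: tuple[str, ...] = ()

    def as_record(self) -> dict:
        rec = asdict(self)
        rec.pop("covariance")
        rec["flags"] = ";".join(self.flags)
        return rec


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def _corrected(trace: FrapTrace) -> tuple[np.ndarray, np.ndarray]:
    bl = trace.bleach - trace.background
    ref = trace.reference - trace.background
    bad = np.nonzero(ref <= 0)[0]
    if bad.size:
        raise NormalizationError(
            f"corrected reference non-positive at frame {int(bad[0])}"
        )
    return bl, ref


def _assemble(trace: FrapTrace, f: np.ndarray, mode: str) -> FrapNormalized:
    pre = f[: trace.n_prebleach]
    post = f[trace.post_start :]
    t_post = trace.time[trace.post_start :] - trace.time[trace.post_start]
    return FrapNormalized(
        time_post=t_post, f_post=post, f_pre=pre, normalization_mode=mode
    )


def normalize_simple(trace: FrapTrace) -> FrapNormalized:
    """Background-corrected ratio normalization.

    f(t) = ((BL - BG) / (REF - BG)) / mean_pre((BL - BG) / (REF - BG))
    """
    bl, ref = _corrected(trace)
    ratio = bl / ref
    pre_mean = float(np.mean(ratio[: trace.n_prebleach]))
    if pre_mean <= 0:
        raise NormalizationError("pre-bleach corrected ratio mean is non-positive")
    return _assemble(trace, ratio / pre_mean, "simple")


def normalize_double(trace: FrapTrace) -> FrapNormalized:
    """Double normalization (easyFRAP convention).

    f(t) = [mean_pre(REF - BG) / (REF(t) - BG(t))]
         * [(BL(t) - BG(t)) / mean_pre(BL - BG)]

    Corrects the bleach-ROI signal for whole-cell acquisition photobleaching
    through the time-varying reference, then scales to the pre-bleach mean.
    """
    bl, ref = _corrected(trace)
    pre = slice(0, trace.n_prebleach)
    ref_pre = float(np.mean(ref[pre]))
    bl_pre = float(np.mean(bl[pre]))
    if bl_pre <= 0:
        raise NormalizationError("pre-bleach corrected bleach mean is non-positive")
    f = (ref_pre / ref) * (bl / bl_pre)
    return _assemble(trace, f, "double")


def compute_qc(
    trace: FrapTrace,
    norm: FrapNormalized,
    *,
    gap_frames: int = 1,
    efficacy_threshold: float = 0.60,
    gap_threshold: float = 0.60,
    r2_threshold: float = 0.70,
) -> FrapQc:
    """Bleach efficacy and gap ratio gates.

    * bleach efficacy: ``1 - f(first post-bleach frame)`` -- how deeply the
      target region was bleached.
    * gap ratio: corrected whole-cell intensity over the first ``gap_frames``
      post-bleach frames relative to its pre-bleach mean -- how much total
      fluorescence the bleach pulse destroyed.
    """
    _, ref = _corrected(trace)
    pre_mean = float(np.mean(ref[: trace.n_prebleach]))
    k = max(1, int(gap_frames))
    post = ref[trace.post_start : trace.post_start + k]
    gap_ratio = float(np.mean(post) / pre_mean)
    efficacy = float(1.0 - norm.f_post[0])
    return FrapQc(
        bleach_efficacy=efficacy,
        gap_ratio=gap_ratio,
        efficacy_threshold=efficacy_threshold,
        gap_threshold=gap_threshold,
        r2_threshold=r2_threshold,
    )


# ---------------------------------------------------------------------------
# recovery model
# ---------------------------------------------------------------------------


def _model_one(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    # parameterized by (f0, plateau, rate) so the plateau can be bounded
    f0, plateau, b = params
    return f0 + (plateau - f0) * (1.0 - np.exp(-b * t))


def _model_two(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    # (f0, plateau, split w, rate b, rate d)
    f0, plateau, w, b, d = params
    rec = w * (1.0 - np.exp(-b * t)) + (1.0 - w) * (1.0 - np.exp(-d * t))
    return f0 + (plateau - f0) * rec


class FrapRecoveryModel(BaseEstimator):
    """Least-squares exponential recovery fit with multi-start initialization.

    Parameters
    ----------
    model:
        ``"one_component"`` fits ``f0 + a(1-e^{-bt})``; ``"two_component"``
        adds a second term ``c(1-e^{-dt})``.  Two-exponential fits are
        multimodal, hence rates are initialized from a log-spaced grid and the
        best of all starts is kept.
    rate_bounds:
        Bounds for the rate constants in 1/s.  By default the lower bound is
        ``max(1e-4, 1 / t_span)``: a recovery component with a time constant
        longer than the observation window is not identifiable and, left
        free, absorbs tail noise into an inflated plateau.
    degeneracy_rtol:
        When a two-component fit converges with nearly equal rates the model
        is collapsed to one component and flagged ``degenerate_rates``.

    Fitted attributes (set by :meth:`fit`): ``f0_``, ``a_``, ``b_``, ``c_``,
    ``d_``, ``plateau_``, ``mobile_fraction_``, ``t_half_``, ``r_squared_``,
    ``covariance_``, ``mobile_fraction_sd_``, ``t_half_sd_``, ``flags_``.
    """

    def __init__(
        self,
        model: str = "two_component",
        n_starts: int = 6,
        rate_bounds: tuple[float, float] | None = None,
        degeneracy_rtol: float = 0.05,
    ) -> None:
        self.model = model
        self.n_starts = n_starts
        self.rate_bounds = rate_bounds
        self.degeneracy_rtol = degeneracy_rtol

    # -- internals ---------------------------------------------------------

    def _fit_once(self, t, f, x0, bounds):
        fun = _model_one if len(x0) == 3 else _model_two
        res = least_squares(
            lambda p: fun(p, t) - f, x0=x0, bounds=bounds, method="trf",
            x_scale="jac", xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        return res

    def _rate_bounds(self, t):
        if self.rate_bounds is not None:
            return self.rate_bounds
        t_span = float(t[-1] - t[0]) if t[-1] > t[0] else 1.0
        return (max(1e-4, 1.0 / t_span), 10.0)

    def _starts(self, t, f):
        lo, hi = self._rate_bounds(t)
        f0 = float(f[0])
        plateau = float(np.mean(f[max(1, int(0.9 * f.size)) :]))
        plateau = min(max(plateau, f0 + 1e-3), 1.04)
        t_span = t[-1] - t[0] if t[-1] > t[0] else 1.0
        rates = np.geomspace(
            max(lo * 1.01, 0.2 / t_span / 10), min(hi * 0.99, 50.0 / t_span),
            max(3, self.n_starts),
        )
        if self.model == "one_component":
            for r in rates:
                yield np.array([f0, plateau, r])
        else:
            pairs = [(rates[i], rates[j]) for i in range(len(rates))
                     for j in range(i + 1, len(rates))]
            step = max(1, len(pairs) // max(1, 2 * self.n_starts))
            for rb, rd in pairs[::step]:
                yield np.array([f0, plateau, 0.5, rd, rb])

    # -- public API --------------------------------------------------------

    def fit(self, t: np.ndarray, f: np.ndarray) -> "FrapRecoveryModel":
        """Fit the recovery model to a normalized post-bleach curve.

        ``t`` is measured from the first post-bleach frame (t[0] == 0).
        """
        t = np.asarray(t, dtype=float)
        f = np.asarray(f, dtype=float)
        if t.size != f.size:
            raise ParameterError("t and f must have equal length")
        if t.size < 8:
            raise ParameterError("at least 8 post-bleach frames required for fitting")
        if self.model not in ("one_component", "two_component"):
            raise ParameterError(f"unknown model '{self.model}'")

        lo, hi = self._rate_bounds(t)
        # plateau bounded at 1.05: a normalized recovery cannot exceed the
        # pre-bleach level (small overshoot tolerated, mirroring the mobile
        # fraction invariant)
        if self.model == "one_component":
            bounds = ([-0.5, 0.0, lo], [1.0, 1.05, hi])
        else:
            bounds = ([-0.5, 0.0, 0.0, lo, lo], [1.0, 1.05, 1.0, hi, hi])

        best = None
        diagnostics = []
        for x0 in self._starts(t, f):
            x0 = np.clip(x0, bounds[0], bounds[1])
            try:
                res = self._fit_once(t, f, x0, bounds)
            except Exception as exc:  # pragma: no cover - defensive
                diagnostics.append(str(exc))
                continue
            if not np.all(np.isfinite(res.x)):
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise FitError(f"recovery fit failed from every start: {diagnostics}")

        flags: list[str] = []
        params = best.x
        model_used = self.model
        if self.model == "two_component":
            b, d = params[3], params[4]
            if abs(np.log(b / d)) < self.degeneracy_rtol:
                warnings.warn(
                    "two-component rates degenerate; collapsing to one component",
                    stacklevel=2,
                )
                flags.append("degenerate_rates")
                one = FrapRecoveryModel(
                    model="one_component",
                    n_starts=self.n_starts,
                    rate_bounds=self.rate_bounds,
                ).fit(t, f)
                params = np.array([one.f0_, one.plateau_, one.b_])
                model_used = "one_component"
                best = None

        self.model_used_ = model_used
        if model_used == "one_component":
            self.f0_, self.plateau_, self.b_ = map(float, params)
            self.a_ = self.plateau_ - self.f0_
            self.c_, self.d_ = 0.0, float("nan")
            predict = lambda tt: _model_one(params, tt)  # noqa: E731
        else:
            self.f0_, self.plateau_, w, self.b_, self.d_ = map(float, params)
            amp = self.plateau_ - self.f0_
            self.a_ = amp * w
            self.c_ = amp * (1.0 - w)
            predict = lambda tt: _model_two(params, tt)  # noqa: E731
        self._params_ = params
        self._predict = predict

        resid = predict(t) - f
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((f - f.mean()) ** 2))
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

        # covariance of the fitted parameters from the Jacobian at the optimum
        self.covariance_ = self._covariance(t, f, params)

        mf = (self.plateau_ - self.f0_) / (1.0 - self.f0_) if self.f0_ < 1 else 0.0
        if self.plateau_ <= self.f0_:
            mf = 0.0
            flags.append("degenerate_fit")
        if mf > 1.05:
            flags.append("mobile_fraction_overshoot")
        self.mobile_fraction_ = float(mf)
        self.t_half_ = self._t_half(params, model_used)
        self.mobile_fraction_sd_, self.t_half_sd_ = self._propagate(params, model_used)
        self.flags_ = tuple(flags)
        self.n_points_ = int(t.size)
        return self

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self._predict(np.asarray(t, dtype=float))

    # -- derived quantities --------------------------------------------------

    @staticmethod
    def _t_half(params: np.ndarray, model: str) -> float:
        if model == "one_component":
            return float(np.log(2.0) / params[2])
        _, _, w, b, d = params

        def g(tt):
            return w * (1 - np.exp(-b * tt)) + (1 - w) * (1 - np.exp(-d * tt)) - 0.5

        hi = 10.0 * max(1.0 / b, 1.0 / d)
        while g(hi) < 0:  # ensure bracket
            hi *= 2
            if hi > 1e9:
                return float("nan")
        return float(brentq(g, 1e-12, hi, xtol=1e-12, rtol=1e-14))

    def _covariance(self, t, f, params) -> np.ndarray | None:
        fun = _model_one if params.size == 3 else _model_two
        eps = 1e-7
        J = np.empty((t.size, params.size))
        for j in range(params.size):
            dp = np.zeros_like(params)
            h = eps * max(abs(params[j]), 1.0)
            dp[j] = h
            J[:, j] = (fun(params + dp, t) - fun(params - dp, t)) / (2 * h)
        resid = fun(params, t) - f
        dof = max(t.size - params.size, 1)
        s2 = float(np.sum(resid**2)) / dof
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
        except np.linalg.LinAlgError:
            return None
        return cov

    def _propagate(self, params, model) -> tuple[float, float]:
        """Delta-method standard deviations for mobile fraction and t_half."""
        cov = self.covariance_
        if cov is None:
            return float("nan"), float("nan")

        def both(p):
            f0, plateau = p[0], p[1]
            mf = (plateau - f0) / (1 - f0) if f0 < 1 else 0.0
            th = self._t_half(np.asarray(p, dtype=float), model)
            return np.array([mf, th])

        eps = 1e-6
        G = np.empty((2, params.size))
        for j in range(params.size):
            dp = np.zeros_like(params)
            h = eps * max(abs(params[j]), 1.0)
            dp[j] = h
            G[:, j] = (both(params + dp) - both(params - dp)) / (2 * h)
        var = np.einsum("ij,jk,ik->i", G, cov, G)
        var = np.clip(var, 0, None)
        return float(np.sqrt(var[0])), float(np.sqrt(var[1]))

    def to_fit(self) -> FrapFit:
        return FrapFit(
            model=self.model_used_,
            f0=self.f0_,
            a=self.a_,
            b=self.b_,
            c=self.c_,
            d=self.d_,
            plateau=self.plateau_,
            mobile_fraction=self.mobile_fraction_,
            t_half=self.t_half_,
            r_squared=self.r_squared_,
            mobile_fraction_sd=self.mobile_fraction_sd_,
            t_half_sd=self.t_half_sd_,
            covariance=self.covariance_,
            flags=self.flags_,
        )


def fit_recovery(
    norm: FrapNormalized, model: str = "two_component", **kwargs
) -> FrapFit:
    """Fit the exponential recovery model to a normalized trace."""
    est = FrapRecoveryModel(model=model, **kwargs)
    est.fit(norm.time_post, norm.f_post)
    return est.to_fit()


def extract_kinetics(fit: FrapFit) -> tuple[float, float]:
    """Return ``(t_half, mobile_fraction)`` from a fitted recovery model."""
    return fit.t_half, fit.mobile_fraction


# ---------------------------------------------------------------------------
# batch analysis
# ---------------------------------------------------------------------------


def frap_batch(
    traces: Sequence[FrapTrace],
    *,
    normalization: str = "double",
    model: str = "two_component",
    gap_frames: int = 1,
    efficacy_threshold: float = 0.60,
    gap_threshold: float = 0.60,
    r2_threshold: float = 0.70,
) -> dict:
    """Normalize, QC-gate and fit a collection of FRAP traces.

    Returns a dict with ``fits`` (per-trace DataFrame including QC columns and
    exclusion reasons), ``summary`` (per-condition mean +/- SEM of t_half and
    mobile fraction over QC-passing traces) and ``mean_curves`` (per-condition
    mean normalized recovery).
    """
    if len(traces) == 0:
        raise ParameterError("at least one trace required")
    norm_fun = {"simple": normalize_simple, "double": normalize_double}.get(
        normalization
    )
    if norm_fun is None:
        raise ParameterError(f"unknown normalization '{normalization}'")

    rows = []
    curves: dict[str, list[FrapNormalized]] = {}
    for i, trace in enumerate(traces):
        row: dict = {"trace": i, "condition": trace.condition}
        try:
            norm = norm_fun(trace)
            qc = compute_qc(
                trace,
                norm,
                gap_frames=gap_frames,
                efficacy_threshold=efficacy_threshold,
                gap_threshold=gap_threshold,
                r2_threshold=r2_threshold,
            )
            fit = fit_recovery(norm, model=model)
            qc.r_squared = fit.r_squared
            row.update(fit.as_record())
            row["bleach_efficacy"] = qc.bleach_efficacy
            row["gap_ratio"] = qc.gap_ratio
            row["qc_pass"] = qc.passed
            row["qc_reasons"] = ";".join(qc.failure_reasons)
            if qc.passed:
                curves.setdefault(trace.condition, []).append(norm)
        except (NormalizationError, FitError, ParameterError) as exc:
            row["qc_pass"] = False
            row["qc_reasons"] = f"error:{exc}"
        rows.append(row)

    fits = pd.DataFrame(rows)
    passing = fits[fits["qc_pass"] == True]  # noqa: E712
    if passing.empty:
        summary = pd.DataFrame(
            columns=["condition", "n", "t_half_mean", "t_half_sem",
                     "mobile_mean", "mobile_sem"]
        )
        status = "empty"
    else:
        g = passing.groupby("condition")
        summary = pd.DataFrame(
            {
                "n": g.size(),
                "t_half_mean": g["t_half"].mean(),
                "t_half_sem": g["t_half"].sem(ddof=1).fillna(0.0),
                "mobile_mean": g["mobile_fraction"].mean(),
                "mobile_sem": g["mobile_fraction"].sem(ddof=1).fillna(0.0),
            }
        ).reset_index()
        status = "ok"

    mean_curves = {}
    for cond, norms in curves.items():
        n_min = min(n.f_post.size for n in norms)
        stack = np.vstack([n.f_post[:n_min] for n in norms])
        mean_curves[cond] = pd.DataFrame(
            {
                "time_post": norms[0].time_post[:n_min],
                "f_mean": stack.mean(axis=0),
                "f_sem": stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
                if stack.shape[0] > 1
                else np.zeros(n_min),
            }
        )
    return {"fits": fits, "summary": summary, "mean_curves": mean_curves,
            "status": status}
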