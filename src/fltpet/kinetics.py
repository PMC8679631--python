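"""Reversible two-tissue-compartment (2TCM) kinetics for dynamic FLT PET.

The model has a free (exchangeable) tissue compartment C1 and a trapped
(phosphorylated) compartment C2 driven by the plasma parent input Cp:

    dC1/dt = K1*Cp - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2
    C_T(t) = (1 - Vb)*(C1 + C2) + Vb*Cb(t)

with delivery K1 (mL/min/g), efflux k2, phosphorylation k3, release k4
(all 1/min) and fractional blood volume Vb.  The net influx constant is
Ki = K1*k3/(k2 + k3).

The forward model is evaluated analytically: the tissue impulse response
is a bi-exponential with eigenrates

    alpha_{1,2} = [(k2 + k3 + k4) -/+ sqrt((k2 + k3 + k4)^2 - 4 k2 k4)] / 2

and the convolution with a piecewise-linear Cp is computed exactly per
grid interval via a first-order recursive filter, which is both faster
and more accurate than generic quadrature.

Fitting is bounded weighted least squares with a seeded Latin-hypercube
multistart, exposed as a scikit-learn style estimator
(:class:`TwoTissueFitter`) plus the thin functional wrapper
:func:`fit_2tcm`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import lfilter
from scipy.stats import qmc, wilcoxon
from sklearn.base import BaseEstimator, RegressorMixin

from .core import FrameSchedule, TimeActivityCurve
from .errors import (
    FitFailureError,
    InvalidConfigError,
    PairingError,
    RangeError,
)
from .input_function import ArterialInputFunction

__all__ = [
    "TwoTissueParams",
    "FitConfig",
    "FitResult",
    "TwoTissueFitter",
    "model_tac",
    "frame_average",
    "fit_2tcm",
    "ki",
    "kinetic_cohort_summary",
]

PARAM_NAMES = ("K1", "k2", "k3", "k4", "vb")

#: default box bounds for (K1, k2, k3, k4, Vb)
DEFAULT_BOUNDS = ((0.0, 2.0), (0.0, 2.0), (0.0, 1.0), (0.0, 0.5), (0.0, 0.5))


@dataclass(frozen=True)
class TwoTissueParams:
    """Rate constants of one lesion. K1 in mL/min/g, k2-k4 in 1/min, Vb a fraction."""

    K1: float
    k2: float
    k3: float
    k4: float = 0.0
    vb: float = 0.0

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.k2 < 0 or self.k3 < 0 or self.k4 < 0:
            raise InvalidConfigError("rate constants must be >= 0")
        if not (0.0 <= self.vb < 1.0):
            raise InvalidConfigError("Vb must lie in [0, 1)")

    @property
    def ki(self) -> float:
        """Net influx constant Ki = K1*k3/(k2+k3); 0 when k2+k3 = 0."""
        denom = self.k2 + self.k3
        return 0.0 if denom == 0.0 else self.K1 * self.k3 / denom

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.k2, self.k3, self.k4, self.vb])


def ki(params: TwoTissueParams) -> float:
    """Net influx (metabolic flux) constant, mL/min/g."""
    return params.ki


def _exp_conv(x: np.ndarray, alpha: float, dt: float) -> np.ndarray:
    """Exact convolution of a piecewise-linear signal with exp(-alpha*t).

    Returns y(t_i) = int_0^{t_i} exp(-alpha*(t_i - s)) x(s) ds on the
    uniform grid t_i = i*dt, assuming x is linear between samples.
    Implemented as the recursion y_{i+1} = E y_i + b0 x_{i+1} + b1 x_i
    with exact segment integrals, evaluated by scipy.signal.lfilter.
    """
    ad = alpha * dt
    if abs(ad) < 1e-8:
        i0, j1 = dt, dt * dt / 2.0
        E = 1.0 - ad
    else:
        E = np.exp(-ad)
        i0 = -np.expm1(-ad) / alpha          # int_0^dt e^{-a v} dv
        j1 = (1.0 - E * (1.0 + ad)) / (alpha * alpha)  # int_0^dt v e^{-a v} dv
    b1 = j1 / dt                 # weight of the left sample
    b0 = i0 - b1                 # weight of the right sample
    y = lfilter([b0, b1], [1.0, -E], x)
    if x[0] != 0.0:
        # enforce y(0) = 0: remove the filter's spurious initial response
        y = y - (b0 * x[0]) * E ** np.arange(x.size)
    else:
        y[0] = 0.0
    return y


def _eigenrates(k2: float, k3: float, k4: float) -> tuple:
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    sq = np.sqrt(max(disc, 0.0))
    sq = max(sq, 1e-9)  # guard the repeated-eigenvalue measure-zero case
    return (s - sq) / 2.0, (s + sq) / 2.0


def model_on_grid(params: TwoTissueParams, dt: float,
                  cp: np.ndarray, cb: np.ndarray | None = None) -> np.ndarray:
    """Total tissue concentration C_T on a uniform grid of spacing dt.

    ``cp`` is the plasma-parent input sampled on the grid; ``cb`` the
    whole-blood curve (required when Vb > 0).
    """
    a1, a2 = _eigenrates(params.k2, params.k3, params.k4)
    # C1+C2 impulse response: K1/(a2-a1) [(k3+k4-a1) e^{-a1 t} + (a2-k3-k4) e^{-a2 t}]
    w = params.K1 / (a2 - a1)
    tissue = w * ((params.k3 + params.k4 - a1) * _exp_conv(cp, a1, dt)
                  + (a2 - params.k3 - params.k4) * _exp_conv(cp, a2, dt))
    if params.vb > 0.0:
        if cb is None:
            raise InvalidConfigError("whole-blood curve required when Vb > 0")
        return (1.0 - params.vb) * tissue + params.vb * cb
    return tissue


def model_tac(params: TwoTissueParams, aif: ArterialInputFunction, times,
              dt: float = 0.05) -> TimeActivityCurve:
    """Forward 2TCM solution C_T at arbitrary times (minutes).

    The AIF grid must span the requested times.
    """
    t = np.asarray(times, dtype=float)
    if t.max() > aif.t_max + 1e-9:
        raise RangeError(
            f"AIF ends at {aif.t_max} min but {t.max()} min was requested"
        )
    grid = np.arange(0.0, t.max() + dt, dt)
    ct = model_on_grid(params, dt, aif.plasma_at(grid), aif.blood_at(grid))
    return TimeActivityCurve(t, np.interp(t, grid, ct), units="kBq/mL")


def frame_average(curve: TimeActivityCurve, schedule: FrameSchedule) -> TimeActivityCurve:
    """Per-frame time-average of a finely sampled model curve.

    Matches a continuous-time model output to frame-integrated PET data.
    The curve must span every frame.
    """
    if curve.times[0] > schedule.start[0] + 1e-9 or curve.times[-1] < schedule.end[-1] - 1e-9:
        raise RangeError("curve does not span the frame schedule")
    return TimeActivityCurve(
        schedule.mid,
        _frame_average_values(curve.times, curve.values, schedule),
        units=curve.units,
    )


def _frame_average_values(t: np.ndarray, v: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    # cumulative trapezoid integral, then exact differences at frame edges
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(t))])
    f_start = np.interp(schedule.start, t, cum)
    f_end = np.interp(schedule.end, t, cum)
    return (f_end - f_start) / schedule.duration


@dataclass(frozen=True)
class FitConfig:
    """Settings for the bounded multistart least-squares fit."""

    n_starts: int = 20
    seed: int = 20200101
    weighting: str = "duration"  # uniform | duration | duration-over-value
    dt: float = 0.05
    k4_free: bool = True         # False -> irreversible (k4 fixed at 0)
    bounds: tuple = DEFAULT_BOUNDS

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise InvalidConfigError("n_starts must be >= 1")
        if self.weighting not in ("uniform", "duration", "duration-over-value"):
            raise InvalidConfigError(f"unknown weighting '{self.weighting}'")
        if len(self.bounds) != 5:
            raise InvalidConfigError("bounds must give 5 (lo, hi) pairs")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one lesion fit."""

    params: TwoTissueParams
    ki: float
    weighted_rss: float
    success: bool
    stderr: dict
    n_restarts_used: int

    def __post_init__(self) -> None:
        denom = self.params.k2 + self.params.k3
        expect = 0.0 if denom == 0.0 else self.params.K1 * self.params.k3 / denom
        if abs(self.ki - expect) > 1e-12 * max(1.0, abs(expect)):
            raise InvalidConfigError("Ki inconsistent with rate constants")


class TwoTissueFitter(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for the reversible 2TCM.

    Parameters
    ----------
    aif : ArterialInputFunction
        Metabolite-corrected input function spanning the schedule.
    schedule : FrameSchedule
        Frame timing of the measured TAC.
    n_starts, seed, weighting, dt, k4_free, bounds
        See :class:`FitConfig`.

    ``fit(X, y)`` takes frame mid-times (minutes) in ``X`` (shape
    ``(n_frames,)`` or ``(n_frames, 1)``) and the measured region TAC in
    ``y`` (kBq/mL).  Fitted attributes: ``K1_``, ``k2_``, ``k3_``,
    ``k4_``, ``vb_``, ``ki_``, ``params_``, ``weighted_rss_``,
    ``success_``, ``stderr_``, ``n_restarts_used_``.
    """

    def __init__(self, aif=None, schedule=None, n_starts=20, seed=20200101,
                 weighting="duration", dt=0.05, k4_free=True, bounds=DEFAULT_BOUNDS):
        self.aif = aif
        self.schedule = schedule
        self.n_starts = n_starts
        self.seed = seed
        self.weighting = weighting
        self.dt = dt
        self.k4_free = k4_free
        self.bounds = bounds

    # -- internal machinery -------------------------------------------------

    def _prepare(self):
        if self.aif is None or self.schedule is None:
            raise InvalidConfigError("aif and schedule are required to fit")
        sched = self.schedule
        if self.aif.t_max < sched.end[-1] - 1e-9:
            raise RangeError("AIF does not span the frame schedule")
        grid = np.arange(0.0, sched.end[-1] + self.dt, self.dt)
        return grid, self.aif.plasma_at(grid), self.aif.blood_at(grid)

    def _weights(self, y: np.ndarray) -> np.ndarray:
        d = self.schedule.duration
        if self.weighting == "uniform":
            w = np.ones_like(d)
        elif self.weighting == "duration":
            w = d / d.mean()
        else:  # duration-over-value
            w = d / np.maximum(np.abs(y), 1e-3 * max(np.abs(y).max(), 1e-12))
            w = w / w.mean()
        return np.sqrt(w)

    def _predict_frames(self, x: np.ndarray, grid, cp, cb) -> np.ndarray:
        p = TwoTissueParams(*x) if x.size == 5 else TwoTissueParams(*x, 0.0, 0.0)
        ct = model_on_grid(p, self.dt, cp, cb)
        return _frame_average_values(grid, ct, self.schedule)

    def objective(self, params: TwoTissueParams, y: np.ndarray) -> float:
        """Weighted residual sum of squares of ``params`` against data ``y``."""
        grid, cp, cb = self._prepare()
        sw = self._weights(np.asarray(y, dtype=float))
        r = sw * (self._predict_frames(params.as_array(), grid, cp, cb) - y)
        return float(r @ r)

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.size != y.size:
            raise InvalidConfigError("X and y must have equal length")
        if y.size < 8:
            raise InvalidConfigError("at least 8 frames are needed for a 2TCM fit")
        mid = self.schedule.mid
        if X.size != mid.size or not np.allclose(X, mid, atol=1e-6):
            raise InvalidConfigError("X must be the schedule's frame mid-times")

        grid, cp, cb = self._prepare()
        sw = self._weights(y)
        free = [0, 1, 2, 3, 4] if self.k4_free else [0, 1, 2, 4]
        lo = np.array([self.bounds[i][0] for i in free])
        hi = np.array([self.bounds[i][1] for i in free])

        def residual(xfree):
            x = np.zeros(5)
            x[free] = xfree
            return sw * (self._predict_frames(x, grid, cp, cb) - y)

        sampler = qmc.LatinHypercube(d=len(free), seed=self.seed)
        starts = lo + sampler.random(self.n_starts) * (hi - lo)

        best = None
        n_ok = 0
        for x0 in starts:
            try:
                sol = least_squares(residual, x0, bounds=(lo, hi),
                                    method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10)
            except Exception:  # noqa: BLE001 - a diverged start is not fatal
                continue
            n_ok += 1
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitFailureError(
                f"all {self.n_starts} restarts failed (n={y.size} frames, "
                f"weighting={self.weighting})"
            )

        x = np.zeros(5)
        x[free] = best.x
        self.params_ = TwoTissueParams(*x)
        self.K1_, self.k2_, self.k3_, self.k4_, self.vb_ = x
        self.ki_ = self.params_.ki
        self.weighted_rss_ = float(2.0 * best.cost)
        self.success_ = bool(best.status > 0)
        self.n_restarts_used_ = n_ok

        # approximate per-parameter uncertainty from local curvature
        dof = max(y.size - len(free), 1)
        s2 = self.weighted_rss_ / dof
        jtj = best.jac.T @ best.jac
        try:
            cov = s2 * np.linalg.pinv(jtj)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(len(free), np.nan)
        self.stderr_ = {PARAM_NAMES[i]: float(s) for i, s in zip(free, se)}
        if not self.k4_free:
            self.stderr_["k4"] = 0.0
        return self

    def predict(self, X):
        """Model frame-averaged TAC at the schedule's frame mid-times."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float).reshape(-1)
        grid, cp, cb = self._prepare()
        pred = self._predict_frames(self.params_.as_array(), grid, cp, cb)
        idx = np.searchsorted(self.schedule.mid, X)
        idx = np.clip(idx, 0, pred.size - 1)
        if not np.allclose(self.schedule.mid[idx], X, atol=1e-6):
            raise InvalidConfigError("X must be frame mid-times of the schedule")
        return pred[idx]


def fit_2tcm(tac: TimeActivityCurve, aif: ArterialInputFunction,
             schedule: FrameSchedule, config: FitConfig | None = None) -> FitResult:
    """Fit the reversible 2TCM to a region TAC; thin wrapper over TwoTissueFitter."""
    cfg = config or FitConfig()
    est = TwoTissueFitter(aif=aif, schedule=schedule, n_starts=cfg.n_starts,
                          seed=cfg.seed, weighting=cfg.weighting, dt=cfg.dt,
                          k4_free=cfg.k4_free, bounds=cfg.bounds)
    est.fit(tac.times, tac.values)
    return FitResult(params=est.params_, ki=est.ki_, weighted_rss=est.weighted_rss_,
                     success=est.success_, stderr=est.stderr_,
                     n_restarts_used=est.n_restarts_used_)


def kinetic_cohort_summary(baseline, post=None) -> dict:
    """Mean +/- SD of each kinetic parameter, and paired changes if post given.

    Parameters
    ----------
    baseline, post : sequence of mappings
        Each element must expose keys among K1, k2, k3, k4, vb, ki
        (e.g. dicts, or records from ``response.load_table2``).  ``post``
        must pair with ``baseline`` element-wise (same subjects, same order).

    Returns
    -------
    dict with per-parameter ``{mean, sd, n}``; when ``post`` is supplied,
    also per-parameter ``{pct_change_mean, pct_change_sd, wilcoxon_p}``
    over the per-subject percentage changes.
    """

    def column(records, key):
        out = []
        for r in records:
            v = r.get(key) if isinstance(r, dict) else getattr(r, key, None)
            if v is not None and np.isfinite(v):
                out.append(float(v))
            else:
                out.append(np.nan)
        return np.asarray(out)

    base_list = list(baseline)
    if len(base_list) < 2:
        raise PairingError("need at least 2 subjects to summarize")
    result: dict = {"n": len(base_list)}
    keys = ("K1", "k2", "k3", "k4", "vb", "ki")
    for key in keys:
        col = column(base_list, key)
        ok = np.isfinite(col)
        if ok.sum() == 0:
            continue
        result[key] = {"mean": float(np.mean(col[ok])),
                       "sd": float(np.std(col[ok], ddof=1)) if ok.sum() > 1 else 0.0,
                       "n": int(ok.sum())}
    if post is not None:
        post_list = list(post)
        if len(post_list) != len(base_list):
            raise PairingError(
                f"baseline has {len(base_list)} subjects but post has {len(post_list)}"
            )
        for key in keys:
            b, p = column(base_list, key), column(post_list, key)
            ok = np.isfinite(b) & np.isfinite(p) & (b != 0)
            if ok.sum() < 2 or key not in result:
                continue
            pct = 100.0 * (p[ok] - b[ok]) / b[ok]
            entry = result[key]
            entry["pct_change_mean"] = float(pct.mean())
            entry["pct_change_sd"] = float(pct.std(ddof=1))
            diffs = p[ok] - b[ok]
            if np.any(diffs != 0) and ok.sum() >= 5:
                entry["wilcoxon_p"] = float(wilcoxon(b[ok], p[ok]).pvalue)
    return result
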