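"""Arterial input functions: image-derived extraction, metabolite
correction, and a parametric (Feng-type) bolus model for simulation.

The kinetic model is driven by the metabolite-corrected plasma
parent-tracer concentration Cp(t); the whole-blood curve Cb(t) enters
through the fractional blood volume term.  Clinically both come from a
blood-pool ROI; in simulation they come from the tri-exponential bolus
model below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DynamicPETSeries, ROIMask, TimeActivityCurve, extract_tac
from .errors import GeometryError, InvalidAIFError, InvalidConfigError, RangeError

__all__ = [
    "ParametricAIFParams",
    "ParentFractionModel",
    "ArterialInputFunction",
    "feng_aif",
    "extract_idaif",
    "metabolite_correct",
    "resample_tac",
]


@dataclass(frozen=True)
class ParametricAIFParams:
    """Tri-exponential bolus input function (Feng model 2).

    Cp(t') = (A1*t' - A2 - A3) e^(-l1 t') + A2 e^(-l2 t') + A3 e^(-l3 t')
    for t' = t - delay (zero before the delay).  A1 is kBq/mL/min; A2, A3
    kBq/mL; l1 > l2 > l3 > 0 in 1/min.  Defaults give a realistic bolus
    with ~100 kBq/mL peak for a standard injected activity.
    """

    A1: float = 800.0
    A2: float = 22.0
    A3: float = 21.0
    lambda1: float = 4.1
    lambda2: float = 0.12
    lambda3: float = 0.01
    delay: float = 0.5

    def __post_init__(self) -> None:
        if not (self.lambda1 > self.lambda2 > self.lambda3 > 0):
            raise InvalidAIFError("require lambda1 > lambda2 > lambda3 > 0")
        if self.A2 < 0 or self.A3 < 0:
            raise InvalidAIFError("A2 and A3 must be >= 0")
        if self.delay < 0:
            raise InvalidAIFError("delay must be >= 0")
        # the curve must be nonnegative on its support; a negative dip can
        # only arise just after onset where the first term dominates
        t = np.linspace(0.0, 5.0 / self.lambda1, 200)
        c = (self.A1 * t - self.A2 - self.A3) * np.exp(-self.lambda1 * t) \
            + self.A2 * np.exp(-self.lambda2 * t) + self.A3 * np.exp(-self.lambda3 * t)
        if np.any(c < -1e-9):
            raise InvalidAIFError("parameters produce a negative input curve")


def feng_aif(params: ParametricAIFParams, times) -> TimeActivityCurve:
    """Evaluate the parametric bolus at the given times (minutes >= 0)."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise InvalidAIFError("times must be >= 0")
    tp = t - params.delay
    c = np.where(
        tp <= 0,
        0.0,
        (params.A1 * tp - params.A2 - params.A3) * np.exp(-params.lambda1 * np.maximum(tp, 0))
        + params.A2 * np.exp(-params.lambda2 * np.maximum(tp, 0))
        + params.A3 * np.exp(-params.lambda3 * np.maximum(tp, 0)),
    )
    return TimeActivityCurve(t, np.maximum(c, 0.0), units="kBq/mL")


@dataclass(frozen=True)
class ParentFractionModel:
    """Sigmoid parent fraction p(t) = floor + (1-floor)/(1 + (t/half_time)^steepness).

    p(0) = 1 and p decays monotonically toward ``floor``.  FLT is
    metabolized slowly (glucuronidation), so the default is a gentle
    decline: half_time 60 min, steepness 1.5, floor 0.7.
    """

    half_time: float = 60.0
    steepness: float = 1.5
    floor: float = 0.7

    def __post_init__(self) -> None:
        if not (self.half_time > 0 and self.steepness > 0):
            raise InvalidConfigError("half_time and steepness must be > 0")
        if not (0.0 <= self.floor <= 1.0):
            raise InvalidConfigError("floor must lie in [0, 1]")

    def __call__(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return self.floor + (1.0 - self.floor) / (1.0 + (t / self.half_time) ** self.steepness)


@dataclass(frozen=True)
class ArterialInputFunction:
    """Paired whole-blood and metabolite-corrected plasma-parent curves.

    Both curves live on a common, strictly increasing time grid.  The
    plasma-parent curve can never exceed ``plasma_to_blood`` times the
    whole-blood curve (the parent fraction is <= 1).
    """

    times: np.ndarray
    whole_blood: np.ndarray
    plasma_parent: np.ndarray
    plasma_to_blood: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "whole_blood", np.asarray(self.whole_blood, dtype=float))
        object.__setattr__(self, "plasma_parent", np.asarray(self.plasma_parent, dtype=float))
        if not (self.times.shape == self.whole_blood.shape == self.plasma_parent.shape):
            raise InvalidAIFError("times, whole_blood, plasma_parent must share a grid")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise InvalidAIFError("time grid must be strictly increasing")
        if np.any(self.whole_blood < 0) or np.any(self.plasma_parent < 0):
            raise InvalidAIFError("blood curves must be nonnegative")
        ceiling = self.plasma_to_blood * self.whole_blood
        if np.any(self.plasma_parent > ceiling + 1e-9 * (1.0 + ceiling)):
            raise InvalidAIFError("plasma_parent exceeds plasma_to_blood * whole_blood")

    def plasma_at(self, times) -> np.ndarray:
        """Plasma-parent concentration, linearly interpolated (0 before t0)."""
        return np.interp(np.asarray(times, dtype=float), self.times, self.plasma_parent,
                         left=0.0)

    def blood_at(self, times) -> np.ndarray:
        return np.interp(np.asarray(times, dtype=float), self.times, self.whole_blood,
                         left=0.0)

    @property
    def t_max(self) -> float:
        return float(self.times[-1])


def extract_idaif(series: DynamicPETSeries, blood_mask: ROIMask,
                  hottest_fraction: float = 0.2,
                  early_window_min: float = 2.0) -> TimeActivityCurve:
    """Image-derived whole-blood curve from a blood-pool ROI.

    Voxels are ranked by their time-integral over the early frames
    (mid-time <= ``early_window_min``), when activity is concentrated in
    the vasculature; the mean TAC of the hottest fraction is returned.
    Restricting to the hottest voxels mitigates partial-volume dilution.
    """
    if not (0.0 < hottest_fraction <= 1.0):
        raise InvalidConfigError("hottest_fraction must lie in (0, 1]")
    if series.values[..., 0].shape != blood_mask.mask.shape:
        raise GeometryError("blood mask grid does not match series grid")
    if hottest_fraction == 1.0:
        return extract_tac(series, blood_mask)
    mid = series.schedule.mid
    early = mid <= early_window_min
    if not early.any():
        early = np.zeros_like(mid, dtype=bool)
        early[0] = True
    voxel_tacs = series.values[blood_mask.mask, :]
    score = voxel_tacs[:, early] @ series.schedule.duration[early]
    n_keep = max(1, int(np.ceil(hottest_fraction * voxel_tacs.shape[0])))
    keep = np.argsort(score)[::-1][:n_keep]
    return TimeActivityCurve(mid, voxel_tacs[keep, :].mean(axis=0), units="kBq/mL")


def metabolite_correct(whole_blood: TimeActivityCurve,
                       model: ParentFractionModel | None = None,
                       plasma_to_blood: float = 1.0) -> ArterialInputFunction:
    """Apply plasma scaling and parent-fraction correction to a blood curve.

    plasma_parent(t) = whole_blood(t) * plasma_to_blood * p(t).
    """
    if model is None:
        model = ParentFractionModel()
    if plasma_to_blood <= 0:
        raise InvalidConfigError("plasma_to_blood must be > 0")
    if np.any(whole_blood.values < 0):
        raise InvalidAIFError("whole-blood curve must be nonnegative")
    p = model(whole_blood.times)
    return ArterialInputFunction(
        times=whole_blood.times,
        whole_blood=whole_blood.values,
        plasma_parent=whole_blood.values * plasma_to_blood * p,
        plasma_to_blood=plasma_to_blood,
    )


def resample_tac(curve: TimeActivityCurve, new_times) -> TimeActivityCurve:
    """Linearly interpolate a curve onto a new grid (0 before first sample).

    Extrapolation beyond the last sample is refused.
    """
    if len(curve) < 2:
        raise RangeError("need at least 2 samples to resample")
    new_t = np.asarray(new_times, dtype=float)
    if np.any(new_t < 0) or np.any(new_t > curve.times[-1] + 1e-12):
        raise RangeError(
            f"new times must lie in [0, {curve.times[-1]}] min; extrapolation refused"
        )
    vals = np.interp(new_t, curve.times, curve.values, left=0.0)
    return TimeActivityCurve(new_t, vals, units=curve.units)
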