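"""Data model for dynamic PET and static SUV quantification.

The objects here mirror what a dynamic liver acquisition produces: a 4D
activity-concentration volume with its frame schedule, ROI masks drawn on
the same grid, subject dosimetry metadata, and region time-activity curves.
All concentrations are kBq/mL; times are minutes post-injection; SUV uses
the body-weight convention (g/mL, dimensionless).

Decay correction is assumed to have been applied during reconstruction,
as is standard for clinical PET; the package does not re-correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    GeometryError,
    InvalidBackgroundError,
    InvalidSubjectError,
    InvalidWindowError,
)

__all__ = [
    "FrameSchedule",
    "DynamicPETSeries",
    "SubjectInfo",
    "ROIMask",
    "TimeActivityCurve",
    "summed_image",
    "compute_suv",
    "suv_stats",
    "extract_tac",
    "tumor_to_liver_ratio",
]


@dataclass(frozen=True)
class FrameSchedule:
    """Frame timing of a dynamic acquisition.

    Parameters
    ----------
    start : array-like
        Frame start times, minutes since injection, strictly increasing.
    duration : array-like
        Frame durations in minutes, all positive.  Frames may be
        contiguous or gapped but must not run backwards.
    """

    start: np.ndarray
    duration: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", np.asarray(self.start, dtype=float))
        object.__setattr__(self, "duration", np.asarray(self.duration, dtype=float))
        if self.start.ndim != 1 or self.start.shape != self.duration.shape:
            raise InvalidWindowError("start and duration must be 1D and equal length")
        if np.any(self.duration <= 0):
            raise InvalidWindowError("frame durations must be positive")
        if np.any(np.diff(self.start) <= 0):
            raise InvalidWindowError("frame start times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.start.size

    @property
    def mid(self) -> np.ndarray:
        """Frame mid-times in minutes."""
        return self.start + self.duration / 2.0

    @property
    def end(self) -> np.ndarray:
        return self.start + self.duration

    @property
    def total_minutes(self) -> float:
        return float(self.end[-1])

    @classmethod
    def from_durations(cls, durations_min, t0: float = 0.0) -> "FrameSchedule":
        """Build a contiguous schedule from a list of frame durations."""
        d = np.asarray(durations_min, dtype=float)
        starts = t0 + np.concatenate([[0.0], np.cumsum(d)[:-1]])
        return cls(starts, d)


@dataclass(frozen=True)
class SubjectInfo:
    """Dosimetry metadata needed for SUV normalization.

    injected_activity_mbq is decay-corrected to injection time;
    body_weight_g is in grams.
    """

    injected_activity_mbq: float
    body_weight_g: float

    def __post_init__(self) -> None:
        if not (self.injected_activity_mbq > 0):
            raise InvalidSubjectError("injected activity must be > 0 MBq")
        if not (self.body_weight_g > 0):
            raise InvalidSubjectError("body weight must be > 0 g")


@dataclass(frozen=True)
class DynamicPETSeries:
    """A 4D dynamic PET volume: (x, y, z, frame) in kBq/mL."""

    values: np.ndarray
    voxel_size_mm: tuple
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        if self.values.ndim != 4:
            raise GeometryError("dynamic series must be 4D (x, y, z, frame)")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise GeometryError("voxel_size_mm must be 3 positive values")
        if self.values.shape[3] != self.schedule.n_frames:
            raise GeometryError(
                f"frame axis ({self.values.shape[3]}) does not match schedule "
                f"({self.schedule.n_frames} frames)"
            )
        if np.any(self.values < 0):
            raise GeometryError("activity concentrations must be >= 0")

    @property
    def spatial_shape(self) -> tuple:
        return self.values.shape[:3]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0


@dataclass(frozen=True)
class ROIMask:
    """Boolean voxel membership on the image grid, with a free-text label."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.mask.ndim != 3:
            raise GeometryError("ROI mask must be 3D")
        if not self.mask.any():
            raise GeometryError(f"ROI mask '{self.label}' is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class TimeActivityCurve:
    """Tracer concentration (or SUV) in a region as a function of time."""

    times: np.ndarray
    values: np.ndarray
    units: str = "kBq/mL"  # "kBq/mL" | "SUV"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise GeometryError("times and values must be 1D and equal length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise GeometryError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def _check_grid(volume: np.ndarray, roi: ROIMask) -> None:
    if volume.shape != roi.mask.shape:
        raise GeometryError(
            f"volume grid {volume.shape} does not match mask grid {roi.mask.shape}"
        )


def summed_image(series: DynamicPETSeries, window: tuple) -> np.ndarray:
    """Duration-weighted mean concentration over frames inside a time window.

    A frame contributes if its mid-time lies in ``[window[0], window[1]]``
    (inclusive).  The result is the static "summed image" on which ROIs
    are drawn and SUVs measured.

    Parameters
    ----------
    series : DynamicPETSeries
    window : (t_lo, t_hi) in minutes.

    Returns
    -------
    3D ndarray, kBq/mL.
    """
    t_lo, t_hi = float(window[0]), float(window[1])
    if t_hi <= t_lo:
        raise InvalidWindowError(f"window {window} is empty or reversed")
    mid = series.schedule.mid
    sel = (mid >= t_lo) & (mid <= t_hi)
    if not sel.any():
        raise InvalidWindowError(
            f"window [{t_lo}, {t_hi}] min contains no frame mid-times "
            f"(schedule spans {series.schedule.start[0]}-{series.schedule.total_minutes} min)"
        )
    w = series.schedule.duration[sel]
    return np.tensordot(series.values[..., sel], w, axes=([3], [0])) / w.sum()


def compute_suv(volume: np.ndarray, subject: SubjectInfo) -> np.ndarray:
    """Convert a concentration volume (kBq/mL) to body-weight SUV (g/mL).

    SUV = C / (injected activity / body weight), with activity expressed
    in kBq so the ratio has units kBq/g; injected activity is given in
    MBq, hence the factor 1000.  Doubling injected activity halves SUV.
    """
    # SubjectInfo validates positivity at construction.
    dose_per_gram = subject.injected_activity_mbq * 1000.0 / subject.body_weight_g
    return np.asarray(volume, dtype=float) / dose_per_gram


def suv_stats(suv_volume: np.ndarray, roi: ROIMask) -> dict:
    """SUV_mean and SUV_max over a region of interest."""
    suv_volume = np.asarray(suv_volume, dtype=float)
    _check_grid(suv_volume, roi)
    vals = suv_volume[roi.mask]
    return {"suv_mean": float(vals.mean()), "suv_max": float(vals.max())}


def extract_tac(series: DynamicPETSeries, roi: ROIMask) -> TimeActivityCurve:
    """Region-mean time-activity curve; times are frame mid-times."""
    _check_grid(series.values[..., 0], roi)
    vals = series.values[roi.mask, :].mean(axis=0)
    return TimeActivityCurve(series.schedule.mid, vals, units="kBq/mL")


def tumor_to_liver_ratio(tumor_suv_max: float, liver_suv_mean: float) -> float:
    """Lesion conspicuity index: tumor SUV_max over background liver SUV_mean."""
    if not (liver_suv_mean > 0):
        raise InvalidBackgroundError("liver SUV_mean must be > 0")
    return float(tumor_suv_max) / float(liver_suv_mean)
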