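"""Kinetic spatial filtering (KSF) of dynamic liver PET.

Hepatic FLT uptake is high enough to hide tumors on static images.  KSF
classifies every voxel's time-activity curve against tissue-class
template curves (liver, tumor, blood, ...), spatially regularizes the
class map with a neighborhood-majority filter, and zeroes voxels of
excluded classes (liver-like physiologic uptake) in the summed image.
Shape, not amplitude, drives the classification: curves are normalized
(unit area by default) before the distance is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin

from .core import DynamicPETSeries, ROIMask, extract_tac, summed_image, suv_stats
from .errors import DegenerateROIError, GeometryError, InvalidConfigError, MaskConflictError

__all__ = [
    "TissueClassTemplate",
    "KSFConfig",
    "KSFResult",
    "NearestTemplateClassifier",
    "build_templates",
    "classify_voxels",
    "apply_ksf",
    "ksf_metrics",
]

OTHER_CLASS = "other"


def _normalize(curves: np.ndarray, times: np.ndarray, how: str) -> np.ndarray:
    """Normalize TAC rows to unit area (trapezoid) or unit peak.

    All-zero rows are returned unchanged (flagged by the caller).
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    if how == "unit-area":
        scale = np.trapezoid(curves, times, axis=1)
    elif how == "unit-peak":
        scale = curves.max(axis=1)
    else:
        raise InvalidConfigError(f"unknown normalization '{how}'")
    scale = np.where(scale > 0, scale, 1.0)
    return curves / scale[:, None]


@dataclass(frozen=True)
class TissueClassTemplate:
    """A named, unit-area-normalized tissue-class time-activity curve."""

    name: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.values < 0):
            raise InvalidConfigError("template curve must be nonnegative")
        area = np.trapezoid(self.values, self.times)
        if abs(area - 1.0) > 1e-9:
            raise InvalidConfigError(
                f"template '{self.name}' must have unit area (got {area:.3g})"
            )


@dataclass(frozen=True)
class KSFConfig:
    """Free choices of the filter, recorded explicitly."""

    distance: str = "normalized-l2"      # normalized-l2 | one-minus-correlation
    normalization: str = "unit-area"     # unit-area | unit-peak
    spatial_filter_radius: int = 1       # voxels; 0 disables majority relabeling
    exclusion_classes: tuple = ("liver",)

    def __post_init__(self) -> None:
        if self.distance not in ("normalized-l2", "one-minus-correlation"):
            raise InvalidConfigError(f"unknown distance '{self.distance}'")
        if self.normalization not in ("unit-area", "unit-peak"):
            raise InvalidConfigError(f"unknown normalization '{self.normalization}'")
        if self.spatial_filter_radius < 0:
            raise InvalidConfigError("spatial_filter_radius must be >= 0")


@dataclass(frozen=True)
class KSFResult:
    """Class map, filtered summed image, and suppression metrics."""

    class_map: np.ndarray          # class-name strings per voxel
    filtered_summed: np.ndarray
    unfiltered_summed: np.ndarray
    excluded: tuple


class NearestTemplateClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-template TAC classifier (scikit-learn style).

    ``fit(X, y)`` takes voxel TACs as rows of ``X`` (n_voxels, n_frames)
    with class labels ``y``; the per-class mean curve, normalized per
    ``normalization``, becomes the class template.  ``predict(X)``
    assigns each row the nearest template under ``distance``; ties break
    in favor of the earlier class in ``class_order`` (liver first, so
    suppression is conservative).  All-zero rows get class ``"other"``.

    Parameters
    ----------
    times : array of frame mid-times (minutes); required for unit-area
        normalization and for exporting templates.
    distance, normalization : see :class:`KSFConfig`.
    class_order : optional explicit ordering used for tie-breaking;
        defaults to first appearance in ``y`` with "liver" hoisted first.
    """

    def __init__(self, times=None, distance="normalized-l2",
                 normalization="unit-area", class_order=None):
        self.times = times
        self.distance = distance
        self.normalization = normalization
        self.class_order = class_order

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if X.shape[0] != y.size:
            raise InvalidConfigError("X rows and y labels must match")
        if self.times is None:
            raise InvalidConfigError("times is required")
        times = np.asarray(self.times, dtype=float)
        if times.size != X.shape[1]:
            raise GeometryError("times length must equal the TAC length")
        KSFConfig(distance=self.distance, normalization=self.normalization)

        if self.class_order is not None:
            order = list(self.class_order)
        else:
            seen = list(dict.fromkeys(y.tolist()))
            order = (["liver"] if "liver" in seen else []) + [c for c in seen if c != "liver"]
        if len(order) < 2:
            raise InvalidConfigError("need at least 2 tissue classes")
        means = np.stack([X[y == c].mean(axis=0) for c in order])
        self.classes_ = np.asarray(order)
        self.templates_ = _normalize(means, times, self.normalization)
        self.times_ = times
        return self

    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "templates_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        zero = X.max(axis=1) <= 0
        Xn = _normalize(X, self.times_, self.normalization)
        if self.distance == "normalized-l2":
            d = ((Xn[:, None, :] - self.templates_[None, :, :]) ** 2).sum(axis=2)
        else:  # one-minus-correlation
            xc = Xn - Xn.mean(axis=1, keepdims=True)
            tc = self.templates_ - self.templates_.mean(axis=1, keepdims=True)
            xs = np.sqrt((xc * xc).sum(axis=1, keepdims=True))
            ts = np.sqrt((tc * tc).sum(axis=1))
            denom = np.maximum(xs * ts[None, :], 1e-30)
            d = 1.0 - (xc @ tc.T) / denom
        # argmin returns the first minimum -> earlier class wins ties
        labels = self.classes_[np.argmin(d, axis=1)].astype(object)
        labels[zero] = OTHER_CLASS
        return labels.astype("U32")


def build_templates(series: DynamicPETSeries, class_masks: list,
                    config: KSFConfig | None = None) -> list:
    """Per-class mean TACs, normalized to unit area, from labeled ROIs."""
    cfg = config or KSFConfig()
    total = np.zeros(series.spatial_shape, dtype=int)
    for m in class_masks:
        total += m.mask.astype(int)
    if np.any(total > 1):
        raise MaskConflictError("tissue-class masks must be disjoint")
    templates = []
    for m in class_masks:
        tac = extract_tac(series, m)
        vals = _normalize(tac.values, tac.times, "unit-area")[0]
        templates.append(TissueClassTemplate(m.label, tac.times, vals))
    return templates


def classify_voxels(series: DynamicPETSeries, templates: list,
                    config: KSFConfig | None = None) -> np.ndarray:
    """Assign every voxel the nearest tissue-class template.

    Returns a 3D array of class-name strings ("other" for all-zero TACs).
    """
    cfg = config or KSFConfig()
    if len(templates) < 2:
        raise InvalidConfigError("need at least 2 templates")
    times = series.schedule.mid
    clf = NearestTemplateClassifier(times=times, distance=cfg.distance,
                                    normalization=cfg.normalization,
                                    class_order=[t.name for t in templates])
    # install templates directly: re-normalize per config from the stored
    # unit-area curves (unit-peak differs only by a positive rescale)
    clf.classes_ = np.asarray([t.name for t in templates])
    curves = np.stack([np.interp(times, t.times, t.values) for t in templates])
    clf.templates_ = _normalize(curves, times, cfg.normalization)
    clf.times_ = times
    X = series.values.reshape(-1, series.schedule.n_frames)
    return clf.predict(X).reshape(series.spatial_shape)


def _majority_filter(class_map: np.ndarray, classes: list, radius: int) -> np.ndarray:
    """Mode filter over a cubic neighborhood; ties go to the earlier class."""
    if radius == 0:
        return class_map.copy()
    size = 2 * radius + 1
    kernel = np.ones((size, size, size))
    counts = np.stack([
        ndimage.convolve((class_map == c).astype(float), kernel, mode="nearest")
        for c in classes
    ])
    winner = np.argmax(counts, axis=0)  # first max wins ties
    return np.asarray(classes, dtype=class_map.dtype)[winner]


def apply_ksf(series: DynamicPETSeries, class_map: np.ndarray,
              config: KSFConfig | None = None,
              window: tuple = (50.0, 60.0)) -> KSFResult:
    """Majority-filter the class map, then zero excluded classes in the summed image."""
    cfg = config or KSFConfig()
    if class_map.shape != series.spatial_shape:
        raise GeometryError("class map grid does not match the series grid")
    classes = sorted(np.unique(class_map).tolist(),
                     key=lambda c: (c not in cfg.exclusion_classes, c))
    smoothed = _majority_filter(class_map, classes, cfg.spatial_filter_radius)
    unfiltered = summed_image(series, window)
    keep = ~np.isin(smoothed, list(cfg.exclusion_classes))
    return KSFResult(class_map=smoothed,
                     filtered_summed=unfiltered * keep,
                     unfiltered_summed=unfiltered,
                     excluded=tuple(cfg.exclusion_classes))


def ksf_metrics(unfiltered_summed: np.ndarray, filtered_summed: np.ndarray,
                tumor_mask: ROIMask, liver_mask: ROIMask) -> dict:
    """Percent signal reduction per ROI and the post-filter tumor-to-liver ratio.

    reduction = 100 * (1 - mean_filtered / mean_unfiltered).  A fully
    suppressed liver makes the post-filter ratio +inf (flagged).
    """
    out = {}
    for name, roi in (("tumor", tumor_mask), ("liver", liver_mask)):
        mu_un = float(unfiltered_summed[roi.mask].mean())
        if mu_un <= 0:
            raise DegenerateROIError(f"{name} ROI has zero unfiltered mean")
        mu_f = float(filtered_summed[roi.mask].mean())
        out[f"{name}_pct_reduction"] = 100.0 * (1.0 - mu_f / mu_un)
    liver_mean = float(filtered_summed[liver_mask.mask].mean())
    tumor_max = float(filtered_summed[tumor_mask.mask].max())
    if liver_mean <= 0:
        out["post_filter_tumor_to_liver"] = float("inf")
        out["liver_fully_suppressed"] = True
    else:
        out["post_filter_tumor_to_liver"] = tumor_max / liver_mean
        out["liver_fully_suppressed"] = False
    return out
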