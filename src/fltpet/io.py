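"""File formats: NIfTI volumes with JSON timing sidecars, CSV curves.

Conventions
-----------
* 4D dynamic series and 3D volumes: NIfTI-1 (.nii / .nii.gz), voxel size
  taken from the affine/zooms, concentrations in kBq/mL.
* Frame schedule: sidecar JSON ``{"frame_start_min": [...],
  "frame_duration_min": [...]}``.
* Subject metadata: JSON ``{"injected_activity_mbq": ..., "body_weight_g": ...}``.
* TACs and input functions: 2-column CSV (time_min, kBq_per_mL) with a
  header row; AIFs use 3 columns (adds plasma_parent).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import DynamicPETSeries, FrameSchedule, ROIMask, SubjectInfo, TimeActivityCurve
from .errors import GeometryError, SchemaError
from .input_function import ArterialInputFunction


def save_series(series: DynamicPETSeries, image_path, timing_path=None) -> None:
    affine = np.diag(list(series.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(series.values.astype(np.float32), affine), str(image_path))
    if timing_path is not None:
        save_schedule(series.schedule, timing_path)


def save_schedule(schedule: FrameSchedule, path) -> None:
    Path(path).write_text(json.dumps({
        "frame_start_min": schedule.start.tolist(),
        "frame_duration_min": schedule.duration.tolist(),
    }, indent=1))


def load_schedule(path) -> FrameSchedule:
    doc = json.loads(Path(path).read_text())
    try:
        return FrameSchedule(doc["frame_start_min"], doc["frame_duration_min"])
    except KeyError as exc:
        raise SchemaError(f"timing JSON missing key {exc}") from exc


def load_series(image_path, timing_path) -> DynamicPETSeries:
    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4:
        raise GeometryError(f"{image_path}: expected a 4D volume, got {data.ndim}D")
    return DynamicPETSeries(data, img.header.get_zooms()[:3], load_schedule(timing_path))


def save_volume(volume: np.ndarray, voxel_size_mm, path) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def load_mask(path, label: str = "") -> ROIMask:
    img = nib.load(str(path))
    return ROIMask(np.asanyarray(img.dataobj) > 0.5, label=label or Path(path).stem)


def save_mask(mask: ROIMask, voxel_size_mm, path) -> None:
    save_volume(mask.mask.astype(np.uint8), voxel_size_mm, path)


def load_subject(path) -> SubjectInfo:
    doc = json.loads(Path(path).read_text())
    try:
        return SubjectInfo(doc["injected_activity_mbq"], doc["body_weight_g"])
    except KeyError as exc:
        raise SchemaError(f"subject JSON missing key {exc}") from exc


def save_tac(curve: TimeActivityCurve, path) -> None:
    pd.DataFrame({"time_min": curve.times, "kBq_per_mL": curve.values}).to_csv(
        path, index=False)


def load_tac(path) -> TimeActivityCurve:
    df = pd.read_csv(path)
    if not {"time_min", "kBq_per_mL"}.issubset(df.columns):
        raise SchemaError(f"{path}: TAC CSV needs columns time_min, kBq_per_mL")
    return TimeActivityCurve(df["time_min"].to_numpy(), df["kBq_per_mL"].to_numpy())


def save_aif(aif: ArterialInputFunction, path) -> None:
    pd.DataFrame({"time_min": aif.times, "kBq_per_mL": aif.whole_blood,
                  "plasma_parent_kBq_per_mL": aif.plasma_parent}).to_csv(path, index=False)


def load_aif(path) -> ArterialInputFunction:
    df = pd.read_csv(path)
    need = {"time_min", "kBq_per_mL", "plasma_parent_kBq_per_mL"}
    if not need.issubset(df.columns):
        raise SchemaError(f"{path}: AIF CSV needs columns {sorted(need)}")
    return ArterialInputFunction(df["time_min"].to_numpy(),
                                 df["kBq_per_mL"].to_numpy(),
                                 df["plasma_parent_kBq_per_mL"].to_numpy())
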