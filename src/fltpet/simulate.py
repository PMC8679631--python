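"""Seeded synthetic dynamic FLT liver phantoms and response cohorts.

The phantom emulates a 60-minute dynamic liver acquisition: a cirrhotic
liver background with high physiologic delivery, a blood pool following
the arterial bolus, and one or more spherical tumors whose two-tissue
kinetics span the clinically observed range.  Every voxel's noise-free
TAC is the frame-averaged forward 2TCM solution for its tissue; frame
noise is zero-mean Gaussian with SD = noise_coeff * sqrt(value /
frame_duration), clipped at zero — a count-statistics proxy, not a
sinogram simulation.  Every output is a pure function of the config
(including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    DynamicPETSeries,
    FrameSchedule,
    ROIMask,
    SubjectInfo,
    compute_suv,
)
from .errors import InvalidConfigError
from .input_function import (
    ArterialInputFunction,
    ParametricAIFParams,
    ParentFractionModel,
    feng_aif,
    metabolite_correct,
)
from .kinetics import TwoTissueParams, _frame_average_values, model_on_grid
from .response import LesionRecord

__all__ = [
    "Lesion",
    "PhantomConfig",
    "PhantomTruth",
    "TaceEffect",
    "CohortConfig",
    "default_schedule",
    "build_aif",
    "generate_phantom",
    "simulate_post_tace",
    "generate_cohort",
    "cohort_from_crosstab",
]

#: kinetics used for the default tumor (observed mid-range lesion values)
DEFAULT_TUMOR = TwoTissueParams(K1=0.31, k2=0.40, k3=0.24, k4=0.04, vb=0.019)

#: high-delivery, low-trapping liver background — the central difficulty
#: (high physiologic hepatic signal); plausible defaults, not measured values
DEFAULT_LIVER = TwoTissueParams(K1=0.25, k2=0.9, k3=0.02, k4=0.01, vb=0.10)


def default_schedule() -> FrameSchedule:
    """6x10s, 8x15s, 6x60s, 5x120s, 8x300s — 59 min in 33 frames."""
    durations = [10] * 6 + [15] * 8 + [60] * 6 + [120] * 5 + [300] * 8
    return FrameSchedule.from_durations(np.asarray(durations) / 60.0)


@dataclass(frozen=True)
class Lesion:
    """A spherical tumor: center in voxel indices, diameter in mm."""

    center_vox: tuple
    diameter_mm: float
    params: TwoTissueParams

    def __post_init__(self) -> None:
        if not (self.diameter_mm > 0):
            raise InvalidConfigError("lesion diameter must be > 0 mm")


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple = (40, 40, 20)
    voxel_size_mm: float = 4.0
    schedule: FrameSchedule = field(default_factory=default_schedule)
    aif_params: ParametricAIFParams = field(default_factory=ParametricAIFParams)
    parent_fraction: ParentFractionModel = field(default_factory=ParentFractionModel)
    plasma_to_blood: float = 1.0
    liver_params: TwoTissueParams = DEFAULT_LIVER
    lesions: tuple = (Lesion((22, 22, 10), 30.0, DEFAULT_TUMOR),)
    liver_center_vox: tuple = (22, 22, 10)
    liver_semiaxes_mm: tuple = (60.0, 52.0, 36.0)
    blood_center_xy: tuple = (6, 6)
    blood_radius_mm: float = 8.0
    noise_coeff: float = 0.5
    seed: int = 20200101
    subject: SubjectInfo = field(default_factory=lambda: SubjectInfo(370.0, 70000.0))
    dt: float = 0.05

    def __post_init__(self) -> None:
        if self.noise_coeff < 0:
            raise InvalidConfigError("noise_coeff must be >= 0")
        for les in self.lesions:
            r_vox = les.diameter_mm / 2.0 / self.voxel_size_mm
            for c, n in zip(les.center_vox, self.shape):
                if c - r_vox < -0.5 or c + r_vox > n - 0.5:
                    raise InvalidConfigError(
                        f"lesion at {les.center_vox} (d={les.diameter_mm} mm) "
                        f"exceeds the {self.shape} grid"
                    )


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth the generator emits for recovery tests."""

    masks: dict                  # label -> ROIMask (liver excludes lesions/blood)
    params: dict                 # label -> TwoTissueParams (blood has none)
    noise_free: DynamicPETSeries
    aif: ArterialInputFunction
    config: PhantomConfig


def build_aif(config: PhantomConfig) -> ArterialInputFunction:
    """The phantom's input function on a fine grid spanning the schedule."""
    grid = np.arange(0.0, config.schedule.end[-1] + config.dt, config.dt)
    wb = feng_aif(config.aif_params, grid)
    return metabolite_correct(wb, config.parent_fraction, config.plasma_to_blood)


def _sphere_mask(shape, center, radius_vox) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
    return d2 <= radius_vox ** 2


def _geometry(config: PhantomConfig) -> dict:
    """Disjoint masks: blood cylinder, lesion spheres, liver = ellipsoid minus both."""
    shape = config.shape
    idx = np.indices(shape, dtype=float)
    sa = tuple(s / config.voxel_size_mm for s in config.liver_semiaxes_mm)
    liver = sum(((idx[i] - config.liver_center_vox[i]) / sa[i]) ** 2
                for i in range(3)) <= 1.0
    bx, by = config.blood_center_xy
    r_b = config.blood_radius_mm / config.voxel_size_mm
    blood = (idx[0] - bx) ** 2 + (idx[1] - by) ** 2 <= r_b ** 2

    masks = {"blood": blood}
    lesion_union = np.zeros(shape, dtype=bool)
    for i, les in enumerate(config.lesions, start=1):
        sph = _sphere_mask(shape, les.center_vox, les.diameter_mm / 2.0 / config.voxel_size_mm)
        if (sph & blood).any():
            raise InvalidConfigError(f"lesion_{i} overlaps the blood pool")
        if (sph & lesion_union).any():
            raise InvalidConfigError(f"lesion_{i} overlaps another lesion")
        lesion_union |= sph
        masks[f"lesion_{i}"] = sph
    masks["liver"] = liver & ~lesion_union & ~blood
    return masks


def generate_phantom(config: PhantomConfig | None = None):
    """Simulate one dynamic acquisition.

    Returns ``(series, truth)``: the noisy :class:`DynamicPETSeries` and
    the :class:`PhantomTruth` (masks, per-tissue parameters, noise-free
    series, input function).
    """
    cfg = config or PhantomConfig()
    aif = build_aif(cfg)
    grid = aif.times
    sched = cfg.schedule

    masks = _geometry(cfg)
    params = {"liver": cfg.liver_params}
    for i, les in enumerate(cfg.lesions, start=1):
        params[f"lesion_{i}"] = les.params

    frame_values = {
        "blood": _frame_average_values(grid, aif.whole_blood, sched),
    }
    for label, p in params.items():
        ct = model_on_grid(p, cfg.dt, aif.plasma_parent, aif.whole_blood)
        frame_values[label] = _frame_average_values(grid, ct, sched)

    clean = np.zeros(cfg.shape + (sched.n_frames,))
    for label, mask in masks.items():
        clean[mask, :] = frame_values[label]

    rng = np.random.default_rng(cfg.seed)
    if cfg.noise_coeff > 0:
        sd = cfg.noise_coeff * np.sqrt(clean / sched.duration)
        noisy = np.maximum(clean + rng.standard_normal(clean.shape) * sd, 0.0)
    else:
        noisy = clean.copy()

    vs = (cfg.voxel_size_mm,) * 3
    truth = PhantomTruth(
        masks={k: ROIMask(v, label=k) for k, v in masks.items()},
        params=params,
        noise_free=DynamicPETSeries(clean, vs, sched),
        aif=aif,
        config=cfg,
    )
    return DynamicPETSeries(noisy, vs, sched), truth


@dataclass(frozen=True)
class TaceEffect:
    """Multiplicative post-treatment factors on lesion K1 and k3.

    Responder-like defaults: the delivery parameter drops by two thirds
    after embolization; trapping falls more modestly.
    """

    k1_factor: float = 0.34
    k3_factor: float = 0.7

    def __post_init__(self) -> None:
        if not (0.0 < self.k1_factor <= 1.0 and 0.0 < self.k3_factor <= 1.0):
            raise InvalidConfigError("effect factors must lie in (0, 1]")


def simulate_post_tace(config: PhantomConfig, effect: TaceEffect | dict | None = None):
    """Re-simulate the phantom with scaled lesion kinetics (liver unchanged).

    ``effect`` may be a single :class:`TaceEffect` applied to every
    lesion, or a mapping ``{"lesion_1": TaceEffect, ...}``.  The same
    schedule, geometry, noise model and seed are reused, so an all-ones
    effect reproduces the baseline series exactly.
    """
    effect = effect or TaceEffect()
    new_lesions = []
    for i, les in enumerate(config.lesions, start=1):
        eff = effect.get(f"lesion_{i}", TaceEffect(1.0, 1.0)) if isinstance(effect, dict) else effect
        p = les.params
        new_lesions.append(replace(les, params=replace(
            p, K1=p.K1 * eff.k1_factor, k3=p.k3 * eff.k3_factor)))
    return generate_phantom(replace(config, lesions=tuple(new_lesions)))


# ---------------------------------------------------------------------------
# synthetic response cohorts


@dataclass(frozen=True)
class CohortConfig:
    """Statistical structure of a synthetic lesion cohort.

    Baseline rate constants are log-normal around the observed cohort
    means; the treatment effect is a multiplicative K1 (and, for
    responders, k3) reduction — mean fractional K1 reduction 0.66 for
    responders and 0.50 for nonresponders.  The conventional-imaging
    label agrees with the true responder status except with probability
    ``discordance_prob``.
    """

    n_subjects: int = 16
    lesion_count_probs: tuple = (0.65, 0.20, 0.10, 0.05)  # P(1..4 lesions)
    responder_fraction: float = 14.0 / 24.0
    k1_reduction_responders: float = 0.66
    k1_reduction_nonresponders: float = 0.50
    k1_reduction_sd: float = 0.10
    k3_reduction_responders: float = 0.30
    k3_reduction_nonresponders: float = 0.0
    discordance_prob: float = 1.0 / 6.0
    measurement_noise_pct: float = 5.0
    baseline_means: tuple = (0.30, 0.30, 0.13, 0.035, 0.04)  # K1, k2, k3, k4, vb
    baseline_cv: float = 0.45
    seed: int = 20200101

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidConfigError("n_subjects must be >= 1")
        for r in (self.k1_reduction_responders, self.k1_reduction_nonresponders):
            if not (0.0 <= r < 1.0):
                raise InvalidConfigError("K1 reductions must lie in [0, 1)")
        if not (0.0 <= self.discordance_prob <= 1.0):
            raise InvalidConfigError("discordance_prob must lie in [0, 1]")


def _lognormal_around(rng, mean, cv, size=None):
    sigma2 = np.log(1.0 + cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _suv60(params: TwoTissueParams, aif: ArterialInputFunction,
           schedule: FrameSchedule, subject: SubjectInfo, dt: float = 0.05) -> float:
    """Model SUV over the late (50-60 min) window for one tissue."""
    ct = model_on_grid(params, dt, aif.plasma_parent, aif.whole_blood)
    fr = _frame_average_values(aif.times, ct, schedule)
    mid = schedule.mid
    sel = (mid >= 50.0) & (mid <= 60.0)
    if not sel.any():
        sel = mid >= mid[-1] - 10.0
    conc = float(np.average(fr[sel], weights=schedule.duration[sel]))
    return float(compute_suv(np.array(conc), subject))


def generate_cohort(config: CohortConfig | None = None):
    """Sample a synthetic lesion table with ground-truth response labels.

    Returns ``(records, truth)`` where ``records`` is a list of
    :class:`LesionRecord` (flag "synthetic") and ``truth`` a DataFrame
    with per-lesion true responder status, sampled kinetics and effect.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    phantom_cfg = PhantomConfig(noise_coeff=0.0)
    aif = build_aif(phantom_cfg)
    sched = phantom_cfg.schedule
    subj = phantom_cfg.subject
    liver_suv = _suv60(DEFAULT_LIVER, aif, sched, subj)

    m_k1, m_k2, m_k3, m_k4, m_vb = cfg.baseline_means
    records, rows = [], []
    for pid in range(1, cfg.n_subjects + 1):
        n_les = 1 + rng.choice(len(cfg.lesion_count_probs), p=cfg.lesion_count_probs)
        for j in range(n_les):
            K1 = _lognormal_around(rng, m_k1, cfg.baseline_cv)
            k2 = _lognormal_around(rng, m_k2, cfg.baseline_cv)
            k3 = _lognormal_around(rng, m_k3, cfg.baseline_cv)
            k4 = min(_lognormal_around(rng, m_k4, cfg.baseline_cv), 0.49)
            vb = min(_lognormal_around(rng, m_vb, cfg.baseline_cv), 0.3)
            base = TwoTissueParams(K1, k2, k3, k4, vb)

            responder = bool(rng.random() < cfg.responder_fraction)
            mean_red = (cfg.k1_reduction_responders if responder
                        else cfg.k1_reduction_nonresponders)
            k1_red = float(np.clip(rng.normal(mean_red, cfg.k1_reduction_sd), 0.0, 0.95))
            k3_red = (cfg.k3_reduction_responders if responder
                      else cfg.k3_reduction_nonresponders)
            post = replace(base, K1=base.K1 * (1.0 - k1_red),
                           k3=base.k3 * (1.0 - k3_red))

            noise = cfg.measurement_noise_pct / 100.0
            suv_pre = _suv60(base, aif, sched, subj) * (1.0 + noise * rng.standard_normal())
            suv_post = _suv60(post, aif, sched, subj) * (1.0 + noise * rng.standard_normal())
            suv_pre = max(suv_pre, 1e-3)
            pct = 100.0 * (suv_post - suv_pre) / suv_pre
            pct = max(pct, -99.9)
            max_factor = 1.0 + rng.uniform(0.3, 0.7)

            discordant = bool(rng.random() < cfg.discordance_prob)
            mrecist_responder = responder != discordant
            mrecist = ("PR" if mrecist_responder else "SD")

            size = float(np.clip(_lognormal_around(rng, 35.0, 0.6), 10.0, 117.0))
            records.append(LesionRecord(
                patient_id=pid, lesion_location=f"synthetic lesion {j + 1}",
                size_mm=size, visual_uptake="hyperintense",
                background_suv_mean=liver_suv,
                suv60_mean_pre=suv_pre, suv60_max_pre=suv_pre * max_factor,
                mrecist=mrecist, pct_change_mean=pct, pct_change_max=pct,
                pfs_months=None, flag="synthetic",
            ))
            rows.append({"patient_id": pid, "lesion": j + 1,
                         "true_responder": responder, "k1_reduction": k1_red,
                         "K1": K1, "k2": k2, "k3": k3, "k4": base.k4, "vb": base.vb,
                         "suv_pre": suv_pre, "suv_post": suv_post})
    return records, pd.DataFrame(rows)


def cohort_from_crosstab(a: int, b: int, c: int, d: int):
    """Deterministic PET/mRECIST label pairs with an exact 2x2 cross-tab.

    ``a`` lesions respond on both systems, ``b`` on PET only, ``c`` on
    mRECIST only, ``d`` on neither — a direct construction for
    concordance checks.
    """
    pet = ["responder"] * a + ["responder"] * b + ["nonresponder"] * c + ["nonresponder"] * d
    mre = ["responder"] * a + ["nonresponder"] * b + ["responder"] * c + ["nonresponder"] * d
    return pet, mre
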