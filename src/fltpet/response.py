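"""Lesion-level response classification, concordance and cohort statistics.

PET response uses the percentage change in SUV60_mean with an inclusive
20% reduction threshold (a change of exactly -20% counts as response,
the usual radiology convention).  mRECIST categories collapse to
responder (CR/PR) versus nonresponder (SD/PD); NE propagates.
Concordance between the two binary systems is Cohen kappa with a
large-sample confidence interval and z-test p-value.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateTestError,
    InvalidBackgroundError,
    NoDataError,
    SchemaError,
    UndefinedKappaError,
)

__all__ = [
    "ResponseLabel",
    "LesionRecord",
    "KineticRecord",
    "ConcordanceResult",
    "percent_change",
    "pet_response",
    "mrecist_binary",
    "cohen_kappa",
    "cohen_kappa_from_counts",
    "wilcoxon_rank",
    "chi_square_2x2",
    "cohort_summary",
    "pet_mrecist_concordance",
    "load_table1",
    "load_table2",
]

MRECIST_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")
VISUAL_CATEGORIES = ("hyperintense", "isotense", "hypotense", "mixed", "rim")


class ResponseLabel(str, enum.Enum):
    RESPONDER = "responder"
    NONRESPONDER = "nonresponder"
    NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class LesionRecord:
    """One lesion of the clinical table."""

    patient_id: int
    lesion_location: str
    size_mm: float
    visual_uptake: str
    background_suv_mean: float
    suv60_mean_pre: float
    suv60_max_pre: float
    mrecist: str
    pct_change_mean: float | None   # None = not evaluable
    pct_change_max: float | None
    pfs_months: float | None = None
    flag: str = ""

    def __post_init__(self) -> None:
        if not (self.size_mm > 0):
            raise SchemaError(f"patient {self.patient_id}: lesion size must be > 0 mm")
        if self.mrecist not in MRECIST_CATEGORIES:
            raise SchemaError(f"patient {self.patient_id}: unknown mRECIST '{self.mrecist}'")
        if self.visual_uptake not in VISUAL_CATEGORIES:
            raise SchemaError(f"patient {self.patient_id}: unknown visual category")
        for v in (self.pct_change_mean, self.pct_change_max):
            if v is not None and v <= -100:
                raise SchemaError(f"patient {self.patient_id}: percent change <= -100")


@dataclass(frozen=True)
class KineticRecord:
    """One subject of the kinetic table.  vb_raw preserves the printed text."""

    patient_id: int
    K1: float
    k2: float
    k3: float
    k4: float
    vb: float
    vb_raw: str
    ki_printed: float
    flag: str = ""

    @property
    def ki(self) -> float:
        """Ki recomputed from the printed rate constants."""
        denom = self.k2 + self.k3
        return 0.0 if denom == 0.0 else self.K1 * self.k3 / denom

    @property
    def vb_valid(self) -> bool:
        return 0.0 <= self.vb < 1.0


@dataclass(frozen=True)
class ConcordanceResult:
    kappa: float
    ci95: tuple
    p_value: float
    counts: tuple  # (both responders, a-only, b-only, neither)

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.kappa <= 1.0 + 1e-12):
            raise UndefinedKappaError("kappa outside [-1, 1]")


# ---------------------------------------------------------------------------
# elementary response operations


def percent_change(pre: float, post: float) -> float:
    """100 * (post - pre) / pre; the baseline must be positive."""
    if not (pre > 0):
        raise InvalidBackgroundError("baseline value must be > 0")
    return 100.0 * (post - pre) / pre


def pet_response(change_mean, threshold: float = 20.0) -> ResponseLabel:
    """PET response: reduction of at least ``threshold`` percent (inclusive)."""
    if change_mean is None or (isinstance(change_mean, float) and math.isnan(change_mean)):
        return ResponseLabel.NOT_EVALUABLE
    return (ResponseLabel.RESPONDER if float(change_mean) <= -threshold
            else ResponseLabel.NONRESPONDER)


def mrecist_binary(category: str) -> ResponseLabel:
    """CR/PR -> responder, SD/PD -> nonresponder, NE -> not evaluable."""
    if category in ("CR", "PR"):
        return ResponseLabel.RESPONDER
    if category in ("SD", "PD"):
        return ResponseLabel.NONRESPONDER
    if category == "NE":
        return ResponseLabel.NOT_EVALUABLE
    raise SchemaError(f"unknown mRECIST category '{category}'")


# ---------------------------------------------------------------------------
# agreement and group-difference statistics


def cohen_kappa_from_counts(a: int, b: int, c: int, d: int) -> ConcordanceResult:
    """Cohen kappa from a 2x2 agreement table.

    ``a``: both raters positive, ``b``: first only, ``c``: second only,
    ``d``: neither.  CI uses the large-sample standard error
    sqrt(p_o (1 - p_o) / n) / (1 - p_e); the p-value tests kappa = 0 with
    the null standard error.
    """
    n = a + b + c + d
    if n < 2:
        raise DegenerateTestError("need at least 2 paired labels")
    po = (a + d) / n
    p1, q1 = (a + b) / n, (a + c) / n      # positive marginals of each rater
    p2, q2 = 1.0 - p1, 1.0 - q1
    pe = p1 * q1 + p2 * q2
    if pe >= 1.0 - 1e-12:
        raise UndefinedKappaError("degenerate marginals: expected agreement is 1")
    kappa = (po - pe) / (1.0 - pe)
    se = math.sqrt(po * (1.0 - po) / n) / (1.0 - pe)
    ci = (kappa - 1.959963984540054 * se, kappa + 1.959963984540054 * se)
    # null SE (Fleiss): kappa = 0
    num = pe + pe * pe - (p1 * q1 * (p1 + q1) + p2 * q2 * (p2 + q2))
    se0 = math.sqrt(max(num, 0.0)) / ((1.0 - pe) * math.sqrt(n))
    z = kappa / se0 if se0 > 0 else math.inf
    p = 2.0 * stats.norm.sf(abs(z))
    return ConcordanceResult(kappa=kappa, ci95=ci, p_value=p, counts=(a, b, c, d))


def cohen_kappa(labels_a, labels_b) -> ConcordanceResult:
    """Cohen kappa between two equal-length binary label sequences."""
    la, lb = list(labels_a), list(labels_b)
    if len(la) != len(lb):
        raise DegenerateTestError("label sequences must have equal length")
    cats = sorted(set(la) | set(lb), key=str)
    if len(cats) > 2:
        raise DegenerateTestError("kappa here is defined for binary labels")
    pos = cats[0]
    a = sum(1 for x, y in zip(la, lb) if x == pos and y == pos)
    b = sum(1 for x, y in zip(la, lb) if x == pos and y != pos)
    c = sum(1 for x, y in zip(la, lb) if x != pos and y == pos)
    d = len(la) - a - b - c
    return cohen_kappa_from_counts(a, b, c, d)


def wilcoxon_rank(group_a, group_b, paired: bool = False) -> dict:
    """Wilcoxon rank test: signed-rank when paired, rank-sum otherwise.

    Exact small-sample null distributions are used where the data permit.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 3 or b.size < 3:
        raise DegenerateTestError("each group needs at least 3 observations")
    if paired:
        if a.size != b.size:
            raise DegenerateTestError("paired groups must have equal length")
        if np.all(a == b):
            raise DegenerateTestError("all pairwise differences are zero")
        res = stats.wilcoxon(a, b, zero_method="wilcox", method="auto")
    else:
        method = "exact" if (a.size <= 25 and b.size <= 25
                             and np.unique(np.concatenate([a, b])).size
                             == a.size + b.size) else "auto"
        if np.array_equal(np.sort(a), np.sort(b)):
            # identical samples: maximally central statistic
            return {"statistic": float(a.size * b.size / 2), "p_value": 1.0}
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}


def chi_square_2x2(counts, correction: bool = False) -> dict:
    """Pearson chi-square on a 2x2 table (no continuity correction by default)."""
    table = np.asarray(counts, dtype=float).reshape(2, 2)
    if np.any(table < 0):
        raise DegenerateTestError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateTestError("a marginal of the 2x2 table is zero")
    res = stats.chi2_contingency(table, correction=correction)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "dof": int(res.dof)}


# ---------------------------------------------------------------------------
# cohort aggregation


def _evaluable(records):
    return [r for r in records if r.pct_change_mean is not None]


def cohort_summary(records, threshold: float = 20.0) -> dict:
    """Aggregate baseline SUVs, percentage changes and responder counts.

    Not-evaluable entries are excluded column-wise.  The percentage-change
    summary reports both mean and median.
    """
    records = list(records)
    if not records:
        raise NoDataError("no lesion records")
    suv_mean = np.array([r.suv60_mean_pre for r in records])
    suv_max = np.array([r.suv60_max_pre for r in records])
    ev = _evaluable(records)
    if not ev:
        raise NoDataError("no evaluable lesions")
    dmean = np.array([r.pct_change_mean for r in ev])
    dmax = np.array([r.pct_change_max for r in ev if r.pct_change_max is not None])
    pet = [pet_response(r.pct_change_mean, threshold) for r in ev]
    mr = [mrecist_binary(r.mrecist) for r in records]
    mr_ev = [m for m in mr if m is not ResponseLabel.NOT_EVALUABLE]

    def ms(x):
        return {"mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
                "median": float(np.median(x)), "n": int(x.size)}

    return {
        "n_lesions": len(records),
        "suv60_mean_pre": ms(suv_mean),
        "suv60_max_pre": ms(suv_max),
        "pct_change_mean": ms(dmean),
        "pct_change_max": ms(dmax),
        "pet_responders": {"count": sum(p is ResponseLabel.RESPONDER for p in pet),
                           "n": len(pet)},
        "mrecist_responders": {"count": sum(m is ResponseLabel.RESPONDER for m in mr_ev),
                               "n": len(mr_ev)},
    }


def pet_mrecist_concordance(records, threshold: float = 20.0) -> ConcordanceResult:
    """Kappa between PET and mRECIST response over dual-evaluable lesions."""
    pairs = []
    for r in records:
        p = pet_response(r.pct_change_mean, threshold)
        m = mrecist_binary(r.mrecist)
        if ResponseLabel.NOT_EVALUABLE in (p, m):
            continue
        pairs.append((p.value, m.value))
    if len(pairs) < 2:
        raise NoDataError("fewer than 2 dual-evaluable lesions")
    a = sum(1 for p, m in pairs if p == "responder" and m == "responder")
    b = sum(1 for p, m in pairs if p == "responder" and m == "nonresponder")
    c = sum(1 for p, m in pairs if p == "nonresponder" and m == "responder")
    d = len(pairs) - a - b - c
    return cohen_kappa_from_counts(a, b, c, d)


# ---------------------------------------------------------------------------
# fixture loaders


def _read_fixture(path, name):
    if path is not None:
        return pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    with resources.files("fltpet.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#", dtype=str, keep_default_na=False)


def _num(text, row, col, optional=False):
    text = (text or "").strip()
    if text in ("", "NE"):
        if optional:
            return None
        raise SchemaError(f"row {row}: missing required value in '{col}'")
    try:
        return float(text)
    except ValueError as exc:
        raise SchemaError(f"row {row}, column '{col}': cannot parse '{text}'") from exc


def load_table1(path=None) -> list:
    """Load the lesion table (packaged fixture by default)."""
    try:
        df = _read_fixture(path, "table1_lesions.csv")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError("lesion table is empty") from exc
    required = {"patient_id", "lesion_location", "size_mm", "visual_uptake",
                "background_suv_mean", "suv60_mean_pre", "suv60_max_pre",
                "mrecist", "pct_change_mean", "pct_change_max"}
    if not required.issubset(df.columns):
        raise SchemaError(f"lesion table missing columns {sorted(required - set(df.columns))}")
    records = []
    for i, row in df.iterrows():
        records.append(LesionRecord(
            patient_id=int(_num(row["patient_id"], i, "patient_id")),
            lesion_location=row["lesion_location"],
            size_mm=_num(row["size_mm"], i, "size_mm"),
            visual_uptake=row["visual_uptake"],
            background_suv_mean=_num(row["background_suv_mean"], i, "background_suv_mean"),
            suv60_mean_pre=_num(row["suv60_mean_pre"], i, "suv60_mean_pre"),
            suv60_max_pre=_num(row["suv60_max_pre"], i, "suv60_max_pre"),
            mrecist=row["mrecist"],
            pct_change_mean=_num(row["pct_change_mean"], i, "pct_change_mean", optional=True),
            pct_change_max=_num(row["pct_change_max"], i, "pct_change_max", optional=True),
            pfs_months=_num(row.get("pfs_months", ""), i, "pfs_months", optional=True),
            flag=row.get("flag", "") or "",
        ))
    if not records:
        raise SchemaError("lesion table has no data rows")
    return records


def load_table2(path=None) -> list:
    """Load the kinetic table; verbatim oddities keep a quality flag."""
    try:
        df = _read_fixture(path, "table2_kinetics.csv")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError("kinetic table is empty") from exc
    required = {"patient_id", "K1", "k2", "k3", "k4", "vb", "ki_printed"}
    if not required.issubset(df.columns):
        raise SchemaError(f"kinetic table missing columns {sorted(required - set(df.columns))}")
    records = []
    for i, row in df.iterrows():
        vb_raw = row["vb"].strip()
        records.append(KineticRecord(
            patient_id=int(_num(row["patient_id"], i, "patient_id")),
            K1=_num(row["K1"], i, "K1"),
            k2=_num(row["k2"], i, "k2"),
            k3=_num(row["k3"], i, "k3"),
            k4=_num(row["k4"], i, "k4"),
            vb=_num(vb_raw, i, "vb"),
            vb_raw=vb_raw,
            ki_printed=_num(row["ki_printed"], i, "ki_printed"),
            flag=row.get("flag", "") or "",
        ))
    if not records:
        raise SchemaError("kinetic table has no data rows")
    return records
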