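"""Data model and basic computations for extended OGTT records.

An extended OGTT here means a 75 g oral glucose load with two fasting
draws (nominally -10 and -1 min) and frequent sampling out to 180 min
(nominally 10, 20, 30, 45, 60, 90, 120, 150, 180 min), with glucose in
mmol/l and insulin and C-peptide in pmol/l.  Any grid with at least eight
points and a fasting anchor is accepted.

Glucose tolerance is classified from the 1 h and 2 h samples into the
four-group ladder used in pancreatic-insufficient cystic fibrosis:
NGT < EGI < IGT < CFRD, where EGI (early glucose intolerance) is an
isolated 1 h elevation with a normal 2 h value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANALYTES",
    "TOLERANCE_LABELS",
    "MGDL_PER_MMOLL",
    "PMOLL_PER_MUUML",
    "ToleranceStatus",
    "Subject",
    "OgttSeries",
    "classify_tolerance",
    "classify_series",
    "tolerance_shares",
    "basal_value",
    "trapezoid_auc",
    "series_auc",
    "read_cohort",
    "write_cohort",
]

ANALYTES = ("glucose", "insulin", "cpeptide")
TOLERANCE_LABELS = ("NGT", "EGI", "IGT", "CFRD")

#: fixed unit conversions: glucose mg/dl = mmol/l * 18.016; insulin
#: uU/ml = pmol/l / 6.0
MGDL_PER_MMOLL = 18.016
PMOLL_PER_MUUML = 6.0

_UNIT_FACTORS = {
    # analyte -> {declared unit -> multiplier into canonical unit}
    "glucose": {"mmol/l": 1.0, "mg/dl": 1.0 / MGDL_PER_MMOLL},
    "insulin": {"pmol/l": 1.0, "uU/ml": PMOLL_PER_MUUML, "µU/ml": PMOLL_PER_MUUML},
    "cpeptide": {"pmol/l": 1.0, "nmol/l": 1000.0},
}


class SchemaError(ValueError):
    """A cohort file does not match the declared schema."""


class RecordError(ValueError):
    """A single subject's record violates an invariant."""


@dataclass(frozen=True, order=True)
class ToleranceStatus:
    """Glucose tolerance group with its ordinal position NGT<EGI<IGT<CFRD."""

    ordinal_code: int
    label: str

    def __post_init__(self):
        if self.label not in TOLERANCE_LABELS:
            raise ValueError(f"unknown tolerance label {self.label!r}")
        if TOLERANCE_LABELS[self.ordinal_code] != self.label:
            raise ValueError("ordinal_code inconsistent with label")

    @classmethod
    def from_label(cls, label: str) -> "ToleranceStatus":
        return cls(TOLERANCE_LABELS.index(label), label)


def classify_tolerance(g60: float, g120: float) -> ToleranceStatus:
    """Classify glucose tolerance from the 1 h and 2 h OGTT glucose (mmol/l).

    CFRD: 2 h >= 11.1; IGT: 2 h in [7.8, 11.1); otherwise EGI when
    1 h >= 8.6 and NGT when 1 h < 8.6.  The 2 h criterion dominates, so
    IGT/CFRD are assigned regardless of the 1 h value.
    """
    if not (np.isfinite(g60) and np.isfinite(g120)) or g60 <= 0 or g120 <= 0:
        raise ValueError("classification needs positive 1 h and 2 h glucose")
    if g120 >= 11.1:
        return ToleranceStatus.from_label("CFRD")
    if g120 >= 7.8:
        return ToleranceStatus.from_label("IGT")
    if g60 >= 8.6:
        return ToleranceStatus.from_label("EGI")
    return ToleranceStatus.from_label("NGT")


@dataclass
class Subject:
    """Covariates carried alongside one OGTT record."""

    subject_id: str
    age: float
    sex: str  # "female" | "male"
    height: float  # cm
    weight: float  # kg
    bmi: float | None = None
    insulin_treated: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.age is not None and np.isfinite(self.age) and not self.age > 0:
            raise ValueError(f"{self.subject_id}: age must be positive")
        if self.sex not in ("female", "male"):
            raise ValueError(f"{self.subject_id}: sex must be female/male")
        have_hw = (
            self.height is not None and self.weight is not None
            and np.isfinite(self.height) and np.isfinite(self.weight)
        )
        if self.bmi is None and have_hw:
            self.bmi = self.weight / (self.height / 100.0) ** 2
        elif self.bmi is not None and np.isfinite(self.bmi) and have_hw:
            implied = self.weight / (self.height / 100.0) ** 2
            if abs(implied - self.bmi) > 0.05 * self.bmi:
                raise ValueError(
                    f"{self.subject_id}: BMI {self.bmi:.1f} inconsistent with "
                    f"height/weight (implied {implied:.1f})"
                )

    @property
    def bsa(self) -> float:
        """Body surface area (m^2), DuBois & DuBois."""
        return 0.007184 * self.height ** 0.725 * self.weight ** 0.425


@dataclass
class OgttSeries:
    """One subject's sampled OGTT trajectories.

    Missing samples are represented as NaN and flagged; times are minutes
    relative to glucose ingestion (negative = fasting).
    """

    subject_id: str
    times: np.ndarray
    glucose: np.ndarray
    insulin: np.ndarray
    cpeptide: np.ndarray
    dose_grams: float = 75.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        for name in ANALYTES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.times.shape:
                raise RecordError(
                    f"{self.subject_id}: {name} must have one value per time point"
                )
            if np.any(arr[np.isfinite(arr)] <= 0):
                raise RecordError(f"{self.subject_id}: non-positive {name} value")
            setattr(self, name, arr)
        if self.times.ndim != 1 or self.times.size < 2:
            raise RecordError(f"{self.subject_id}: need at least two time points")
        if np.any(np.diff(self.times) <= 0):
            raise RecordError(f"{self.subject_id}: times must be strictly increasing")
        if not np.any(self.times < 0):
            raise RecordError(f"{self.subject_id}: no fasting (t<0) sample")
        if self.dose_grams <= 0:
            raise RecordError(f"{self.subject_id}: glucose dose must be positive")

    def analyte(self, name: str) -> np.ndarray:
        if name not in ANALYTES:
            raise KeyError(name)
        return getattr(self, name)

    def value_at(self, name: str, t: float, interpolate: bool = False) -> float:
        """Sample value at time t; optionally linearly interpolated."""
        vals = self.analyte(name)
        hit = np.flatnonzero(np.isclose(self.times, t))
        if hit.size and np.isfinite(vals[hit[0]]):
            return float(vals[hit[0]])
        if not interpolate:
            raise RecordError(f"{self.subject_id}: no {name} sample at t={t}")
        ok = np.isfinite(vals)
        if ok.sum() < 2 or t < self.times[ok][0] or t > self.times[ok][-1]:
            raise RecordError(f"{self.subject_id}: cannot interpolate {name} at t={t}")
        return float(np.interp(t, self.times[ok], vals[ok]))

    def flags(self) -> list[str]:
        """Data-quality flags that do not invalidate the record."""
        out = []
        if (self.times < 0).sum() < 2:
            out.append("single fasting sample")
        for name in ANALYTES:
            miss = int(np.sum(~np.isfinite(self.analyte(name))))
            if miss:
                out.append(f"{miss} missing {name} value(s)")
        return out


def basal_value(series: OgttSeries, analyte: str) -> float:
    """Basal concentration: arithmetic mean of all fasting (t<0) samples."""
    mask = (series.times < 0) & np.isfinite(series.analyte(analyte))
    if not mask.any():
        raise RecordError(f"{series.subject_id}: no fasting {analyte} sample")
    return float(series.analyte(analyte)[mask].mean())


def trapezoid_auc(times: Sequence[float], values: Sequence[float]) -> float:
    """Total area under the curve by the trapezoid rule (conc * min)."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("AUC needs at least two points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if not np.all(np.isfinite(v)):
        raise ValueError("AUC values must be finite")
    return float(np.trapezoid(v, t))


def series_auc(series: OgttSeries, analyte: str, start: float = 0.0,
               end: float | None = None) -> float:
    """Total AUC of one analyte over the post-dose window [start, end].

    The value at the window edges is linearly interpolated from the
    bracketing samples (for start=0 that is between the -1 and 10 min
    draws), so the fasting anchor is included without extrapolation.
    Missing interior samples are linearly interpolated.
    """
    t = series.times
    v = series.analyte(analyte)
    ok = np.isfinite(v)
    if ok.sum() < 2:
        raise RecordError(f"{series.subject_id}: too few {analyte} samples for AUC")
    tt, vv = t[ok], v[ok]
    if end is None:
        end = float(tt[-1])
    if start < tt[0] or end > tt[-1]:
        raise RecordError(f"{series.subject_id}: AUC window outside sampled range")
    grid = np.unique(np.concatenate([[start, end], tt[(tt > start) & (tt < end)]]))
    vals = np.interp(grid, tt, vv)
    return trapezoid_auc(grid, vals)


def classify_series(series: OgttSeries) -> ToleranceStatus:
    """Tolerance status from the 60 and 120 min glucose samples."""
    g60 = series.value_at("glucose", 60.0)
    g120 = series.value_at("glucose", 120.0)
    return classify_tolerance(g60, g120)


def tolerance_shares(counts: Mapping[str, int]) -> dict[str, int]:
    """Group shares as whole percentages of the cohort (reporting convention:
    rounded to the nearest integer percent)."""
    total = sum(int(counts.get(k, 0)) for k in TOLERANCE_LABELS)
    if total <= 0:
        raise ValueError("empty cohort")
    return {
        k: int(round(100.0 * counts.get(k, 0) / total)) for k in TOLERANCE_LABELS
    }


# ---------------------------------------------------------------------------
# cohort I/O

DEFAULT_SCHEMA: dict = {
    "layout": "long",  # "long": subject_id,time,analyte,value ; "wide": one
    # column per analyte
    "units": {"glucose": "mmol/l", "insulin": "pmol/l", "cpeptide": "pmol/l"},
    "dose_grams": 75.0,
}

_COVARIATE_COLS = ("age", "sex", "height", "weight", "bmi", "insulin_treated")


def _unit_factor(analyte: str, unit: str) -> float:
    try:
        return _UNIT_FACTORS[analyte][unit]
    except KeyError:
        raise SchemaError(f"unsupported unit {unit!r} for {analyte}") from None


def read_cohort(path, schema: Mapping | None = None):
    """Read a delimited cohort file into (Subject, OgttSeries) pairs.

    Returns ``(records, report)`` where ``report`` collects per-subject
    flags and hard errors (subjects with errors are dropped, not raised,
    so one bad record cannot sink a cohort load).
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip() for c in df.columns]

    layout = schema["layout"]
    if layout == "long":
        required = {"subject_id", "time", "analyte", "value"}
    elif layout == "wide":
        required = {"subject_id", "time"} | set(ANALYTES)
    else:
        raise SchemaError(f"unknown layout {layout!r}")
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing mandatory column(s): {sorted(missing)}")

    if layout == "long":
        bad = set(df["analyte"].unique()) - set(ANALYTES)
        if bad:
            raise SchemaError(f"unknown analyte(s) {sorted(bad)}")
        wide = df.pivot_table(
            index=["subject_id", "time"], columns="analyte", values="value",
            aggfunc="first",
        ).reset_index()
        counts = df.groupby(["subject_id", "time", "analyte"]).size()
        dupes = counts[counts > 1]
        cov = None
    else:
        wide = df
        dup_mask = df.duplicated(["subject_id", "time"], keep=False)
        dupes = df.loc[dup_mask, ["subject_id", "time"]]
        cov = df
    records = []
    report: dict = {"n_read": 0, "flags": {}, "errors": {}}
    for sid, sub in wide.groupby("subject_id", sort=False):
        sid = str(sid)
        try:
            if len(dupes) and (
                sid in set(map(str, np.atleast_1d(dupes.reset_index()["subject_id"])))
            ):
                raise RecordError(f"{sid}: duplicated time point")
            sub = sub.sort_values("time")
            times = sub["time"].to_numpy(dtype=float)
            if np.any(np.diff(times) <= 0):
                raise RecordError(f"{sid}: non-increasing times")
            arrays = {}
            for name in ANALYTES:
                fac = _unit_factor(name, schema["units"].get(name, "pmol/l"))
                col = sub[name] if name in sub else pd.Series(np.nan, index=sub.index)
                arrays[name] = col.to_numpy(dtype=float) * fac
            series = OgttSeries(
                subject_id=sid, times=times, dose_grams=schema["dose_grams"],
                **arrays,
            )
            subject = _subject_from_rows(sid, sub if cov is not None else None)
            flags = series.flags()
            if flags:
                report["flags"][sid] = flags
            records.append((subject, series))
            report["n_read"] += 1
        except (RecordError, ValueError) as exc:
            report["errors"][sid] = str(exc)
    return records, report


def _subject_from_rows(sid: str, rows: pd.DataFrame | None) -> Subject:
    if rows is None or not set(_COVARIATE_COLS) & set(rows.columns):
        # covariates absent: placeholder adult so model code that needs
        # anthropometry fails loudly rather than silently
        return Subject(sid, age=np.nan, sex="female", height=np.nan,
                       weight=np.nan, bmi=None)
    first = rows.iloc[0]
    extra = {
        c: first[c]
        for c in rows.columns
        if c not in _COVARIATE_COLS + ("subject_id", "time") + ANALYTES
    }
    return Subject(
        subject_id=sid,
        age=float(first.get("age", np.nan)),
        sex=str(first.get("sex", "female")),
        height=float(first.get("height", np.nan)),
        weight=float(first.get("weight", np.nan)),
        bmi=float(first["bmi"]) if "bmi" in rows and np.isfinite(first["bmi"]) else None,
        insulin_treated=bool(first.get("insulin_treated", False)),
        extra=extra,
    )


def write_cohort(records: Iterable[tuple[Subject, OgttSeries]], path,
                 report: Mapping | None = None) -> pd.DataFrame:
    """Write a normalised wide-layout cohort CSV (canonical units)."""
    rows = []
    for subject, series in records:
        for i, t in enumerate(series.times):
            rows.append(
                {
                    "subject_id": series.subject_id,
                    "time": t,
                    "glucose": series.glucose[i],
                    "insulin": series.insulin[i],
                    "cpeptide": series.cpeptide[i],
                    "age": subject.age,
                    "sex": subject.sex,
                    "height": subject.height,
                    "weight": subject.weight,
                    "bmi": subject.bmi,
                    "insulin_treated": subject.insulin_treated,
                    **subject.extra,
                }
            )
    df = pd.DataFrame(rows)
    path = Path(path)
    df.to_csv(path, index=False)
    if report is not None:
        with open(path.with_suffix(".report.json"), "w") as fh:
            json.dump(dict(report), fh, indent=2, default=str)
    return df
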