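"""Closed-form OGTT indices: HOMA-IR, Matsuda, Stumvoll, AUC clearance ratio.

These are the "simple" counterparts of the model-based estimates: HOMA-IR
tracks hepatic insulin resistance from fasting values, the Matsuda index
whole-body insulin sensitivity from a five-sample profile, the Stumvoll
index peripheral sensitivity from a demographics-free linear formula, and
the C-peptide/insulin AUC ratio is the traditional rough estimate of
insulin clearance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    MGDL_PER_MMOLL,
    PMOLL_PER_MUUML,
    OgttSeries,
    Subject,
    basal_value,
    series_auc,
)

__all__ = ["IndexPanel", "homa_ir", "matsuda", "stumvoll",
           "auc_clearance_ratio", "index_panel", "index_table"]

log = logging.getLogger(__name__)

MATSUDA_TIMES = (-1.0, 30.0, 60.0, 90.0, 120.0)


@dataclass(frozen=True)
class IndexPanel:
    subject_id: str
    homa_ir: float
    matsuda: float
    stumvoll: float
    auc_clearance_ratio: float


def homa_ir(g_fast: float, i_fast: float) -> float:
    """HOMA-IR from fasting glucose (mmol/l) and insulin (uU/ml)."""
    if not (g_fast > 0 and i_fast > 0):
        raise ValueError("HOMA-IR needs positive fasting glucose and insulin")
    return g_fast * i_fast / 22.5


def matsuda(series: OgttSeries) -> float:
    """Matsuda whole-body sensitivity index from the -1, 30, 60, 90 and
    120 min samples.

    10000 / sqrt(Gf * If * Gmean * Imean) with glucose in mg/dl and
    insulin in uU/ml; the fasting anchor is the -1 min sample and the
    means run over the five listed samples.  Missing interior samples are
    linearly interpolated with a logged warning.
    """
    g, ins = [], []
    for t in MATSUDA_TIMES:
        try:
            gv = series.value_at("glucose", t)
            iv = series.value_at("insulin", t)
        except Exception:
            gv = series.value_at("glucose", t, interpolate=True)
            iv = series.value_at("insulin", t, interpolate=True)
            log.warning("%s: Matsuda sample at t=%g interpolated",
                        series.subject_id, t)
        g.append(gv * MGDL_PER_MMOLL)
        ins.append(iv / PMOLL_PER_MUUML)
    g = np.asarray(g)
    ins = np.asarray(ins)
    return float(10000.0 / np.sqrt(g[0] * ins[0] * g.mean() * ins.mean()))


def stumvoll(bmi: float, i120: float, g90: float) -> float:
    """Stumvoll OGTT insulin sensitivity index (demographics-free variant).

    0.226 - 0.0032*BMI - 0.0000645*I120 - 0.0037*G90 with insulin at
    120 min in pmol/l and glucose at 90 min in mmol/l.  May be <= 0 for
    extreme inputs and is then reported as-is.
    """
    if bmi < 0 or i120 < 0 or g90 < 0:
        raise ValueError("Stumvoll index inputs must be nonnegative")
    return 0.226 - 0.0032 * bmi - 0.0000645 * i120 - 0.0037 * g90


def auc_clearance_ratio(series: OgttSeries) -> float:
    """Total AUC of C-peptide over total AUC of insulin (dimensionless)."""
    auc_cp = series_auc(series, "cpeptide")
    auc_ins = series_auc(series, "insulin")
    if auc_ins <= 0:
        raise ValueError(f"{series.subject_id}: zero insulin AUC")
    return auc_cp / auc_ins


def index_panel(subject: Subject, series: OgttSeries) -> IndexPanel:
    """All four indices for one subject."""
    gb = basal_value(series, "glucose")
    ib = basal_value(series, "insulin")
    return IndexPanel(
        subject_id=series.subject_id,
        homa_ir=homa_ir(gb, ib / PMOLL_PER_MUUML),
        matsuda=matsuda(series),
        stumvoll=stumvoll(
            subject.bmi,
            series.value_at("insulin", 120.0, interpolate=True),
            series.value_at("glucose", 90.0, interpolate=True),
        ),
        auc_clearance_ratio=auc_clearance_ratio(series),
    )


def index_table(records) -> pd.DataFrame:
    """Per-subject index table for a cohort of (Subject, OgttSeries)."""
    rows = []
    for subject, series in records:
        try:
            rows.append(vars(index_panel(subject, series)))
        except Exception as exc:  # keep going; one subject must not sink a run
            log.warning("%s: index computation failed: %s", series.subject_id, exc)
            rows.append({"subject_id": series.subject_id})
    return pd.DataFrame(rows)
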