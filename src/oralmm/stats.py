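"""Group-level statistics for minimal-model outcomes.

Mirrors the analysis conventions of cross-sectional OGTT studies:
heteroskedasticity-robust (HC3) linear models with the glucose tolerance
group either categorical (marginal means, pairwise contrasts) or ordinal
(trend tests), log transforms with back-transformed geometric means for
positively skewed outcomes, the disposition-index product and its
reciprocal-hyperbola group fit, Spearman comparisons of simple indices
against modelled sensitivity, and per-predictor association models with
fixed adjustment sets.

No multiplicity adjustment is applied across pairwise contrasts; the
p-values are reported as-is and significance flags use 0.05 two-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .core import TOLERANCE_LABELS

__all__ = [
    "DispositionResult",
    "GroupComparison",
    "AssociationEstimate",
    "disposition_index",
    "fit_hyperbola",
    "group_compare",
    "trend_test",
    "spearman",
    "association_models",
]

log = logging.getLogger(__name__)

ROBUST_COV = "HC3"  # small-sample-adjusted sandwich covariance


@dataclass
class DispositionResult:
    """Per-subject disposition indices and per-group hyperbola coefficients.

    di is phi_total * SI on the printed scales: 10^-9 min^-1 times
    10^-4 pmol^-1 l^-1 min^-1 gives 10^-13 pmol^-1 l^-1 min^-2.
    """

    di: np.ndarray
    beta_by_group: dict = field(default_factory=dict)


# exponent bookkeeping for the printed disposition-index scale
_PHI_SCALE_EXP = -9
_SI_SCALE_EXP = -4
_DI_SCALE_EXP = -13
assert _PHI_SCALE_EXP + _SI_SCALE_EXP == _DI_SCALE_EXP


def disposition_index(phi_total, si) -> np.ndarray:
    """Elementwise product of phi_total (10^-9 min^-1 scale) and insulin
    sensitivity (10^-4 scale), giving the 10^-13 disposition scale."""
    phi = np.asarray(phi_total, dtype=float)
    s = np.asarray(si, dtype=float)
    if np.any(phi[np.isfinite(phi)] < 0) or np.any(s[np.isfinite(s)] < 0):
        raise ValueError("disposition index inputs must be nonnegative")
    return phi * s


def fit_hyperbola(si, phi_total) -> float:
    """Least-squares beta for phi_total = beta / SI (asymptotes at zero).

    Minimising sum_i (phi_i - beta/si_i)^2 gives the closed form
    beta = sum(phi_i/si_i) / sum(1/si_i^2).
    """
    s = np.asarray(si, dtype=float)
    p = np.asarray(phi_total, dtype=float)
    ok = np.isfinite(s) & np.isfinite(p)
    s, p = s[ok], p[ok]
    if s.size < 1:
        raise ValueError("hyperbola fit needs at least one point")
    if np.any(s <= 0):
        raise ValueError("hyperbola fit needs si > 0")
    return float(np.sum(p / s) / np.sum(1.0 / s ** 2))


@dataclass
class GroupComparison:
    outcome: str
    transform: str  # "none" | "log"
    table: pd.DataFrame  # group, n, mean, ci_lo, ci_hi (back-transformed)
    pairwise: pd.DataFrame  # group_a, group_b, estimate, p, significant
    trend_slope: float
    trend_p: float
    trend_p_raw: float  # trend on the untransformed scale, secondary


def _robust_ols(y: np.ndarray, X: np.ndarray):
    model = sm.OLS(y, X)
    return model.fit(cov_type=ROBUST_COV)


def group_compare(values, groups, transform: str = "none",
                  outcome: str = "outcome") -> GroupComparison:
    """Marginal means with robust 95 % CIs and all pairwise contrasts.

    Saturated linear model on the (optionally log-transformed) outcome
    with group indicators, HC3 covariance and t-reference inference;
    log-scale results are back-transformed to geometric means.  Groups
    with fewer than two subjects are excluded with a warning.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    ok = np.isfinite(v)
    if transform == "log":
        ok &= v > 0
    v, g = v[ok], g[ok]
    labels = [lab for lab in TOLERANCE_LABELS if np.sum(g == lab) > 0]
    labels += [lab for lab in pd.unique(g) if lab not in labels]
    keep = []
    for lab in labels:
        n_g = int(np.sum(g == lab))
        if n_g < 2:
            log.warning("group %s has %d subject(s); excluded from %s",
                        lab, n_g, outcome)
        else:
            keep.append(lab)
    if len(keep) < 2:
        raise ValueError("need at least two groups with >=2 subjects")
    mask = np.isin(g, keep)
    v, g = v[mask], g[mask]
    y = np.log(v) if transform == "log" else v

    X = np.column_stack([(g == lab).astype(float) for lab in keep])
    res = _robust_ols(y, X)
    df_resid = res.df_resid
    tcrit = sps.t.ppf(0.975, df_resid)
    means = res.params
    ses = res.bse
    lo, hi = means - tcrit * ses, means + tcrit * ses
    back = np.exp if transform == "log" else (lambda x: x)
    table = pd.DataFrame({
        "group": keep,
        "n": [int(np.sum(g == lab)) for lab in keep],
        "mean": back(means),
        "ci_lo": back(lo),
        "ci_hi": back(hi),
    })

    cov = res.cov_params()
    rows = []
    for i in range(len(keep)):
        for j in range(i + 1, len(keep)):
            diff = means[i] - means[j]
            se = np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j])
            tstat = diff / se if se > 0 else 0.0
            p = 2 * sps.t.sf(abs(tstat), df_resid) if se > 0 else 1.0
            rows.append({
                "group_a": keep[i], "group_b": keep[j],
                "estimate": back(diff) if transform == "log" else diff,
                "p": p, "significant": bool(p < 0.05),
            })
    pairwise = pd.DataFrame(rows)

    codes = np.array([TOLERANCE_LABELS.index(lab) if lab in TOLERANCE_LABELS
                      else keep.index(lab) for lab in g], dtype=float)
    slope, trend_p = _linear_trend(y, codes)
    _, trend_p_raw = _linear_trend(v, codes)
    return GroupComparison(outcome=outcome, transform=transform, table=table,
                           pairwise=pairwise, trend_slope=slope,
                           trend_p=trend_p, trend_p_raw=trend_p_raw)


def _linear_trend(y: np.ndarray, codes: np.ndarray):
    if np.ptp(y) == 0 or np.ptp(codes) == 0:
        return 0.0, 1.0
    X = sm.add_constant(codes)
    res = _robust_ols(y, X)
    t = res.params[1] / res.bse[1]
    p = 2 * sps.t.sf(abs(t), res.df_resid)
    return float(res.params[1]), float(p)


def trend_test(values, ordinal_codes, family: str = "linear"):
    """Single-slope regression of an outcome on the ordinal group code.

    ``family='linear'`` uses OLS with HC3 robust SEs and a t-reference
    Wald test; ``family='logistic'`` fits a logit model with the usual
    MLE covariance.  A constant outcome returns p = 1 by convention.

    Returns ``(slope, p)``.
    """
    v = np.asarray(values, dtype=float)
    c = np.asarray(ordinal_codes, dtype=float)
    ok = np.isfinite(v) & np.isfinite(c)
    v, c = v[ok], c[ok]
    if np.unique(c).size < 3:
        raise ValueError("trend test needs >=3 distinct ordinal levels")
    if np.ptp(v) == 0:
        log.warning("constant outcome in trend test; p=1 by convention")
        return 0.0, 1.0
    if family == "linear":
        return _linear_trend(v, c)
    if family == "logistic":
        uniq = set(np.unique(v))
        if not uniq <= {0.0, 1.0}:
            raise ValueError("logistic trend needs a 0/1 outcome")
        X = sm.add_constant(c)
        try:
            res = sm.Logit(v, X).fit(disp=0)
            return float(res.params[1]), float(res.pvalues[1])
        except Exception as exc:  # separation etc.
            log.warning("logistic trend failed (%s); p=1", exc)
            return np.nan, 1.0
    raise ValueError(f"unknown family {family!r}")


def spearman(x, y):
    """Spearman rank correlation with midranks for ties; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("Spearman needs at least 4 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class AssociationEstimate:
    outcome: str
    predictor: str
    adjustment: str  # "minimal" | "multivariable"
    slope: float
    ci_lo: float
    ci_hi: float
    p: float
    n: int


#: adjustment sets: minimal adds BMI; multivariable adds BMI, age, sex and
#: modelled insulin sensitivity; a covariate identical to the predictor is
#: dropped from its own adjustment set
ADJUSTMENT_SETS = {
    "minimal": ("bmi",),
    "multivariable": ("bmi", "age", "sex_female", "si"),
}


def association_models(outcome: pd.Series, predictors: pd.DataFrame,
                       covariates: pd.DataFrame,
                       adjustment: str = "minimal",
                       outcome_name: str = "clearance_n",
                       min_n: int = 10) -> list[AssociationEstimate]:
    """One robust-SE linear model per predictor (not a joint model).

    ``covariates`` must contain the adjustment columns (bmi, and for the
    multivariable set also age, sex_female, si).  Constant or collinear
    adjustment columns are dropped with a warning.
    """
    adj_cols = ADJUSTMENT_SETS[adjustment]
    out = []
    for name in predictors.columns:
        x = predictors[name].astype(float)
        frame = pd.concat([outcome.rename("_y"), x.rename("_x")], axis=1)
        used = []
        for c in adj_cols:
            if c == name or (c in predictors and
                             predictors[c].equals(predictors[name])):
                log.warning("%s: predictor adjusted for itself; dropping %s",
                            name, c)
                continue
            if c not in covariates:
                log.warning("adjustment covariate %s missing; dropped", c)
                continue
            frame[c] = covariates[c].astype(float)
            used.append(c)
        frame = frame.dropna()
        if len(frame) < min_n:
            log.warning("%s: only %d complete rows; model skipped",
                        name, len(frame))
            continue
        dropped = [c for c in used if np.ptp(frame[c].to_numpy()) == 0]
        for c in dropped:
            log.warning("%s: constant adjustment covariate %s dropped", name, c)
        used = [c for c in used if c not in dropped]
        X = sm.add_constant(frame[["_x"] + used].to_numpy())
        try:
            res = _robust_ols(frame["_y"].to_numpy(), X)
        except Exception as exc:
            log.warning("%s: association model failed (%s)", name, exc)
            continue
        tcrit = sps.t.ppf(0.975, res.df_resid)
        slope, se = res.params[1], res.bse[1]
        p = 2 * sps.t.sf(abs(slope / se), res.df_resid) if se > 0 else 1.0
        out.append(AssociationEstimate(
            outcome=outcome_name, predictor=name, adjustment=adjustment,
            slope=float(slope), ci_lo=float(slope - tcrit * se),
            ci_hi=float(slope + tcrit * se), p=float(p), n=len(frame),
        ))
    return out
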