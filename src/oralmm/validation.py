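"""Whole-pipeline validation studies: recovery, calibration, reproduction.

These are the package's main evidence that the estimation machinery works
under its stated study conditions: simulate-then-fit parameter recovery
on synthetic cohorts, type-I-error calibration of the robust group
statistics under a simulated null, and reproduction of the qualitative
group orderings (secretion collapse in CFRD, monotone sensitivity
decline, elevated clearance in CFRD) across replicate cohorts.  The same
functions back ``scripts/acceptance.py`` and the acceptance tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .clearance import fit_clearance
from .cohort import default_cf_config, generate_cohort
from .core import TOLERANCE_LABELS
from .pipeline import fit_cohort
from .secretion import fit_secretion, vancauter_kinetics
from .sensitivity import fit_omm, ra_auc_target
from .stats import group_compare, trend_test

__all__ = ["recovery_study", "null_calibration", "qualitative_study",
           "oracle_checks"]

log = logging.getLogger(__name__)

#: group sizes of the recovery studies (40 subjects spanning all strata)
RECOVERY_SIZES = {"NGT": 10, "EGI": 10, "IGT": 10, "CFRD": 10}


def _child_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2 ** 31))


def recovery_study(seed: int = 0, noise: bool = True,
                   group_sizes: dict | None = None,
                   n_starts: int = 1) -> pd.DataFrame:
    """Simulate-then-fit study: one row per subject with true and fitted
    parameters plus convergence flags and the Ra-area deviation."""
    cfg = default_cf_config()
    cfg.group_sizes = dict(group_sizes or RECOVERY_SIZES)
    recs = generate_cohort(cfg, seed=seed, noise=noise)
    rows = []
    for subject, series, truth in recs:
        row = {f"true_{k}": v for k, v in truth.items()
               if np.isscalar(v) or isinstance(v, str)}
        row["subject_id"] = truth["subject_id"]
        try:
            kin = vancauter_kinetics(
                subject, diabetic=(truth["group_true"] == "CFRD"))
            sec, sec_fit = fit_secretion(series, kin, n_starts=n_starts)
            row.update(est_phi_d=sec.phi_d, est_phi_s=sec.phi_s,
                       est_tau=sec.tau, est_phi_total=sec.phi_total,
                       secretion_converged=sec_fit.converged)
        except Exception as exc:
            log.warning("%s: secretion fit failed: %s", series.subject_id, exc)
            row["secretion_converged"] = False
            sec, kin = None, None
        try:
            omm, omm_fit = fit_omm(series, subject.weight, n_starts=n_starts)
            target = ra_auc_target(series.dose_grams, subject.weight)
            row.update(est_si=omm.si, est_sg=omm.sg, est_p2=omm.p2,
                       est_v=omm.v, ra_auc=omm.ra_auc(), ra_target=target,
                       ra_dev_pct=100.0 * abs(omm.ra_auc() - target) / target,
                       omm_converged=omm_fit.converged)
        except Exception as exc:
            log.warning("%s: sensitivity fit failed: %s", series.subject_id, exc)
            row["omm_converged"] = False
        if sec is not None and row.get("secretion_converged"):
            try:
                clr, clr_fit = fit_clearance(series, sec, kin, subject.weight,
                                             n_starts=n_starts)
                row.update(est_clearance_n=clr.clearance_n, est_he=clr.he,
                           clearance_converged=clr_fit.converged)
            except Exception as exc:
                log.warning("%s: clearance fit failed: %s",
                            series.subject_id, exc)
                row["clearance_converged"] = False
        else:
            row["clearance_converged"] = False
        rows.append(row)
    return pd.DataFrame(rows)


def recovery_errors(study: pd.DataFrame) -> dict:
    """Relative-error summaries of a recovery study, per parameter."""
    out = {}
    pairs = {
        "si": ("est_si", "true_si", "omm_converged"),
        "phi_d": ("est_phi_d", "true_phi_d", "secretion_converged"),
        "phi_s": ("est_phi_s", "true_phi_s", "secretion_converged"),
        "phi_total": ("est_phi_total", "true_phi_total", "secretion_converged"),
        "clearance_n": ("est_clearance_n", "true_clearance_n",
                        "clearance_converged"),
        "he": ("est_he", "true_he", "clearance_converged"),
    }
    for name, (est_c, true_c, conv_c) in pairs.items():
        if est_c not in study:
            continue
        sub = study[study[conv_c].fillna(False).astype(bool)].dropna(
            subset=[est_c, true_c])
        rel = np.abs(sub[est_c] - sub[true_c]) / np.abs(sub[true_c])
        out[name] = {
            "n": int(len(rel)),
            "median_pct": float(100 * np.median(rel)) if len(rel) else np.nan,
            "max_pct": float(100 * np.max(rel)) if len(rel) else np.nan,
        }
    out["convergence_rate"] = float(
        study[["secretion_converged", "omm_converged", "clearance_converged"]]
        .fillna(False).astype(bool).all(axis=1).mean()
    )
    return out


def null_calibration(n_reps: int = 2000, seed: int = 0,
                     group_sizes=(13, 20, 10, 18)) -> dict:
    """Type-I-error rates of the robust trend test and pairwise contrasts.

    Outcomes are drawn i.i.d. standard normal (no group effect) at the
    study's group sizes; rejections are counted at the two-sided 0.05
    level over ``n_reps`` replicates.
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat(list(TOLERANCE_LABELS), group_sizes)
    codes = np.repeat(np.arange(4), group_sizes)
    n = labels.size
    trend_rej = 0
    pair_tests = 0
    pair_rej = 0
    for _ in range(n_reps):
        y = rng.standard_normal(n)
        _, p = trend_test(y, codes)
        trend_rej += p < 0.05
        cmp = group_compare(y, labels)
        pair_tests += len(cmp.pairwise)
        pair_rej += int((cmp.pairwise["p"] < 0.05).sum())
    return {
        "n_reps": n_reps,
        "trend_rejection_rate": trend_rej / n_reps,
        "pairwise_rejection_rate": pair_rej / pair_tests,
    }


def qualitative_study(n_seeds: int = 50, seed: int = 0) -> dict:
    """Replicate-cohort reproduction of the headline group orderings.

    For each replicate the default synthetic cohort is generated, every
    subject is classified from its sampled curves and fitted with all
    three models, and three orderings of the fitted group means are
    scored: all phi indices lowest in CFRD, SI strictly decreasing across
    the ordinal groups, and clearance higher in CFRD than NGT.  A
    replicate where any tolerance group is empty scores as a failure for
    the orderings it cannot evaluate.
    """
    hits = {"phi_lowest_cfrd": 0, "si_monotone": 0, "clearance_cfrd_gt_ngt": 0}
    for k in range(n_seeds):
        recs = generate_cohort(seed=_child_seed(seed, k))
        results, _ = fit_cohort(
            [(s, ser) for s, ser, _ in recs],
            n_starts_secretion=1, n_starts_omm=0, n_starts_clearance=1,
            also_fixed_he=None,
        )
        res = results[results["tolerance"].notna()]
        sec = res[res["secretion_converged"].fillna(False).astype(bool)]
        omm = res[res["omm_converged"].fillna(False).astype(bool)]
        clr = res[res["clearance_converged"].fillna(False).astype(bool)]

        def group_means(df, col):
            m = df.groupby("tolerance")[col].mean()
            return [m.get(g, np.nan) for g in TOLERANCE_LABELS]

        phi_ok = True
        for col in ("phi_total", "phi_d", "phi_s"):
            means = group_means(sec.dropna(subset=[col]), col)
            if not np.all(np.isfinite(means)) or np.nanargmin(means) != 3:
                phi_ok = False
        hits["phi_lowest_cfrd"] += phi_ok

        si_means = group_means(omm, "si_printed")
        if np.all(np.isfinite(si_means)) and np.all(np.diff(si_means) < 0):
            hits["si_monotone"] += 1

        cl_means = group_means(clr, "clearance_n")
        if np.isfinite(cl_means[0]) and np.isfinite(cl_means[3]) \
                and cl_means[3] > cl_means[0]:
            hits["clearance_cfrd_gt_ngt"] += 1
    return {"n_seeds": n_seeds,
            **{k: v / n_seeds for k, v in hits.items()}}


def oracle_checks(seed: int = 0) -> dict:
    """Numerical-equivalence checks of the core primitives against
    independent oracles; returns the observed deviations."""
    from scipy.optimize import minimize_scalar

    from .core import trapezoid_auc
    from .engine import integrate
    from .secretion import kinetics_from_biexp
    from .stats import fit_hyperbola, spearman

    rng = np.random.default_rng(seed)
    out = {}

    # trapezoid AUC vs a fine-grid integral of the same interpolant
    t = np.array([0.0, 20.0, 60.0, 120.0, 180.0])
    v = np.array([5.0, 9.0, 10.0, 7.0, 5.5]) * rng.uniform(0.8, 1.2)
    fine = np.linspace(0.0, 180.0, 360001)
    oracle = np.trapezoid(np.interp(fine, t, v), fine)
    out["auc_abs_dev"] = abs(trapezoid_auc(t, v) - oracle)

    # hyperbola closed form vs a numeric minimiser
    si = rng.uniform(0.5, 15, 30)
    phi = 800.0 / si * np.exp(0.2 * rng.standard_normal(30))
    beta = fit_hyperbola(si, phi)
    closed = np.sum(phi / si) / np.sum(1.0 / si ** 2)
    num = minimize_scalar(lambda b: np.sum((phi - b / si) ** 2),
                          bounds=(1.0, 1e5), method="bounded",
                          options={"xatol": 1e-9})
    out["hyperbola_closed_form_dev"] = abs(beta - closed)
    out["hyperbola_numeric_dev_rel"] = abs(beta - num.x) / beta

    # two-compartment impulse response vs the biexponential closed form
    F, tf, ts = 0.76, 4.95, 29.2
    kin = kinetics_from_biexp(F, tf, ts, vc=4.0)
    a, b = np.log(2) / tf, np.log(2) / ts
    tt = np.linspace(0.0, 150.0, 151)
    resp = integrate(lambda s, x: kin.matrix @ x, [1.0, 0.0], tt)
    out["impulse_max_abs_dev"] = float(np.max(np.abs(
        resp[:, 0] - (F * np.exp(-a * tt) + (1 - F) * np.exp(-b * tt)))))

    # Spearman vs brute-force midrank Pearson on tied data
    x = rng.integers(0, 5, 40).astype(float)
    y = x + rng.integers(0, 3, 40)

    def midranks(vv):
        order = np.argsort(vv, kind="mergesort")
        ranks = np.empty(vv.size)
        i = 0
        sv = vv[order]
        while i < vv.size:
            j = i
            while j < vv.size and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        return ranks

    rho, _ = spearman(x, y)
    out["spearman_midrank_dev"] = abs(rho - np.corrcoef(midranks(x),
                                                        midranks(y))[0, 1])
    return out
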