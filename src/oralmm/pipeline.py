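"""Cohort-level orchestration: simulate -> fit -> indices -> analyze.

Each stage reads/writes plain CSV/JSON artifacts so a run is fully
reproducible from its manifest (config hash + seed + package version).
Subjects whose model fits fail stay in the classification and index
outputs and are dropped only from model-parameter statistics, with the
reason logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clearance import fit_clearance
from .core import (
    TOLERANCE_LABELS,
    basal_value,
    classify_series,
    read_cohort,
    tolerance_shares,
)
from .cohort import cohort_frames, default_cf_config, generate_cohort
from .engine import DEFAULT_SEED, SignalInterpolant
from .indices import index_table
from .secretion import fit_secretion, isr_summary, simulate_secretion, vancauter_kinetics
from .sensitivity import fit_omm, ra_auc_target
from .stats import (
    association_models,
    disposition_index,
    fit_hyperbola,
    group_compare,
    spearman,
)

__all__ = ["RunManifest", "fit_cohort", "analyze_cohort", "run_pipeline",
           "PipelineError", "DependencyError"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "fit", "indices", "analyze")

#: outcomes summarised per glucose tolerance group: name -> transform
GROUP_OUTCOMES = {
    "phi_total": "none",
    "phi_d": "log",
    "phi_s": "none",
    "si_printed": "log",
    "di": "none",
    "clearance_n": "none",
    "he": "none",
    "tau": "none",
    "t_max_static": "none",
    "homa_ir": "log",
    "matsuda": "log",
    "stumvoll": "none",
    "auc_clearance_ratio": "none",
}


class PipelineError(RuntimeError):
    pass


class DependencyError(PipelineError):
    """A stage was requested without its upstream outputs."""


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)
    convergence: dict = field(default_factory=dict)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def fit_cohort(records, n_starts_secretion: int = 1, n_starts_omm: int = 1,
               n_starts_clearance: int = 1, fix_he: float | None = None,
               also_fixed_he: float | None = 0.5,
               seed: int = DEFAULT_SEED) -> tuple[pd.DataFrame, list]:
    """Fit all three models to every subject of a cohort.

    Returns ``(results, fit_log)``: one row per subject with tolerance
    class, basal values, model parameters (printed scales), secretion
    peak summaries and convergence flags; plus a JSON-able fit log.
    ``also_fixed_he`` re-runs the clearance fit with that fixed hepatic
    extraction (the sensitivity variant), reported as
    ``clearance_n_fixhe``.
    """
    rows = []
    fit_log = []
    for rec in records:
        subject, series = rec[0], rec[1]
        row: dict = {
            "subject_id": series.subject_id,
            "age": subject.age, "sex": subject.sex,
            "sex_female": 1.0 if subject.sex == "female" else 0.0,
            "bmi": subject.bmi, "weight": subject.weight,
            "insulin_treated": subject.insulin_treated,
        }
        entry: dict = {"subject_id": series.subject_id}
        try:
            status = classify_series(series)
            row["tolerance"] = status.label
            row["tolerance_code"] = status.ordinal_code
        except Exception as exc:
            log.warning("%s: classification failed: %s", series.subject_id, exc)
            row["tolerance"] = None
            row["tolerance_code"] = np.nan
        try:
            row["gb"] = basal_value(series, "glucose")
            row["ib"] = basal_value(series, "insulin")
            row["cpb"] = basal_value(series, "cpeptide")
            gmask = np.isfinite(series.glucose)
            row["max_glucose"] = float(np.nanmax(series.glucose[gmask]))
        except Exception as exc:
            log.warning("%s: basal extraction failed: %s", series.subject_id, exc)

        diabetic = row.get("tolerance") == "CFRD"
        kin = None
        sec_params = None
        try:
            kin = vancauter_kinetics(subject, diabetic=diabetic)
            sec_params, sec_fit = fit_secretion(
                series, kin, n_starts=n_starts_secretion, seed=seed
            )
            row.update(
                phi_d=sec_params.phi_d, phi_s=sec_params.phi_s,
                tau=sec_params.tau, h=sec_params.h, phi_b=sec_params.phi_b,
                phi_total=sec_params.phi_total,
                secretion_converged=sec_fit.converged,
            )
            entry["secretion"] = {
                "converged": sec_fit.converged,
                "objective": sec_fit.objective,
                "fractional_sd": sec_fit.fractional_sd,
            }
            if sec_fit.converged:
                gb = row["gb"]
                ok_g = np.isfinite(series.glucose)
                glu = SignalInterpolant(series.times[ok_g], series.glucose[ok_g])
                dense = np.arange(0.0, 180.0 + 0.5, 1.0)
                sim = simulate_secretion(kin, sec_params, glu, gb, row["cpb"],
                                         dense)
                peaks = isr_summary(dense, sim["sr_d"], sim["sr_s"])
                row.update(
                    isr_max_dynamic=peaks.isr_max_dynamic,
                    t_max_dynamic=peaks.t_max_dynamic,
                    isr_max_static=peaks.isr_max_static,
                    t_max_static=peaks.t_max_static,
                )
        except Exception as exc:
            log.warning("%s: secretion fit failed: %s", series.subject_id, exc)
            row["secretion_converged"] = False
            entry["secretion"] = {"error": str(exc)}

        try:
            omm_params, omm_fit = fit_omm(series, subject.weight,
                                          n_starts=n_starts_omm, seed=seed)
            row.update(
                si_printed=omm_params.si_printed, sg=omm_params.sg,
                p2=omm_params.p2, v=omm_params.v,
                ra_auc=omm_params.ra_auc(),
                ra_auc_target=ra_auc_target(series.dose_grams, subject.weight),
                omm_converged=omm_fit.converged,
            )
            entry["omm"] = {
                "converged": omm_fit.converged,
                "objective": omm_fit.objective,
                "fractional_sd": omm_fit.fractional_sd,
            }
        except Exception as exc:
            log.warning("%s: sensitivity fit failed: %s", series.subject_id, exc)
            row["omm_converged"] = False
            entry["omm"] = {"error": str(exc)}

        if sec_params is not None and kin is not None and row.get(
                "secretion_converged"):
            try:
                clr_params, clr_fit = fit_clearance(
                    series, sec_params, kin, subject.weight, fix_he=fix_he,
                    n_starts=n_starts_clearance, seed=seed,
                )
                row.update(clearance_n=clr_params.clearance_n,
                           he=clr_params.he,
                           clearance_converged=clr_fit.converged)
                entry["clearance"] = {
                    "converged": clr_fit.converged,
                    "objective": clr_fit.objective,
                }
                if also_fixed_he is not None and fix_he is None:
                    clr_fixed, _ = fit_clearance(
                        series, sec_params, kin, subject.weight,
                        fix_he=also_fixed_he, n_starts=n_starts_clearance,
                        seed=seed,
                    )
                    row["clearance_n_fixhe"] = clr_fixed.clearance_n
            except Exception as exc:
                log.warning("%s: clearance fit failed: %s",
                            series.subject_id, exc)
                row["clearance_converged"] = False
                entry["clearance"] = {"error": str(exc)}
        else:
            row["clearance_converged"] = False
            entry["clearance"] = {"skipped": "no converged secretion fit"}

        if all(row.get(k) for k in
               ("secretion_converged", "omm_converged", "clearance_converged")):
            row["di"] = float(disposition_index(row["phi_total"],
                                                row["si_printed"]))
        rows.append(row)
        fit_log.append(entry)
    return pd.DataFrame(rows), fit_log


def analyze_cohort(results: pd.DataFrame) -> dict:
    """Group-level statistics from a fitted-cohort results table.

    Returns a dict of data frames: ``group_sizes``, ``group_comparisons``
    (marginal means, CIs), ``pairwise``, ``trends``, ``hyperbola``,
    ``correlations`` and ``associations``.
    """
    out: dict = {}
    res = results[results["tolerance"].notna()].copy()
    counts = res["tolerance"].value_counts().to_dict()
    shares = tolerance_shares(counts)
    out["group_sizes"] = pd.DataFrame({
        "group": list(TOLERANCE_LABELS),
        "n": [int(counts.get(g, 0)) for g in TOLERANCE_LABELS],
        "share_pct": [shares[g] for g in TOLERANCE_LABELS],
    })

    gtab, pairs, trends = [], [], []
    for outcome, transform in GROUP_OUTCOMES.items():
        if outcome not in res:
            continue
        sub = res.dropna(subset=[outcome, "tolerance"])
        if outcome in ("phi_total", "phi_d", "phi_s", "si_printed", "di",
                       "clearance_n", "he", "tau", "t_max_static"):
            conv_col = {
                "clearance_n": "clearance_converged", "he": "clearance_converged",
                "si_printed": "omm_converged",
            }.get(outcome, "secretion_converged")
            if conv_col in sub:
                sub = sub[sub[conv_col].fillna(False).astype(bool)]
        try:
            cmp = group_compare(sub[outcome].to_numpy(),
                                sub["tolerance"].to_numpy(),
                                transform=transform, outcome=outcome)
        except Exception as exc:
            log.warning("group comparison for %s failed: %s", outcome, exc)
            continue
        t = cmp.table.copy()
        t.insert(0, "outcome", outcome)
        t["transform"] = transform
        gtab.append(t)
        p = cmp.pairwise.copy()
        p.insert(0, "outcome", outcome)
        pairs.append(p)
        trends.append({"outcome": outcome, "transform": transform,
                       "slope": cmp.trend_slope, "p_trend": cmp.trend_p,
                       "p_trend_raw_scale": cmp.trend_p_raw})
    out["group_comparisons"] = pd.concat(gtab, ignore_index=True) if gtab else pd.DataFrame()
    out["pairwise"] = pd.concat(pairs, ignore_index=True) if pairs else pd.DataFrame()
    out["trends"] = pd.DataFrame(trends)

    # disposition-index hyperbola per group
    hyp = []
    ok = res.dropna(subset=["phi_total", "si_printed"])
    for g in TOLERANCE_LABELS:
        pts = ok[ok["tolerance"] == g]
        if len(pts) >= 2:
            try:
                beta = fit_hyperbola(pts["si_printed"], pts["phi_total"])
                hyp.append({"group": g, "beta": beta, "n": len(pts)})
            except ValueError as exc:
                log.warning("hyperbola fit for %s failed: %s", g, exc)
    out["hyperbola"] = pd.DataFrame(hyp)

    # Spearman comparisons of simple indices against modelled estimates
    cors = []
    for a, b in [("si_printed", "homa_ir"), ("si_printed", "matsuda"),
                 ("si_printed", "stumvoll"),
                 ("clearance_n", "auc_clearance_ratio"),
                 ("clearance_n", "he")]:
        if a in res and b in res:
            sub = res.dropna(subset=[a, b])
            if len(sub) >= 4:
                try:
                    rho, p = spearman(sub[a], sub[b])
                    cors.append({"x": a, "y": b, "rho": rho, "p": p,
                                 "n": len(sub)})
                except ValueError as exc:
                    log.warning("correlation %s~%s failed: %s", a, b, exc)
    out["correlations"] = pd.DataFrame(cors)

    # per-predictor association models with insulin clearance (and HE)
    assoc_rows = []
    predictors = [c for c in ("age", "sex_female", "bmi", "homa_ir",
                              "matsuda", "stumvoll", "si_printed", "di",
                              "phi_total", "phi_d", "phi_s",
                              "tolerance_code", "max_glucose")
                  if c in res]
    cov = pd.DataFrame({
        "bmi": res.get("bmi"), "age": res.get("age"),
        "sex_female": res.get("sex_female"), "si": res.get("si_printed"),
    })
    for outcome_col in ("clearance_n", "he", "clearance_n_fixhe"):
        if outcome_col not in res:
            continue
        for adj in ("minimal", "multivariable"):
            ests = association_models(
                res[outcome_col], res[predictors], cov, adjustment=adj,
                outcome_name=outcome_col,
            )
            assoc_rows.extend(vars(e) for e in ests)
    out["associations"] = pd.DataFrame(assoc_rows)
    return out


def _plot_results(results: pd.DataFrame, analysis: dict, figdir: Path):
    """Bar charts of marginal means and the disposition hyperbola scatter."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir.mkdir(parents=True, exist_ok=True)
    gc = analysis.get("group_comparisons")
    made = []
    if gc is not None and len(gc):
        for outcome in ("phi_total", "si_printed", "di", "clearance_n", "he"):
            t = gc[gc["outcome"] == outcome]
            if not len(t):
                continue
            fig, ax = plt.subplots(figsize=(4, 3))
            x = np.arange(len(t))
            ax.bar(x, t["mean"], yerr=[t["mean"] - t["ci_lo"],
                                       t["ci_hi"] - t["mean"]],
                   color="#88aacc", capsize=3)
            ax.set_xticks(x, t["group"])
            ax.set_ylabel(outcome)
            fig.tight_layout()
            p = figdir / f"group_means_{outcome}.svg"
            fig.savefig(p)
            plt.close(fig)
            made.append(str(p))
    ok = results.dropna(subset=["phi_total", "si_printed"])
    if len(ok) and "hyperbola" in analysis and len(analysis["hyperbola"]):
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        colors = dict(zip(TOLERANCE_LABELS, ["#2c7fb8", "#7fcdbb", "#fdae61",
                                             "#d7191c"]))
        for g in TOLERANCE_LABELS:
            pts = ok[ok["tolerance"] == g]
            ax.scatter(pts["si_printed"], pts["phi_total"], s=14,
                       color=colors[g], label=g)
        si_grid = np.linspace(max(ok["si_printed"].min(), 1e-3),
                              ok["si_printed"].max(), 100)
        for _, r in analysis["hyperbola"].iterrows():
            ax.plot(si_grid, r["beta"] / si_grid, color=colors[r["group"]],
                    lw=1, alpha=0.7)
        ax.set_xlabel("insulin sensitivity (1e-4 pmol$^{-1}$ l min$^{-1}$)")
        ax.set_ylabel("phi total (1e-9 min$^{-1}$)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = figdir / "disposition_hyperbola.svg"
        fig.savefig(p)
        plt.close(fig)
        made.append(str(p))
    # normality screening artifact: Q-Q plots of key outcomes
    from scipy import stats as sps

    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax, outcome in zip(axes, ("phi_total", "si_printed", "clearance_n")):
        vals = results[outcome].dropna() if outcome in results else []
        if len(vals) >= 4:
            sps.probplot(vals, dist="norm", plot=ax)
            ax.set_title(outcome, fontsize=8)
    fig.tight_layout()
    p = figdir / "qq_screening.svg"
    fig.savefig(p)
    plt.close(fig)
    made.append(str(p))
    return made


def run_pipeline(config: dict | str | Path | None = None,
                 stages=STAGES, outdir: str | Path = "oralmm_run",
                 seed: int | None = None) -> RunManifest:
    """Execute the requested stages in order and write a run manifest.

    ``config`` may be a dict or a YAML/JSON file with keys ``seed``,
    ``cohort`` (path to an existing cohort CSV; omit to simulate),
    ``schema``, ``group_sizes``, ``fix_he``, ``n_starts``.  Raises
    :class:`DependencyError` when a stage lacks its upstream inputs.
    """
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    config = dict(config or {})
    if seed is not None:
        config["seed"] = seed
    config.setdefault("seed", 0)
    seed = int(config["seed"])
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stage(s): {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config), seed=seed,
                           version=__version__)

    records = None
    truth = None
    if "simulate" in stages:
        cfg = default_cf_config()
        if "group_sizes" in config:
            cfg.group_sizes = dict(config["group_sizes"])
        triples = generate_cohort(cfg, seed=seed)
        records = [(s, ser) for s, ser, _ in triples]
        cohort_df, truth = cohort_frames(triples)
        cohort_path = outdir / "cohort.csv"
        cohort_df.to_csv(cohort_path, index=False)
        truth_path = outdir / "truth.csv"
        truth.to_csv(truth_path, index=False)
        snap = outdir / "config.json"
        with open(snap, "w") as fh:
            json.dump({"seed": seed, "group_sizes": cfg.group_sizes,
                       "assay_cv": cfg.assay_cv,
                       "dose_grams": cfg.dose_grams}, fh, indent=2)
        manifest.stages["simulate"] = {
            "outputs": [str(cohort_path), str(truth_path), str(snap)],
        }
    elif "cohort" in config:
        records, report = read_cohort(config["cohort"], config.get("schema"))
        manifest.stages["load"] = {"inputs": [str(config["cohort"])],
                                   "report": report}

    results = None
    if "fit" in stages:
        if records is None:
            raise DependencyError(
                "fit stage needs a cohort (run simulate or set 'cohort')"
            )
        results, fit_log = fit_cohort(
            records, fix_he=config.get("fix_he"),
            n_starts_secretion=config.get("n_starts", 1),
            n_starts_omm=config.get("n_starts", 1),
            n_starts_clearance=config.get("n_starts", 1),
            seed=DEFAULT_SEED,
        )
        fits_path = outdir / "fits.csv"
        results.to_csv(fits_path, index=False)
        logpath = outdir / "fit_log.jsonl"
        with open(logpath, "w") as fh:
            for entry in fit_log:
                fh.write(json.dumps(entry, default=str) + "\n")
        conv = {
            m: int(results.get(f"{m}_converged", pd.Series(dtype=bool))
                   .fillna(False).astype(bool).sum())
            for m in ("secretion", "omm", "clearance")
        }
        manifest.convergence = {"n_subjects": len(results), **conv}
        manifest.stages["fit"] = {"outputs": [str(fits_path), str(logpath)]}

    if "indices" in stages:
        if records is None:
            raise DependencyError(
                "indices stage needs a cohort (run simulate or set 'cohort')"
            )
        idx = index_table(records)
        idx_path = outdir / "indices.csv"
        idx.to_csv(idx_path, index=False)
        manifest.stages["indices"] = {"outputs": [str(idx_path)]}
        if results is not None:
            results = results.merge(idx, on="subject_id", how="left")

    if "analyze" in stages:
        if results is None:
            fits_path = outdir / "fits.csv"
            if not fits_path.exists():
                raise DependencyError(
                    "analyze stage needs fit outputs (run fit first)"
                )
            results = pd.read_csv(fits_path)
        analysis = analyze_cohort(results)
        outputs = []
        for name, df in analysis.items():
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            outputs.append(str(p))
        outputs += _plot_results(results, analysis, outdir / "figures")
        manifest.stages["analyze"] = {"outputs": outputs}

    manifest.to_json(outdir / "manifest.json")
    return manifest
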