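"""Insulin clearance and hepatic extraction (Watanabe formulation).

Plasma insulin is a single linear compartment fed by post-hepatic
delivery of newly secreted insulin (equimolar with C-peptide secretion)
and drained by a fractional clearance n:

    dI/dt = -n I + (1 - HE) ISR_ab(t) / (Vi * weight)      I(0) = 0
    (above basal; predicted insulin = I(t) + Ib)

ISR_ab is the above-basal insulin secretion rate (pmol/min) from the
C-peptide model, HE the hepatic extraction fraction (constant over the
test), Vi the insulin distribution volume (l/kg, configuration: joint
estimation of n, HE and Vi from a single insulin curve is not
identifiable).  At basal the model closes with
(1 - HE) ISR_b = n Ib Vi weight.

The fractional clearance n (min^-1) is invariant to the choice of Vi
given that closure, which is why it is the headline kinetic outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._linode import affine_recurrence, phi1, phi2
from .core import OgttSeries, RecordError, basal_value
from .engine import DEFAULT_SEED, SignalInterpolant, assay_weights, wnls_fit
from .secretion import CPeptideKinetics, SecretionParams, simulate_secretion

__all__ = ["INSULIN_VOLUME_L_PER_KG", "ClearanceParams", "simulate_insulin",
           "fit_clearance", "basal_isr", "profile_objective"]

log = logging.getLogger(__name__)

#: insulin distribution volume, litres per kg body weight (literature-scale
#: configuration constant, not an estimated parameter)
INSULIN_VOLUME_L_PER_KG = 0.14


@dataclass
class ClearanceParams:
    """Fractional insulin clearance n (min^-1), hepatic extraction HE
    (fraction in [0, 1)) and the configured distribution volume (l/kg)."""

    clearance_n: float
    he: float
    vi: float = INSULIN_VOLUME_L_PER_KG

    def __post_init__(self):
        if not self.clearance_n > 0:
            raise ValueError("clearance_n must be positive")
        if not (0.0 <= self.he < 1.0):
            raise ValueError("he must lie in [0, 1)")


def basal_isr(params: ClearanceParams, ib: float, weight: float) -> float:
    """Basal pancreatic insulin delivery (pmol/min) from the steady-state
    closure (1-HE) ISR_b = n Ib Vi weight."""
    return params.clearance_n * ib * params.vi * weight / (1.0 - params.he)


def _convolve_decay(n: float, t_nodes: np.ndarray, u: np.ndarray) -> np.ndarray:
    """x(t) for dx/dt = -n x + u(t), x(0)=0, u piecewise linear on nodes."""
    d = np.diff(t_nodes)
    lam = -n
    E = np.exp(lam * d)
    slope = np.diff(u) / d
    beta = phi1(lam, d) * u[:-1] + phi2(lam, d) * slope
    return affine_recurrence(E, beta, 0.0)


def simulate_insulin(params: ClearanceParams, isr_times, isr_above_basal,
                     ib: float, weight: float, t_grid) -> dict:
    """Insulin trajectory given an above-basal secretion input.

    ``isr_above_basal`` (pmol/min) is interpreted as piecewise linear on
    ``isr_times``; supply it on a dense grid if it came from the
    secretion model.  Propagation is exact for that interpolant.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    it = np.asarray(isr_times, dtype=float)
    iv = np.asarray(isr_above_basal, dtype=float)
    if t_grid.size < 1 or np.any(np.diff(t_grid) <= 0) or t_grid[0] < 0:
        raise ValueError("t_grid must be increasing and >= 0")
    nodes = np.unique(np.concatenate([[0.0], it[(it > 0) & (it < t_grid[-1])],
                                      t_grid]))
    u = np.interp(nodes, it, iv) * (1.0 - params.he) / (
        params.vi * weight
    )
    x = _convolve_decay(params.clearance_n, nodes, u)
    idx = np.searchsorted(nodes, t_grid)
    return {"t": t_grid, "insulin": x[idx] + ib, "above_basal": x[idx]}


def fit_clearance(series: OgttSeries, secretion_params: SecretionParams,
                  kin: CPeptideKinetics, weight: float,
                  fix_he: float | None = None,
                  n_starts: int = 5, seed: int = DEFAULT_SEED,
                  cv: dict | None = None, t_end: float = 180.0):
    """Fit fractional clearance and hepatic extraction to measured insulin.

    The above-basal secretion input is reconstructed from the fitted
    C-peptide model on a 1 min grid.  HE enters the model linearly
    through (1-HE) and is profiled out of the one-dimensional search
    over n; ``fix_he`` pins it (e.g. 0.5 for the sensitivity variant).
    Returns ``(ClearanceParams, FitResult)``.
    """
    gb = basal_value(series, "glucose")
    cpb = basal_value(series, "cpeptide")
    ib = basal_value(series, "insulin")
    ok_g = np.isfinite(series.glucose)
    glucose = SignalInterpolant(series.times[ok_g], series.glucose[ok_g])
    if secretion_params is None:
        raise ValueError(f"{series.subject_id}: secretion fit required first")

    fit_mask = (series.times > 0) & (series.times <= t_end) & np.isfinite(
        series.insulin
    )
    if fit_mask.sum() < 5:
        raise RecordError(f"{series.subject_id}: too few insulin samples")
    t_fit = series.times[fit_mask]
    y = series.insulin[fit_mask]
    w = assay_weights(y, "insulin", cv)

    dense = np.arange(0.0, t_end + 0.5, 1.0)
    sim = simulate_secretion(kin, secretion_params, glucose, gb, cpb, dense)
    isr_ab = sim["sr"] * kin.vc  # pmol/min, above basal
    if not weight or not np.isfinite(weight) or weight <= 0:
        raise ValueError(f"{series.subject_id}: positive body weight required")
    scale0 = 1.0 / (INSULIN_VOLUME_L_PER_KG * weight)

    nodes = np.unique(np.concatenate([dense, t_fit]))
    u_unit = np.interp(nodes, dense, isr_ab) * scale0  # response per unit (1-HE)
    idx = np.searchsorted(nodes, t_fit)

    inner: dict = {}

    def predict(theta):
        n_ = theta[0]
        R = _convolve_decay(n_, nodes, u_unit)[idx]
        if fix_he is not None:
            c = 1.0 - fix_he
        else:
            den = float(R @ (w * R))
            c = float(R @ (w * (y - ib))) / den if den > 0 else 1.0
            c = float(np.clip(c, 1e-6, 1.0))
        inner["he"] = 1.0 - c
        return ib + c * R

    fit = wnls_fit(predict, y, w, {"n": (0.01, 1.0)}, transforms={"n": "log"},
                   x0={"n": 0.15}, n_starts=n_starts, seed=seed)
    predict(np.array([fit.estimates["n"]]))
    he = float(fix_he) if fix_he is not None else inner["he"]
    if fix_he is None and (he <= 1e-5 or he >= 1.0 - 1e-6):
        fit.message += " | HE at bound"
    fit.estimates.update(he=he, clearance_n=fit.estimates["n"])
    params = ClearanceParams(clearance_n=fit.estimates["n"],
                             he=min(max(he, 0.0), 1.0 - 1e-9))
    return params, fit


def profile_objective(series: OgttSeries, secretion_params: SecretionParams,
                      kin: CPeptideKinetics, weight: float,
                      n_grid=None, he_grid=None,
                      cv: dict | None = None, t_end: float = 180.0):
    """Weighted-SSR surface over (HE, n) for identifiability diagnostics.

    Returns ``(he_grid, n_grid, ssr, ridge_warning)``; the warning fires
    when the best SSR along the profiled valley varies by less than 5 %
    over a wide HE range, i.e. the data cannot pin HE and n jointly
    (the model yields only relatively crude estimates in that regime).
    """
    n_grid = np.asarray(n_grid if n_grid is not None else
                        np.geomspace(0.02, 0.8, 25))
    he_grid = np.asarray(he_grid if he_grid is not None else
                         np.linspace(0.05, 0.95, 19))
    gb = basal_value(series, "glucose")
    cpb = basal_value(series, "cpeptide")
    ib = basal_value(series, "insulin")
    ok_g = np.isfinite(series.glucose)
    glucose = SignalInterpolant(series.times[ok_g], series.glucose[ok_g])
    fit_mask = (series.times > 0) & (series.times <= t_end) & np.isfinite(
        series.insulin
    )
    t_fit = series.times[fit_mask]
    y = series.insulin[fit_mask]
    w = assay_weights(y, "insulin", cv)
    dense = np.arange(0.0, t_end + 0.5, 1.0)
    sim = simulate_secretion(kin, secretion_params, glucose, gb, cpb, dense)
    isr_ab = sim["sr"] * kin.vc
    nodes = np.unique(np.concatenate([dense, t_fit]))
    idx = np.searchsorted(nodes, t_fit)
    scale0 = 1.0 / (INSULIN_VOLUME_L_PER_KG * weight)
    u_unit = np.interp(nodes, dense, isr_ab) * scale0

    ssr = np.empty((he_grid.size, n_grid.size))
    for j, n_ in enumerate(n_grid):
        R = _convolve_decay(n_, nodes, u_unit)[idx]
        for i, he_ in enumerate(he_grid):
            r = y - ib - (1.0 - he_) * R
            ssr[i, j] = float(r @ (w * r))
    valley = ssr.min(axis=1)
    lo, hi = valley.min(), valley.max()
    ridge_warning = bool(hi <= 1.05 * lo)
    if ridge_warning:
        log.warning("%s: flat (HE, n) objective ridge - crude estimates",
                    series.subject_id)
    return he_grid, n_grid, ssr, ridge_warning
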