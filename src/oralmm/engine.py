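"""Shared numerical machinery for the three minimal-model fits.

Provides a piecewise-linear forcing-signal interpolant, a deterministic
ODE integrator for arbitrary right-hand sides (used mainly as an
independent check on the exact model propagators), and bounded weighted
nonlinear least squares with Latin-hypercube multi-start.

Weighting convention: measurement errors are taken as multiplicative with
assay-level coefficients of variation (glucose 2 %, insulin 6 %,
C-peptide 5 % by default), so residual i gets weight 1/(CV*y_i)^2.
Positive parameters are searched on a log scale and fractions on a logit
scale, which enforces the bounds without constrained optimisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from scipy.stats import qmc

__all__ = ["ASSAY_CV", "DEFAULT_SEED", "SignalInterpolant", "integrate",
           "FitResult", "wnls_fit", "assay_weights"]

#: default assay coefficients of variation (fractional)
ASSAY_CV = {"glucose": 0.02, "insulin": 0.06, "cpeptide": 0.05}

#: fixed default seed for the multi-start sampler (reproducibility of a
#: non-convex fit)
DEFAULT_SEED = 20200801

DEFAULT_N_STARTS = 10


def assay_weights(values: np.ndarray, analyte: str,
                  cv: Mapping[str, float] | None = None) -> np.ndarray:
    """1/(CV*y)^2 weights for one measured analyte."""
    c = (cv or ASSAY_CV)[analyte]
    v = np.asarray(values, dtype=float)
    return 1.0 / (c * v) ** 2


class SignalInterpolant:
    """Continuous forcing signal through sampled knots.

    Linear mode evaluates the piecewise-linear interpolant exactly at the
    knots; the derivative is the piecewise slope, taken from the right at
    knot points (one-sided).  Outside the knot range the signal is held
    constant.  A lightly smoothed mode (monotone cubic) is available but
    off by default.
    """

    def __init__(self, times: Sequence[float], values: Sequence[float],
                 mode: str = "linear"):
        t = np.asarray(times, dtype=float)
        v = np.asarray(values, dtype=float)
        ok = np.isfinite(v)
        if ok.sum() < 2:
            raise ValueError("interpolant needs at least two finite knots")
        self.times = t[ok]
        self.values = v[ok]
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("knot times must be strictly increasing")
        if mode not in ("linear", "smoothed"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        if mode == "smoothed":
            from scipy.interpolate import PchipInterpolator

            self._f = PchipInterpolator(self.times, self.values, extrapolate=False)
        self._slopes = np.diff(self.values) / np.diff(self.times)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.mode == "smoothed":
            out = self._f(np.clip(t, self.times[0], self.times[-1]))
            return out if out.ndim else float(out)
        out = np.interp(t, self.times, self.values)
        return out if out.ndim else float(out)

    def derivative(self, t):
        """Right-hand slope of the interpolant (zero outside the knots)."""
        t = np.asarray(t, dtype=float)
        if self.mode == "smoothed":
            d = self._f.derivative()(np.clip(t, self.times[0], self.times[-1]))
            return d if d.ndim else float(d)
        idx = np.searchsorted(self.times, t, side="right") - 1
        inside = (idx >= 0) & (idx < self._slopes.size)
        out = np.where(inside, self._slopes[np.clip(idx, 0, self._slopes.size - 1)], 0.0)
        return out if out.ndim else float(out)

    def crossings(self, level: float) -> np.ndarray:
        """Times where the linear interpolant crosses a level (exact)."""
        t, v = self.times, self.values - level
        out = []
        for k in range(t.size - 1):
            if v[k] == 0.0:
                out.append(t[k])
            if v[k] * v[k + 1] < 0:
                out.append(t[k] + (t[k + 1] - t[k]) * (-v[k]) / (v[k + 1] - v[k]))
        if v[-1] == 0.0:
            out.append(t[-1])
        return np.asarray(out)


class SolverError(RuntimeError):
    """ODE solver failure, carrying the offending parameters and time."""

    def __init__(self, message: str, params=None, t_fail=None):
        super().__init__(message)
        self.params = params
        self.t_fail = t_fail


def integrate(rhs: Callable, x0: Sequence[float], t_grid: Sequence[float],
              args: tuple = (), discontinuities: Sequence[float] | None = None,
              rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Integrate dx/dt = rhs(t, x, *args) on an increasing grid.

    Piecewise-smooth right-hand sides (linear forcing interpolants kink at
    their knots) are handled by restarting the solver at the listed
    discontinuity times, keeping the stated accuracy.  Deterministic for
    fixed inputs.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size < 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be nonempty and strictly increasing")
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    breaks = np.asarray([] if discontinuities is None else discontinuities, float)
    breaks = breaks[(breaks > t_grid[0]) & (breaks < t_grid[-1])]
    seg_edges = np.unique(np.concatenate([[t_grid[0], t_grid[-1]], breaks]))

    out = np.empty((t_grid.size, x0.size))
    if np.isclose(t_grid[0], seg_edges[0]):
        out[0] = x0
    x = x0
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        eval_mask = (t_grid > a) & (t_grid <= b)
        t_eval = np.unique(np.concatenate([t_grid[eval_mask], [b]]))
        sol = solve_ivp(
            rhs, (a, b), x, t_eval=t_eval, args=args, rtol=rtol, atol=atol,
            method="RK45", dense_output=False,
        )
        if not sol.success:
            t_reached = np.asarray(sol.t)
            raise SolverError(
                f"ODE solver failed: {sol.message}", params=args,
                t_fail=float(t_reached[-1]) if t_reached.size else float(a),
            )
        if eval_mask.any():
            idx = np.searchsorted(sol.t, t_grid[eval_mask])
            out[eval_mask] = sol.y.T[idx]
        x = sol.y[:, -1]
    return out


# ---------------------------------------------------------------------------
# weighted nonlinear least squares with multi-start


@dataclass
class FitResult:
    """Outcome of one weighted nonlinear least-squares fit."""

    estimates: dict
    fractional_sd: dict  # per-parameter CV of the estimate, percent
    residuals: np.ndarray  # weighted residual vector at the optimum
    objective: float  # weighted SSR
    converged: bool
    n_starts_used: int
    seed: int
    start_objectives: np.ndarray = field(default_factory=lambda: np.array([]))
    start_initial_objectives: np.ndarray = field(
        default_factory=lambda: np.array([]))
    message: str = ""


def _to_internal(x, transform):
    if transform == "log":
        return np.log(x)
    if transform == "logit":
        return np.log(x / (1.0 - x))
    return x


def _from_internal(z, transform):
    if transform == "log":
        return np.exp(z)
    if transform == "logit":
        return 1.0 / (1.0 + np.exp(-z))
    return z


class FitError(RuntimeError):
    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


def wnls_fit(
    predict: Callable[[np.ndarray], np.ndarray],
    data: np.ndarray,
    weights: np.ndarray,
    bounds: Mapping[str, tuple[float, float]],
    transforms: Mapping[str, str] | None = None,
    x0: Mapping[str, float] | None = None,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = DEFAULT_SEED,
    xtol: float = 1e-10,
    ftol: float = 1e-12,
    gtol: float = 1e-12,
) -> FitResult:
    """Minimise sum_i w_i (y_i - predict(theta)_i)^2 over bounded theta.

    ``bounds`` maps parameter names (in order) to (lo, hi) on the natural
    scale; ``transforms`` chooses the internal search scale per parameter
    ("log" for positive parameters, "logit" for fractions, "linear").
    The best of ``n_starts`` Latin-hypercube starts (plus ``x0`` if given)
    is returned; fractional SDs come from the Gauss-Newton covariance
    approximation at the optimum.
    """
    names = list(bounds)
    lo = np.array([bounds[k][0] for k in names], dtype=float)
    hi = np.array([bounds[k][1] for k in names], dtype=float)
    trans = [(transforms or {}).get(k, "linear") for k in names]
    data = np.asarray(data, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if n_starts < 1 and x0 is None:
        raise ValueError("n_starts must be >= 1 (or supply x0)")
    sw = np.sqrt(w)

    zlo = np.array([_to_internal(l, tr) for l, tr in zip(lo, trans)])
    zhi = np.array([_to_internal(h, tr) for h, tr in zip(hi, trans)])

    def resid(zvec):
        theta = np.array([_from_internal(z, tr) for z, tr in zip(zvec, trans)])
        yhat = predict(theta)
        return sw * (data - yhat)

    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(max(n_starts, 0))
    starts = zlo + unit * (zhi - zlo)
    start_list = list(starts)
    if x0 is not None:
        z0 = np.array([
            _to_internal(np.clip(x0[k], bounds[k][0], bounds[k][1]), tr)
            for k, tr in zip(names, trans)
        ])
        start_list.insert(0, z0)

    best = None
    diagnostics = []
    start_objs = []
    start_obj0 = []
    for s in start_list:
        try:
            r0 = resid(s)
            obj0 = float(r0 @ r0)
            start_obj0.append(obj0)
            sol = least_squares(
                resid, s, bounds=(zlo, zhi), method="trf", xtol=xtol,
                ftol=ftol, gtol=gtol,
            )
            obj = float(sol.fun @ sol.fun)
            start_objs.append(obj)
            diagnostics.append({"start_objective": obj0, "objective": obj,
                                "status": int(sol.status)})
            if np.isfinite(obj) and (best is None or obj < best[0]):
                best = (obj, sol)
        except Exception as exc:  # a failed start is diagnostic, not fatal
            start_objs.append(np.inf)
            if len(start_obj0) < len(start_objs):
                start_obj0.append(np.inf)
            diagnostics.append({"error": str(exc)})
    if best is None:
        raise FitError("all starts failed", diagnostics=diagnostics)

    obj, sol = best
    theta = np.array([_from_internal(z, tr) for z, tr in zip(sol.x, trans)])
    estimates = dict(zip(names, theta))

    # Gauss-Newton covariance in internal coordinates, scaled by the
    # reduced chi-square; mapped to CV% on the natural scale.
    m, p = data.size, len(names)
    frac_sd = {}
    try:
        J = sol.jac
        JtJ = J.T @ J
        dof = max(m - p, 1)
        s2 = obj / dof
        cov = s2 * np.linalg.pinv(JtJ)
        se_int = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        for k, name in enumerate(names):
            tr, est = trans[k], theta[k]
            if tr == "log":
                frac_sd[name] = 100.0 * se_int[k]
            elif tr == "logit":
                frac_sd[name] = (
                    100.0 * se_int[k] * est * (1.0 - est) / est if est > 0 else np.inf
                )
            else:
                frac_sd[name] = (
                    100.0 * se_int[k] / abs(est) if est != 0 else np.inf
                )
    except Exception:
        frac_sd = {name: np.nan for name in names}

    converged = bool(sol.status > 0 and np.isfinite(obj))
    return FitResult(
        estimates=estimates,
        fractional_sd=frac_sd,
        residuals=np.asarray(sol.fun),
        objective=obj,
        converged=converged,
        n_starts_used=len(start_list),
        seed=seed,
        start_objectives=np.asarray(start_objs),
        start_initial_objectives=np.asarray(start_obj0),
        message=str(sol.message),
    )
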