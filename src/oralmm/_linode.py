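"""Exact propagators for small linear time-invariant ODE systems.

All three oral minimal models reduce, between sampling knots, to linear
systems driven by piecewise-linear (or piecewise-constant) inputs.  For a
system dx/dt = A x + u(t) with u linear on a segment of length d,

    x(t0+d) = e^{Ad} x(t0) + phi1(A,d) u(t0) + phi2(A,d) (u(t0+d)-u(t0))/d

with phi1 = int_0^d e^{A(d-s)} ds and phi2 = int_0^d e^{A(d-s)} s ds.
Working in the eigenbasis of A turns these into scalar functions of
lambda*d, which is what this module implements.  The propagation is exact
for piecewise-linear forcing, so no step-size tuning enters the model fits.
"""

from __future__ import annotations

import numpy as np

__all__ = ["phi1", "phi2", "lti_foh", "lti_foh_segments", "affine_recurrence"]

_SMALL = 1e-5


def phi1(lam: np.ndarray, d: np.ndarray) -> np.ndarray:
    """int_0^d e^{lam (d-s)} ds, elementwise; stable near lam*d = 0.

    Accepts real or complex eigenvalues.
    """
    lam = np.asarray(lam)
    d = np.asarray(d, dtype=float)
    z = lam * d
    safe = np.where(lam != 0.0, lam, 1.0)
    with np.errstate(over="ignore", invalid="ignore"):
        out = np.where(
            np.abs(z) > _SMALL,
            (np.exp(z) - 1.0) / safe,
            d * (1.0 + z / 2.0 + z * z / 6.0 + z ** 3 / 24.0),
        )
    return out


def phi2(lam: np.ndarray, d: np.ndarray) -> np.ndarray:
    """int_0^d e^{lam (d-s)} s ds, elementwise; stable near lam*d = 0."""
    lam = np.asarray(lam)
    d = np.asarray(d, dtype=float)
    z = lam * d
    safe = np.where(lam != 0.0, lam, 1.0)
    with np.errstate(over="ignore", invalid="ignore"):
        out = np.where(
            np.abs(z) > _SMALL,
            (np.exp(z) - 1.0 - z) / (safe * safe),
            d * d * (0.5 + z / 6.0 + z * z / 24.0 + z ** 3 / 120.0),
        )
    return out


def lti_foh(
    A: np.ndarray,
    t_nodes: np.ndarray,
    u_nodes: np.ndarray,
    x0: np.ndarray,
) -> np.ndarray:
    """Propagate dx/dt = A x + u(t) exactly through piecewise-linear u.

    Parameters
    ----------
    A : (n, n) system matrix, assumed diagonalisable with nonzero
        eigenvalues (compartmental matrices used here qualify).
    t_nodes : (m,) strictly increasing segment nodes.
    u_nodes : (m, n) forcing values at the nodes; u is linearly
        interpolated inside each segment.  A jump input (piecewise
        constant) is represented by aligning segment nodes with the jumps.
    x0 : (n,) state at t_nodes[0].

    Returns
    -------
    (m, n) array of states at every node.
    """
    u = np.asarray(u_nodes, dtype=float)
    return lti_foh_segments(A, t_nodes, u[:-1], u[1:], x0)


def lti_foh_segments(
    A: np.ndarray,
    t_nodes: np.ndarray,
    u_start: np.ndarray,
    u_end: np.ndarray,
    x0: np.ndarray,
) -> np.ndarray:
    """Like :func:`lti_foh` but with per-segment forcing endpoints.

    ``u_start[k]`` and ``u_end[k]`` give the forcing at the two ends of
    segment k = [t_nodes[k], t_nodes[k+1]]; a piecewise-constant input
    that jumps at a node is represented by u_start[k] == u_end[k]
    differing across segments.
    """
    A = np.asarray(A, dtype=float)
    t = np.asarray(t_nodes, dtype=float)
    us = np.asarray(u_start, dtype=float)
    ue = np.asarray(u_end, dtype=float)
    n = A.shape[0]
    m = t.size
    if us.shape != (m - 1, n) or ue.shape != (m - 1, n):
        raise ValueError(f"segment inputs must have shape {(m - 1, n)}")

    lam, V = np.linalg.eig(A)
    Vinv = np.linalg.inv(V)
    d = np.diff(t)  # (m-1,)
    zs = np.einsum("ij,kj->ki", Vinv, us)
    ze = np.einsum("ij,kj->ki", Vinv, ue)

    E = np.exp(lam[None, :] * d[:, None])  # (m-1, n)
    P1 = phi1(lam[None, :], d[:, None])
    P2 = phi2(lam[None, :], d[:, None])
    slope = (ze - zs) / d[:, None]

    out = np.empty((m, n), dtype=complex)
    x = Vinv @ np.asarray(x0, dtype=complex)
    out[0] = x
    for k in range(m - 1):
        x = E[k] * x + P1[k] * zs[k] + P2[k] * slope[k]
        out[k + 1] = x
    states = np.einsum("ij,kj->ki", V, out)
    return np.real(states)


def affine_recurrence(alpha: np.ndarray, beta: np.ndarray, x0) -> np.ndarray:
    """Evaluate x_{k+1} = alpha_k x_k + beta_k for scalar or stacked states.

    ``alpha`` has shape (n,); ``beta`` has shape (n,) or (n, r) for r
    independent drive columns sharing the same alpha (used when profiling
    linear parameters out of the glucose model).  Returns (n+1,) or
    (n+1, r) including the initial state.  Uses blocked cumulative
    products so strongly-decaying segments cannot underflow.
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    n = alpha.size
    scalar = beta.ndim == 1
    b = beta[:, None] if scalar else beta
    r = b.shape[1]
    x0 = np.broadcast_to(np.asarray(x0, dtype=float), (r,)).copy()

    out = np.empty((n + 1, r))
    out[0] = x0
    # single-pass path when the cumulative decay cannot under/overflow
    if np.all(alpha > 0.0):
        logc = np.cumsum(np.log(alpha))
        if -550.0 < logc.min() and logc.max() < 550.0:
            c = np.cumprod(alpha)
            s = np.cumsum(b / c[:, None], axis=0)
            out[1:] = c[:, None] * (x0[None, :] + s)
            return out[:, 0] if scalar else out
    block = 64
    pos = 0
    x = x0
    while pos < n:
        end = min(pos + block, n)
        a = alpha[pos:end]
        c = np.cumprod(a)
        if c[-1] != 0.0 and np.all(np.abs(c) > 1e-280):
            # x_k = c_{k-1} * (x + sum_{j<=k-1} b_j / c_j)
            s = np.cumsum(b[pos:end] / c[:, None], axis=0)
            out[pos + 1 : end + 1] = c[:, None] * (x[None, :] + s)
        else:  # fall back to the plain loop on pathological decay
            for k in range(pos, end):
                x = alpha[k] * x + b[k]
                out[k + 1] = x
        x = out[end].copy()
        pos = end
    return out[:, 0] if scalar else out
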