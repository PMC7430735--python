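"""Adaptive Gauss-Hermite quadrature over cluster random intercepts.

Each cluster j contributes log ∫ exp(ll_j(v)) φ(v; 0, Σ) dv where ll_j is
the cluster's conditional log-likelihood as a function of its random
effects v (a scalar for one intercept, a pair (u, w) for two).  The rule is
adaptive: the integrand's mode is located per cluster by a damped Newton
search with finite-difference derivatives, the Gauss-Hermite grid is
centred at the mode and scaled by the curvature there, and the weighted
node values are combined with log-sum-exp.  Mode searches can be warm
started from a previous call, which makes repeated evaluations inside an
optimizer cheap.

Cluster functions are vectorized across both clusters and evaluation
points: ``cluster_fn`` maps an array of shape (J,) or (J, M) of per-cluster
random-effect values to per-cluster conditional log-likelihoods of the same
shape, so a whole node grid is evaluated in one call.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

_FD_STEP = 1e-4
_MAX_NEWTON = 50
_NEWTON_TOL = 1e-9
_SQRT2 = np.sqrt(2.0)


def gauss_hermite(n: int):
    """Nodes and log-weights of the n-point (physicists') Gauss-Hermite rule."""
    x, w = np.polynomial.hermite.hermgauss(n)
    return x, np.log(w)


def _find_modes_1d(g, mode0):
    """Vectorized damped-Newton maximization of per-cluster g(u)."""
    u = np.array(mode0, dtype=float, copy=True)
    h = _FD_STEP
    g0 = g(u)
    for _ in range(_MAX_NEWTON):
        gpm = g(np.stack([u + h, u - h], axis=1))
        grad = (gpm[:, 0] - gpm[:, 1]) / (2 * h)
        hess = (gpm[:, 0] - 2 * g0 + gpm[:, 1]) / (h * h)
        hess = np.where(hess < -1e-8, hess, -1.0)
        step = np.clip(-grad / hess, -2.0, 2.0)
        for _ in range(8):
            g1 = g(u + step)
            ok = g1 >= g0 - 1e-12
            if np.all(ok):
                break
            step = np.where(ok, step, step / 2.0)
        u = u + step
        g0 = g1
        if np.max(np.abs(step)) < _NEWTON_TOL:
            break
    gpm = g(np.stack([u + h, u - h], axis=1))
    hess = (gpm[:, 0] - 2 * g0 + gpm[:, 1]) / (h * h)
    hess = np.where(hess < -1e-8, hess, -1e-8)
    return u, hess


def aghq_1d(cluster_fn, sigma2: float, J: int, n_nodes: int, mode_cache=None):
    """Per-cluster log ∫ exp(ll_j(u)) φ(u; 0, σ²) du, adaptively.

    ``cluster_fn`` maps (J,) or (J, M) random-effect values to conditional
    log-likelihoods of the same shape.  A zero variance collapses the
    integral to ll_j(0).  ``mode_cache`` (a dict) warm starts the mode
    search across calls.
    """
    if sigma2 <= 0:
        return cluster_fn(np.zeros(J))
    log_phi_const = -0.5 * np.log(2 * np.pi * sigma2)

    def g(u):
        if u.ndim == 2:
            return cluster_fn(u) + log_phi_const - 0.5 * u * u / sigma2
        return cluster_fn(u) + log_phi_const - 0.5 * u * u / sigma2

    mode0 = np.zeros(J)
    if mode_cache is not None and "mode" in mode_cache:
        mode0 = mode_cache["mode"]
    mode, hess = _find_modes_1d(g, mode0)
    if mode_cache is not None:
        mode_cache["mode"] = mode
    tau = 1.0 / np.sqrt(-hess)  # (J,)
    x, logw = gauss_hermite(n_nodes)
    # ∫ e^{g} du ≈ √2 τ Σ_k w_k e^{x_k²} e^{g(mode + √2 τ x_k)}
    pts = mode[:, None] + _SQRT2 * tau[:, None] * x[None, :]
    body = g(pts) + logw[None, :] + (x * x)[None, :]
    return 0.5 * np.log(2.0) + np.log(tau) + logsumexp(body, axis=1)


def _fd_derivs_2d(g, u, w, g0):
    """Gradient and Hessian of g at (u, w) by central differences.

    One batched call evaluates the 8-point stencil for all clusters.
    """
    h = _FD_STEP
    du_s = np.array([h, -h, 0, 0, h, h, -h, -h])
    dw_s = np.array([0, 0, h, -h, h, -h, h, -h])
    vals = g(u[:, None] + du_s[None, :], w[:, None] + dw_s[None, :])
    gpu, gmu, gpw, gmw, gpp, gpm, gmp, gmm = vals.T
    du = (gpu - gmu) / (2 * h)
    dw = (gpw - gmw) / (2 * h)
    huu = (gpu - 2 * g0 + gmu) / (h * h)
    hww = (gpw - 2 * g0 + gmw) / (h * h)
    huw = (gpp - gpm - gmp + gmm) / (4 * h * h)
    return du, dw, huu, huw, hww


def _find_modes_2d(g, mode0):
    """Damped-Newton maximization of g(u, w) per cluster, vectorized."""
    u = np.array(mode0[0], dtype=float, copy=True)
    w = np.array(mode0[1], dtype=float, copy=True)
    g0 = g(u, w)
    for _ in range(_MAX_NEWTON):
        du, dw, huu, huw, hww = _fd_derivs_2d(g, u, w, g0)
        # force negative definiteness: shift eigenvalues below -1
        tr = huu + hww
        disc = np.sqrt(np.maximum((huu - hww) ** 2 + 4 * huw**2, 0.0))
        lam_max = 0.5 * (tr + disc)
        shift = np.where(lam_max > -1e-8, lam_max + 1.0, 0.0)
        huu = huu - shift
        hww = hww - shift
        det = huu * hww - huw * huw
        su = -(hww * du - huw * dw) / det
        sw = -(huu * dw - huw * du) / det
        norm = np.sqrt(su * su + sw * sw)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(norm > 2.0, 2.0 / norm, 1.0)
        su *= scale
        sw *= scale
        for _ in range(8):
            g1 = g(u + su, w + sw)
            ok = g1 >= g0 - 1e-12
            if np.all(ok):
                break
            su = np.where(ok, su, su / 2.0)
            sw = np.where(ok, sw, sw / 2.0)
        u = u + su
        w = w + sw
        g0 = g1
        if max(np.max(np.abs(su)), np.max(np.abs(sw))) < _NEWTON_TOL:
            break
    _, _, huu, huw, hww = _fd_derivs_2d(g, u, w, g0)
    return (u, w), (huu, huw, hww)


def aghq_2d(cluster_fn, sigma2_u: float, sigma2_w: float, J: int, n_nodes: int,
            mode_cache=None):
    """Per-cluster log ∬ exp(ll_j(u, w)) φ(u; 0, σ_u²) φ(w; 0, σ_w²) du dw.

    Tensor-product adaptive rule with n_nodes per dimension; the grid is
    centred at the joint posterior mode and whitened with the Cholesky
    factor of the negative inverse Hessian there.  A zero variance in either
    dimension degenerates that dimension to a point mass at 0.
    ``cluster_fn`` maps (J,)/(J, M) pairs (u, w) to same-shaped per-cluster
    conditional log-likelihoods.
    """
    if sigma2_u <= 0 and sigma2_w <= 0:
        return cluster_fn(np.zeros(J), np.zeros(J))
    if sigma2_u <= 0:
        return aghq_1d(lambda w: cluster_fn(np.zeros_like(w), w), sigma2_w, J,
                       n_nodes, mode_cache=mode_cache)
    if sigma2_w <= 0:
        return aghq_1d(lambda u: cluster_fn(u, np.zeros_like(u)), sigma2_u, J,
                       n_nodes, mode_cache=mode_cache)

    cu = -0.5 * np.log(2 * np.pi * sigma2_u)
    cw = -0.5 * np.log(2 * np.pi * sigma2_w)

    def g(u, w):
        return (cluster_fn(u, w) + cu + cw
                - 0.5 * u * u / sigma2_u - 0.5 * w * w / sigma2_w)

    mode0 = (np.zeros(J), np.zeros(J))
    if mode_cache is not None and "mode2" in mode_cache:
        mode0 = mode_cache["mode2"]
    (mu_, mw_), (huu, huw, hww) = _find_modes_2d(g, mode0)
    if mode_cache is not None:
        mode_cache["mode2"] = (mu_, mw_)

    # S_j = (-H_j)^{-1}; fall back to a diagonal scaling where -H is not SPD
    a, b, d = -huu, -huw, -hww
    det = a * d - b * b
    bad = (a <= 1e-10) | (d <= 1e-10) | (det <= 1e-12)
    a = np.where(bad, np.maximum(a, 1.0 / sigma2_u), a)
    d = np.where(bad, np.maximum(d, 1.0 / sigma2_w), d)
    b = np.where(bad, 0.0, b)
    det = a * d - b * b
    s11 = d / det
    s12 = -b / det
    s22 = a / det
    l11 = np.sqrt(s11)
    l21 = s12 / l11
    l22 = np.sqrt(np.maximum(s22 - l21 * l21, 1e-16))
    logdetA = np.log(l11) + np.log(l22)

    x, logw = gauss_hermite(n_nodes)
    K = len(x)
    t1 = np.repeat(x, K)
    t2 = np.tile(x, K)
    logw_grid = (np.repeat(logw, K) + np.tile(logw, K) + t1 * t1 + t2 * t2)
    u_pts = mu_[:, None] + _SQRT2 * l11[:, None] * t1[None, :]
    w_pts = (mw_[:, None] + _SQRT2 * (l21[:, None] * t1[None, :]
                                      + l22[:, None] * t2[None, :]))
    body = g(u_pts, w_pts) + logw_grid[None, :]
    return np.log(2.0) + logdetA + logsumexp(body, axis=1)
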