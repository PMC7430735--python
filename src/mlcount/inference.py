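"""Marginal maximum likelihood for multilevel two-part count models.

Cluster random intercepts are integrated out of the likelihood with
adaptive Gauss-Hermite quadrature (:mod:`mlcount.quadrature`).  For the
hurdle families the marginal likelihood factorizes exactly — the zero part
depends only on the zero-part intercept w and the truncated count part only
on u — so each factor is integrated with a one-dimensional rule and the two
parts are fitted separately.  The zero-inflated families do not factorize
(the zero branch mixes both parts) and use a tensor-product two-dimensional
rule.

Optimization is quasi-Newton (L-BFGS-B) on a transformed scale: variance
components enter as log(sigma) and overdispersion as log(alpha), which
enforces positivity.  Standard errors come from the numerically
differentiated Hessian of the marginal log-likelihood at the optimum;
rate-ratio and odds-ratio tables use Wald intervals exp(est ± 1.96 SE),
and variance-component intervals are Wald on log(sigma), back-transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln, logit

from .models import (
    HURDLE_FAMILIES,
    ModelSpec,
    NumericDegeneracyError,
    ParameterVector,
)
from .quadrature import aghq_1d, aghq_2d

Z95 = 1.959963984540054  # standard normal 97.5% quantile

_BOUND_COEF = (-30.0, 30.0)
_BOUND_LOG_ALPHA = (-8.0, 5.0)
_BOUND_LOG_SIGMA = (-6.0, 3.0)


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass
class TermInfo:
    """One model term: a continuous column or a reference-coded categorical."""

    variable: str
    columns: list  # column names contributed to the design, in order
    reference: str | None = None  # reference category label, if categorical


@dataclass
class ModelData:
    """Compact design representation of a mother-level dataset.

    y is the per-mother death count, X / Z the count- and zero-part design
    matrices (leading intercept column), cluster the 0..J-1 enumeration-area
    codes.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    cluster: np.ndarray
    n_clusters: int
    count_names: list = field(default_factory=lambda: ["Intercept"])
    zero_names: list = field(default_factory=lambda: ["Intercept"])
    count_terms: list = field(default_factory=list)
    zero_terms: list = field(default_factory=list)
    cluster_labels: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y)
        if np.any(self.y < 0) or not np.all(np.equal(np.mod(self.y, 1), 0)):
            raise ValueError("outcome must contain nonnegative integers")
        self.y = self.y.astype(np.int64)
        self.X = np.atleast_2d(np.asarray(self.X, float))
        self.Z = np.atleast_2d(np.asarray(self.Z, float))
        self.cluster = np.asarray(self.cluster, dtype=np.int64)
        n = len(self.y)
        if self.X.shape[0] != n or self.Z.shape[0] != n or len(self.cluster) != n:
            raise ValueError("y, X, Z and cluster must have matching lengths")

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def signature(self) -> tuple:
        """Cheap fingerprint used to refuse comparing fits on different data."""
        return (self.n_obs, self.n_clusters, int(self.y.sum()),
                int((self.y * np.arange(1, self.n_obs + 1)).sum() % (2**31)))


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Packing:
    p: int
    q: int
    has_alpha: bool
    re_u: bool
    re_w: bool

    @property
    def k(self) -> int:
        return self.p + self.q + self.has_alpha + self.re_u + self.re_w

    def names(self, count_names, zero_names):
        out = [f"count:{n}" for n in count_names]
        out += [f"zero:{n}" for n in zero_names]
        if self.has_alpha:
            out.append("log_alpha")
        if self.re_u:
            out.append("log_sigma_u")
        if self.re_w:
            out.append("log_sigma_w")
        return out

    def unpack(self, theta):
        theta = np.asarray(theta, float)
        p, q = self.p, self.q
        beta = theta[:p]
        gamma = theta[p:p + q]
        i = p + q
        alpha = None
        if self.has_alpha:
            alpha = float(np.exp(theta[i])); i += 1
        s2u = 0.0
        if self.re_u:
            s2u = float(np.exp(2 * theta[i])); i += 1
        s2w = 0.0
        if self.re_w:
            s2w = float(np.exp(2 * theta[i])); i += 1
        return beta, gamma, alpha, s2u, s2w

    def pack(self, params: ParameterVector):
        parts = [params.beta, params.gamma]
        if self.has_alpha:
            parts.append([np.log(max(params.alpha, 1e-8))])
        if self.re_u:
            parts.append([0.5 * np.log(max(params.sigma2_u, 1e-6))])
        if self.re_w:
            parts.append([0.5 * np.log(max(params.sigma2_w, 1e-6))])
        return np.concatenate([np.atleast_1d(np.asarray(p, float)) for p in parts])

    def bounds(self):
        b = [_BOUND_COEF] * (self.p + self.q)
        if self.has_alpha:
            b.append(_BOUND_LOG_ALPHA)
        if self.re_u:
            b.append(_BOUND_LOG_SIGMA)
        if self.re_w:
            b.append(_BOUND_LOG_SIGMA)
        return b


def _packing_for(data: ModelData, spec: ModelSpec) -> _Packing:
    return _Packing(
        p=data.X.shape[1],
        q=data.Z.shape[1],
        has_alpha=spec.has_alpha,
        re_u=bool(spec.random_intercepts[0]),
        re_w=bool(spec.random_intercepts[1]),
    )


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------


def _log_expit(x):
    """log of the logistic function, stable for large |x|."""
    return -np.logaddexp(0.0, -x)


class _SegmentSum:
    """Per-cluster segment sums over a (possibly subset) observation set.

    Observations are pre-sorted by cluster; sums are computed with
    ``np.add.reduceat`` and scattered into a length-J vector so clusters
    absent from the subset contribute zero.
    """

    def __init__(self, cluster_codes, J):
        order = np.argsort(cluster_codes, kind="stable")
        self.order = order
        cs = np.asarray(cluster_codes)[order]
        self.present, self.starts = np.unique(cs, return_index=True)
        self.sorted_codes = cs
        self.J = J
        self.full = len(self.present) == J

    def __call__(self, lp):
        # lp: (m, M) per-observation values in sorted order -> (J, M)
        sums = np.add.reduceat(lp, self.starts, axis=0)
        if self.full:
            return sums
        out = np.zeros((self.J,) + lp.shape[1:])
        out[self.present] = sums
        return out


class MarginalLikelihood:
    """Evaluator of the marginal log-likelihood for one dataset and family.

    Holds warm-start caches for the per-cluster posterior-mode searches so
    that repeated evaluations inside an optimizer converge in a couple of
    Newton steps.  The conditional-likelihood kernels are inlined per
    family for speed and are checked against :func:`mlcount.models.family_logpmf`
    in the test suite.
    """

    def __init__(self, data: ModelData, spec: ModelSpec, quad_points: int = 15):
        if quad_points < 1:
            raise ValueError("quad_points must be >= 1")
        if data.n_obs == 0:
            raise ValueError("data is empty")
        self.data = data
        self.spec = spec
        self.quad_points = quad_points
        self._cache: dict = {}
        self._J = data.n_clusters

        seg_all = _SegmentSum(data.cluster, self._J)
        self._seg_all = seg_all
        self._y = data.y[seg_all.order].astype(float)
        self._X = data.X[seg_all.order]
        self._Z = data.Z[seg_all.order]
        self._cl = seg_all.sorted_codes
        self._is_zero = self._y == 0
        self._logfact = gammaln(self._y + 1.0)

        pos = np.flatnonzero(~self._is_zero)
        self._seg_pos = _SegmentSum(self._cl[pos], self._J)
        # already sorted; order within subset is identity
        self._ypos = self._y[pos]
        self._Xpos = self._X[pos]
        self._clpos = self._cl[pos]
        self._logfact_pos = self._logfact[pos]

    @staticmethod
    def _cols(v):
        """View a (J,) or (J, M) random-effect array as (J, M)."""
        v = np.asarray(v, float)
        return (v[:, None], True) if v.ndim == 1 else (v, False)

    # -- per-cluster conditional log-likelihood pieces ---------------------

    def _zero_part_fn(self, gamma):
        """Hurdle Bernoulli part: per-cluster loglik as a function of w."""
        xi0 = self._Z @ gamma
        is_zero = self._is_zero
        cl = self._cl
        seg = self._seg_all

        def fn(w):
            w2, squeeze = self._cols(w)
            xi = xi0[:, None] + w2[cl]
            lp = np.where(is_zero[:, None], _log_expit(xi), _log_expit(-xi))
            out = seg(lp)
            return out[:, 0] if squeeze else out

        return fn

    def _trunc_count_fn(self, beta, alpha):
        """Hurdle truncated-count part on positives, as a function of u."""
        y = self._ypos
        eta0 = self._Xpos @ beta
        cl = self._clpos
        seg = self._seg_pos
        logfact = self._logfact_pos
        if self.spec.family == "NBH":
            r = 1.0 / alpha
            const = gammaln(y + r) - logfact - gammaln(r)

            def fn(u):
                u2, squeeze = self._cols(u)
                eta = np.clip(eta0[:, None] + u2[cl], -700, 700)
                lam = np.log1p(alpha * np.exp(eta))
                # log ZTNB = const + y log(alpha mu) - (r+y) log(1+alpha mu)
                #            - log(1 - (1+alpha mu)^{-r})
                lp = (const[:, None] + y[:, None] * (np.log(alpha) + eta)
                      - (r + y[:, None]) * lam - np.log(-np.expm1(-r * lam)))
                out = seg(lp)
                return out[:, 0] if squeeze else out
        else:

            def fn(u):
                u2, squeeze = self._cols(u)
                eta = np.clip(eta0[:, None] + u2[cl], -700, 700)
                mu = np.exp(eta)
                lp = (y[:, None] * eta - mu - logfact[:, None]
                      - np.log(-np.expm1(-mu)))
                out = seg(lp)
                return out[:, 0] if squeeze else out

        return fn

    def _zi_fn(self, beta, gamma, alpha):
        """Zero-inflated families: per-cluster loglik over (u, w)."""
        y = self._y
        eta0 = self._X @ beta
        xi0 = self._Z @ gamma
        cl = self._cl
        seg = self._seg_all
        is_zero = self._is_zero
        logfact = self._logfact
        nb = self.spec.family == "ZINB"
        if nb:
            r = 1.0 / alpha
            const = gammaln(y + r) - logfact - gammaln(r)

        def fn(u, w):
            u2, squeeze = self._cols(u)
            w2, _ = self._cols(w)
            eta = np.clip(eta0[:, None] + u2[cl], -700, 700)
            xi = xi0[:, None] + w2[cl]
            log_pi = _log_expit(xi)
            log_1mpi = _log_expit(-xi)
            if nb:
                lam = np.log1p(alpha * np.exp(eta))
                logp0 = -r * lam
                base = (const[:, None] + y[:, None] * (np.log(alpha) + eta)
                        - (r + y[:, None]) * lam)
            else:
                mu = np.exp(eta)
                logp0 = -mu
                base = y[:, None] * eta - mu - logfact[:, None]
            lp = np.where(is_zero[:, None],
                          np.logaddexp(log_pi, log_1mpi + logp0),
                          log_1mpi + base)
            out = seg(lp)
            return out[:, 0] if squeeze else out

        return fn

    # -- public evaluations ------------------------------------------------

    def zero_part_loglik(self, gamma, s2w) -> float:
        fn = self._zero_part_fn(np.asarray(gamma, float))
        cache = self._cache.setdefault("w", {})
        return float(np.sum(aghq_1d(fn, s2w, self._J, self.quad_points, cache)))

    def count_part_loglik(self, beta, alpha, s2u) -> float:
        fn = self._trunc_count_fn(np.asarray(beta, float), alpha)
        cache = self._cache.setdefault("u", {})
        return float(np.sum(aghq_1d(fn, s2u, self._J, self.quad_points, cache)))

    def loglik(self, params: ParameterVector) -> float:
        spec = self.spec
        if spec.family in HURDLE_FAMILIES:
            return (self.zero_part_loglik(params.gamma, params.sigma2_w)
                    + self.count_part_loglik(params.beta, params.alpha,
                                             params.sigma2_u))
        fn = self._zi_fn(np.asarray(params.beta, float),
                         np.asarray(params.gamma, float), params.alpha)
        cache = self._cache.setdefault("uw", {})
        vals = aghq_2d(fn, params.sigma2_u, params.sigma2_w, self._J,
                       self.quad_points, cache)
        if not np.all(np.isfinite(vals)):
            j = int(np.flatnonzero(~np.isfinite(vals))[0])
            raise FloatingPointError(
                f"marginal likelihood non-finite for cluster index {j}"
            )
        return float(np.sum(vals))


def marginal_loglik(data: ModelData, params: ParameterVector, spec: ModelSpec,
                    quad_points: int = 15) -> float:
    """Marginal log-likelihood (nats), cluster random effects integrated out.

    Σ_j log ∬ L_j(u, w) φ(u; 0, σ_u²) φ(w; 0, σ_w²) du dw by adaptive
    Gauss-Hermite quadrature; one-dimensional factorized rules for hurdle
    families, a tensor-product rule for zero-inflated families.  Zero
    variances collapse the corresponding dimension to u = 0 (or w = 0).
    """
    return MarginalLikelihood(data, spec, quad_points).loglik(params)


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class EffectRow:
    part: str  # "count" or "zero"
    name: str
    estimate: float | None
    se: float | None
    ratio: float | None
    ci_low: float | None
    ci_high: float | None
    is_reference: bool = False


@dataclass
class VarianceComponentRow:
    part: str
    estimate: float
    ci_low: float | None
    ci_high: float | None
    note: str = ""


@dataclass
class FitResult:
    """Maximum-likelihood fit of one two-part multilevel model."""

    spec: ModelSpec
    params_hat: ParameterVector
    theta_hat: np.ndarray
    theta_names: list
    vcov: np.ndarray
    loglik: float
    n_obs: int
    n_clusters: int
    k: int
    converged: bool
    grad_norm: float
    boundary: dict
    trace: list
    data_signature: tuple
    count_names: list
    zero_names: list
    count_terms: list
    zero_terms: list
    quad_points: int = 15
    message: str = ""

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def aic(self) -> float:
        return self.deviance + 2.0 * self.k

    @property
    def bic(self) -> float:
        return self.deviance + self.k * np.log(self.n_obs)

    def se(self, name: str) -> float:
        i = self.theta_names.index(name)
        return float(np.sqrt(max(self.vcov[i, i], 0.0)))


# ---------------------------------------------------------------------------
# numerical derivatives
# ---------------------------------------------------------------------------


def numeric_gradient(f, x, step=1e-5):
    x = np.asarray(x, float)
    g = np.zeros_like(x)
    for i in range(len(x)):
        h = step * (1.0 + abs(x[i]))
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def numeric_hessian(f, x, step=1e-4):
    """Central-difference Hessian; symmetric by construction."""
    x = np.asarray(x, float)
    k = len(x)
    H = np.zeros((k, k))
    hs = step * (1.0 + np.abs(x))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k); ei[i] = hs[i]
        fpp = f(x + 2 * ei)
        fmm = f(x - 2 * ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / (4 * hs[i] ** 2)
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = hs[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * hs[i] * hs[j])
    return H


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _start_values(data: ModelData, spec: ModelSpec) -> ParameterVector:
    """No-random-effect two-part fit used as the starting point.

    Maximizes the conditional likelihood at u = w = 0; variance components
    start at sigma = 0.3 on each active part.
    """
    no_re = replace(spec, random_intercepts=(False, False))
    pk = _packing_for(data, no_re)
    ml = MarginalLikelihood(data, no_re, quad_points=1)

    ybar = max(float(np.mean(data.y)), 0.05)
    zero_frac = float(np.mean(data.y == 0))
    beta0 = np.zeros(pk.p)
    beta0[0] = np.log(max(float(np.mean(data.y[data.y > 0])), 0.2)) \
        if spec.family in HURDLE_FAMILIES and np.any(data.y > 0) else np.log(ybar)
    gamma0 = np.zeros(pk.q)
    gamma0[0] = float(logit(np.clip(zero_frac, 0.02, 0.98)))
    theta0 = np.concatenate([beta0, gamma0, [np.log(0.5)] if pk.has_alpha else []])

    def nll(theta):
        beta, gamma, alpha, _, _ = pk.unpack(theta)
        try:
            return -ml.loglik(ParameterVector(beta, gamma, alpha=alpha))
        except (NumericDegeneracyError, FloatingPointError, OverflowError):
            return 1e12

    res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=pk.bounds(),
                            options={"maxiter": 300})
    beta, gamma, alpha, _, _ = pk.unpack(res.x)
    return ParameterVector(
        beta, gamma, alpha=alpha,
        sigma2_u=0.09 if spec.random_intercepts[0] else 0.0,
        sigma2_w=0.09 if spec.random_intercepts[1] else 0.0,
    )


def _maximize(obj, theta0, bounds, trace):
    """L-BFGS-B maximization of obj (a log-likelihood) with trace capture."""

    def nll(theta):
        v = obj(theta)
        if not np.isfinite(v):
            return 1e12
        return -v

    def cb(theta):
        trace.append(-nll(theta))

    res = optimize.minimize(
        nll, theta0, method="L-BFGS-B", jac="3-point", bounds=bounds,
        callback=cb, options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
    )
    return res


def fit(data: ModelData, spec: ModelSpec, quad_points: int = 15,
        start: ParameterVector | None = None,
        compute_vcov: bool = True) -> FitResult:
    """Fit a two-part multilevel model by marginal maximum likelihood.

    Hurdle families are fitted as two independent maximizations (the
    marginal likelihood factorizes exactly); zero-inflated families as one
    joint maximization with two-dimensional quadrature.  Returns a
    :class:`FitResult` whether or not the optimizer reports convergence;
    check ``converged`` and ``boundary``.  ``compute_vcov=False`` skips the
    numerical observed-information matrix (useful when only information
    criteria are needed).
    """
    if data.n_clusters < 2:
        raise ValueError("need at least 2 clusters to estimate cluster variances")
    if not (np.any(data.y == 0) and np.any(data.y > 0)):
        raise ValueError("two-part families need at least one zero and one "
                         "positive outcome")
    pk = _packing_for(data, spec)
    if start is None:
        start = _start_values(data, spec)
    theta0 = pk.pack(start)
    ml = MarginalLikelihood(data, spec, quad_points)
    trace: list = []

    if spec.family in HURDLE_FAMILIES:
        # indices of the two separable blocks within the full theta
        idx_count = list(range(pk.p))
        i = pk.p + pk.q
        if pk.has_alpha:
            idx_count.append(i); i += 1
        if pk.re_u:
            idx_count.append(i); i += 1
        idx_zero = list(range(pk.p, pk.p + pk.q))
        if pk.re_w:
            idx_zero.append(i)

        all_bounds = pk.bounds()
        theta = np.array(theta0, float)

        def count_obj(tc):
            th = theta.copy()
            th[idx_count] = tc
            beta, _, alpha, s2u, _ = pk.unpack(th)
            try:
                return ml.count_part_loglik(beta, alpha, s2u)
            except (NumericDegeneracyError, FloatingPointError, OverflowError):
                return -np.inf

        def zero_obj(tz):
            th = theta.copy()
            th[idx_zero] = tz
            _, gamma, _, _, s2w = pk.unpack(th)
            return ml.zero_part_loglik(gamma, s2w)

        res_c = _maximize(count_obj, theta0[idx_count],
                          [all_bounds[i] for i in idx_count], trace)
        res_z = _maximize(zero_obj, theta0[idx_zero],
                          [all_bounds[i] for i in idx_zero], trace)
        theta[idx_count] = res_c.x
        theta[idx_zero] = res_z.x
        success = bool(res_c.success and res_z.success)
        message = f"count: {res_c.message}; zero: {res_z.message}"

        vcov = np.zeros((pk.k, pk.k))
        if compute_vcov:
            Hc = numeric_hessian(lambda t: count_obj(t), res_c.x)
            Hz = numeric_hessian(lambda t: zero_obj(t), res_z.x)
            # off-block covariances are exactly zero under factorization
            vcov[np.ix_(idx_count, idx_count)] = _safe_inv(-Hc)
            vcov[np.ix_(idx_zero, idx_zero)] = _safe_inv(-Hz)
        else:
            vcov[:] = np.nan
        grad = np.zeros(pk.k)
        grad[idx_count] = numeric_gradient(count_obj, res_c.x)
        grad[idx_zero] = numeric_gradient(zero_obj, res_z.x)
        ll = count_obj(res_c.x) + zero_obj(res_z.x)
    else:
        def obj(theta):
            beta, gamma, alpha, s2u, s2w = pk.unpack(theta)
            try:
                return ml.loglik(ParameterVector(beta, gamma, alpha=alpha,
                                                 sigma2_u=s2u, sigma2_w=s2w))
            except (NumericDegeneracyError, FloatingPointError, OverflowError):
                return -np.inf

        res = _maximize(obj, theta0, pk.bounds(), trace)
        theta = res.x
        success = bool(res.success)
        message = str(res.message)
        if compute_vcov:
            vcov = _safe_inv(-numeric_hessian(obj, theta))
        else:
            vcov = np.full((pk.k, pk.k), np.nan)
        grad = numeric_gradient(obj, theta)
        ll = obj(theta)

    grad_norm = float(np.max(np.abs(grad)))
    # relative criterion: FD gradients of a likelihood of magnitude |ll|
    # carry noise proportional to it
    converged = success or grad_norm < 1e-5 * (1.0 + abs(ll))

    beta, gamma, alpha, s2u, s2w = pk.unpack(theta)
    boundary = {}
    names = pk.names(data.count_names, data.zero_names)
    for nm, active, val in (("sigma2_u", pk.re_u, s2u), ("sigma2_w", pk.re_w, s2w)):
        if active and val < 1e-3:
            boundary[nm] = val
            warnings.warn(f"variance component {nm} estimated at the boundary "
                          f"({val:.2e})", RuntimeWarning)
    params_hat = ParameterVector(beta, gamma, alpha=alpha,
                                 sigma2_u=s2u, sigma2_w=s2w)
    return FitResult(
        spec=spec, params_hat=params_hat, theta_hat=np.asarray(theta, float),
        theta_names=names, vcov=vcov, loglik=float(ll),
        n_obs=data.n_obs, n_clusters=data.n_clusters, k=pk.k,
        converged=converged, grad_norm=grad_norm, boundary=boundary,
        trace=trace, data_signature=data.signature(),
        count_names=list(data.count_names), zero_names=list(data.zero_names),
        count_terms=list(data.count_terms), zero_terms=list(data.zero_terms),
        quad_points=quad_points, message=message,
    )


def fit_families(data: ModelData, families, quad_points: int = 15,
                 compute_vcov: bool = True,
                 count_covariates=(), zero_covariates=()) -> dict:
    """Fit several families on the same data, warm-starting NB variants.

    ZINB starts from the fitted ZIP (with a small initial overdispersion)
    and NBH from the fitted PH when the simpler family was requested too;
    this shortens the quasi-Newton path without changing the optimum.
    Returns {family: FitResult} in the requested order.
    """
    warm_from = {"ZINB": "ZIP", "NBH": "PH"}
    fits: dict = {}
    for family in families:
        spec = ModelSpec(family, count_covariates=tuple(count_covariates),
                         zero_covariates=tuple(zero_covariates))
        start = None
        src = warm_from.get(family)
        if src in fits:
            p = fits[src].params_hat
            start = ParameterVector(p.beta, p.gamma, alpha=0.3,
                                    sigma2_u=max(p.sigma2_u, 1e-4),
                                    sigma2_w=max(p.sigma2_w, 1e-4))
        fits[family] = fit(data, spec, quad_points=quad_points, start=start,
                           compute_vcov=compute_vcov)
    return fits


def _safe_inv(A):
    try:
        return np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(A)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def _term_rows(fit: FitResult, part: str, terms, names) -> list:
    prefix = f"{part}:"
    rows = []
    covered = set()
    by_col = {n: i for i, n in enumerate(fit.theta_names)}

    def coef_row(col):
        i = by_col[prefix + col]
        est = float(fit.theta_hat[i])
        se = float(np.sqrt(max(fit.vcov[i, i], 0.0)))
        return EffectRow(part, col, est, se, float(np.exp(est)),
                         float(np.exp(est - Z95 * se)),
                         float(np.exp(est + Z95 * se)))

    for t in terms:
        if t.reference is not None:
            rows.append(EffectRow(part, f"{t.variable}={t.reference}",
                                  None, None, 1.0, None, None,
                                  is_reference=True))
        for col in t.columns:
            rows.append(coef_row(col))
            covered.add(col)
    for col in names:
        if col in covered:
            continue
        rows.insert(0 if col == "Intercept" else len(rows), coef_row(col))
        covered.add(col)
    return rows


def effect_table(fit: FitResult) -> list:
    """IRR (count part) and OR (zero part) rows with 95% Wald intervals.

    The zero-part odds are the odds that the death count is zero (the
    hurdle convention used throughout this package).  Reference categories
    appear as ratio-1 rows with no interval.
    """
    if not fit.converged:
        raise ValueError("effect_table requires a converged fit")
    if fit.vcov is None or not np.all(np.isfinite(fit.vcov)):
        raise ValueError("fit has no usable covariance matrix")
    rows = _term_rows(fit, "count", fit.count_terms, fit.count_names)
    rows += _term_rows(fit, "zero", fit.zero_terms, fit.zero_names)
    return rows


def effect_frame(fit: FitResult) -> pd.DataFrame:
    rows = effect_table(fit)
    return pd.DataFrame(
        {
            "part": [r.part for r in rows],
            "name": [r.name for r in rows],
            "estimate": [r.estimate for r in rows],
            "se": [r.se for r in rows],
            "ratio": [r.ratio for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "reference": [r.is_reference for r in rows],
        }
    )


def variance_component_table(fit: FitResult) -> list:
    """Cluster-variance estimates with 95% intervals (Wald on log sigma).

    CI: exp(2 (log sigma_hat ± 1.96 SE(log sigma))), giving asymmetric
    positive intervals.  Boundary estimates get a one-sided note instead.
    """
    if not fit.converged:
        raise ValueError("variance_component_table requires a converged fit")
    out = []
    for part, name, active, est in (
        ("count", "log_sigma_u", fit.spec.random_intercepts[0],
         fit.params_hat.sigma2_u),
        ("zero", "log_sigma_w", fit.spec.random_intercepts[1],
         fit.params_hat.sigma2_w),
    ):
        if not active:
            continue
        key = "sigma2_u" if part == "count" else "sigma2_w"
        if key in fit.boundary:
            out.append(VarianceComponentRow(part, est, None, None,
                                            note="boundary estimate; interval "
                                                 "one-sided at 0"))
            continue
        i = fit.theta_names.index(name)
        se = float(np.sqrt(max(fit.vcov[i, i], 0.0)))
        ls = float(fit.theta_hat[i])
        out.append(VarianceComponentRow(
            part, est,
            float(np.exp(2 * (ls - Z95 * se))),
            float(np.exp(2 * (ls + Z95 * se))),
        ))
    return out


def variance_frame(fit: FitResult) -> pd.DataFrame:
    rows = variance_component_table(fit)
    return pd.DataFrame(
        {
            "part": [r.part for r in rows],
            "estimate": [r.estimate for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "note": [r.note for r in rows],
        }
    )


def model_comparison(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Deviance / AIC / BIC table sorted by AIC; the first row is selected.

    All fits must be on the same dataset (checked with a data fingerprint).
    """
    if not fits:
        raise ValueError("no fits to compare")
    sig = fits[0].data_signature
    for f in fits[1:]:
        if f.data_signature != sig:
            raise ValueError("fits were computed on different datasets; "
                             "information criteria are not comparable")
    df = pd.DataFrame(
        {
            "family": [f.spec.family for f in fits],
            "deviance": [f.deviance for f in fits],
            "aic": [f.aic for f in fits],
            "bic": [f.bic for f in fits],
            "k": [f.k for f in fits],
            "converged": [f.converged for f in fits],
        }
    ).sort_values("aic", kind="mergesort").reset_index(drop=True)
    df.attrs["selected"] = df.loc[0, "family"]
    return df


def information_criteria(deviance: float, k: int, n_obs: int) -> dict:
    """AIC = deviance + 2k; BIC = deviance + k ln(n), n = number of mothers."""
    return {
        "aic": deviance + 2.0 * k,
        "bic": deviance + k * float(np.log(n_obs)),
    }
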