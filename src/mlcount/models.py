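"""Probability mass functions and conditional log-likelihoods for two-part
count models of clustered data.

Four families are supported, all parameterized by a count-part mean ``mu``
and a zero-part probability ``pi``:

``ZIP``
    Zero-inflated Poisson: a point mass at zero with probability ``pi`` is
    mixed with a Poisson(mu) that itself can produce zeros.
``ZINB``
    Zero-inflated negative binomial: as ZIP but the base distribution is
    NB with mean ``mu`` and variance ``mu + alpha*mu**2`` (``alpha`` > 0 is
    the overdispersion).
``PH``
    Poisson hurdle: ``pi`` is P(Y=0) exactly; positive counts follow a
    zero-truncated Poisson(mu).
``NBH``
    Negative binomial hurdle: ``pi`` is P(Y=0); positives follow a
    zero-truncated NB(mu, alpha).

Convention: in the hurdle families the zero part models the probability
that the count IS zero (not the probability of crossing the hurdle); odds
ratios from the zero part are therefore odds of a zero count.  The NB
parameterization uses size 1/alpha and success probability 1/(1+alpha*mu),
so exp of a count-part coefficient is an incidence rate ratio.

All pmf arithmetic is done on the log scale with log-gamma functions; both
``*_logpmf`` and ``*_pmf`` forms are exposed.  In a multilevel fit the
linear predictors receive Gaussian cluster random intercepts ``u`` (count
part) and ``w`` (zero part):

    log(mu_ij)   = x_ij' beta  + u_j
    logit(pi_ij) = z_ij' gamma + w_j
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, gammaln, log1p

FAMILIES = ("ZIP", "ZINB", "PH", "NBH")
NB_FAMILIES = ("ZINB", "NBH")
HURDLE_FAMILIES = ("PH", "NBH")
ZI_FAMILIES = ("ZIP", "ZINB")

# expit clipping keeps pi strictly inside (0, 1)
_PI_EPS = 1e-12


class NumericDegeneracyError(ValueError):
    """Raised when a truncation normalizer underflows to zero."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotherRecord:
    """One mother: outcome count, cluster id, and design vectors.

    ``x`` is the count-part covariate vector and ``z`` the zero-part vector;
    both include the leading intercept 1 and may differ.
    """

    cluster_id: object
    y: int
    x: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        if self.y < 0 or int(self.y) != self.y:
            raise ValueError(f"outcome must be a nonnegative integer, got {self.y!r}")
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))


@dataclass(frozen=True)
class ModelSpec:
    """Model family plus covariate sets for the two parts.

    ``random_intercepts`` is a (count part, zero part) flag pair.  Random
    slopes are accepted in the constructor as a declared extension point but
    are not implemented.
    """

    family: str
    count_covariates: tuple = ()
    zero_covariates: tuple = ()
    random_intercepts: tuple = (True, True)
    random_slopes: tuple = ()

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.random_slopes:
            raise NotImplementedError(
                "random slopes are an extension point and are not implemented"
            )
        object.__setattr__(self, "count_covariates", tuple(self.count_covariates))
        object.__setattr__(self, "zero_covariates", tuple(self.zero_covariates))

    @property
    def has_alpha(self) -> bool:
        return self.family in NB_FAMILIES


@dataclass(frozen=True)
class ParameterVector:
    """Parameters of a two-part multilevel model.

    beta are count-part coefficients (log scale, exp -> IRR), gamma are
    zero-part coefficients (logit scale, exp -> OR), alpha >= 0 the NB
    overdispersion, sigma2_u / sigma2_w the cluster intercept variances.
    """

    beta: np.ndarray
    gamma: np.ndarray
    alpha: float | None = None
    sigma2_u: float = 0.0
    sigma2_w: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, float)))
        object.__setattr__(self, "gamma", np.atleast_1d(np.asarray(self.gamma, float)))
        if self.alpha is not None and self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.sigma2_u < 0 or self.sigma2_w < 0:
            raise ValueError("variance components must be nonnegative")


@dataclass(frozen=True)
class RandomEffects:
    """Cluster-level intercept deviations (count part u, zero part w)."""

    u: float = 0.0
    w: float = 0.0


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------


def _check_y(y):
    y = np.asarray(y)
    if np.any(y < 0) or not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("y must contain nonnegative integers")
    return y.astype(float)


def _check_mu(mu):
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    return mu


def _check_pi(pi):
    pi = np.asarray(pi, dtype=float)
    if np.any(pi < 0) or np.any(pi > 1):
        raise ValueError("pi must lie in [0, 1]")
    return pi


def _check_alpha(alpha):
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    return alpha


def _log(p):
    # log with -inf for 0, no warning
    with np.errstate(divide="ignore"):
        return np.log(p)


# ---------------------------------------------------------------------------
# base log-pmfs
# ---------------------------------------------------------------------------


def _poisson_logpmf(y, mu):
    return y * np.log(mu) - mu - gammaln(y + 1.0)


def _nb_logpmf(y, mu, alpha):
    # size r = 1/alpha, p = 1/(1 + alpha*mu); mean mu, var mu + alpha*mu^2
    r = 1.0 / alpha
    log_1p_am = log1p(alpha * mu)
    return (
        gammaln(y + r)
        - gammaln(y + 1.0)
        - gammaln(r)
        - r * log_1p_am
        + y * (np.log(alpha * mu) - log_1p_am)
    )


def _nb_logp0(mu, alpha):
    """log P(Y=0) of the NB(mu, alpha): -log(1+alpha*mu)/alpha."""
    return -log1p(alpha * mu) / alpha


# ---------------------------------------------------------------------------
# family log-pmfs
# ---------------------------------------------------------------------------


def zip_logpmf(y, mu, pi):
    """Log pmf of the zero-inflated Poisson.

    P(0) = pi + (1-pi) e^{-mu};  P(y>0) = (1-pi) e^{-mu} mu^y / y!.
    """
    y = _check_y(y)
    mu = _check_mu(mu)
    pi = _check_pi(pi)
    y, mu, pi = np.broadcast_arrays(y, mu, pi)
    base = _poisson_logpmf(y, mu)
    with np.errstate(divide="ignore"):
        log_pi = _log(pi)
        log_1mpi = _log(1.0 - pi)
    zero = np.logaddexp(log_pi, log_1mpi + (-mu))
    out = np.where(y == 0, zero, log_1mpi + base)
    return out if out.shape else float(out)


def zinb_logpmf(y, mu, alpha, pi):
    """Log pmf of the zero-inflated negative binomial.

    P(0) = pi + (1-pi)(1+alpha*mu)^{-1/alpha}; positives are (1-pi) times
    the NB(mu, alpha) pmf.
    """
    y = _check_y(y)
    mu = _check_mu(mu)
    alpha = _check_alpha(alpha)
    pi = _check_pi(pi)
    y, mu, alpha, pi = np.broadcast_arrays(y, mu, alpha, pi)
    base = _nb_logpmf(y, mu, alpha)
    log_pi = _log(pi)
    log_1mpi = _log(1.0 - pi)
    zero = np.logaddexp(log_pi, log_1mpi + _nb_logp0(mu, alpha))
    out = np.where(y == 0, zero, log_1mpi + base)
    return out if out.shape else float(out)


def _log_trunc_normalizer(mu, alpha=None):
    """log(1 - P0) of the base distribution, computed stably.

    P0 = e^{-mu} (Poisson) or (1+alpha*mu)^{-1/alpha} (NB).  Raises
    NumericDegeneracyError when 1-P0 underflows (mu too small to carry any
    positive mass at machine precision).
    """
    logp0 = -mu if alpha is None else _nb_logp0(mu, alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(-np.expm1(logp0))
    if np.any(~np.isfinite(out)):
        raise NumericDegeneracyError(
            "zero-truncation normalizer underflowed: mu is too close to 0 for "
            "the truncated distribution to have representable positive mass"
        )
    return out


def hurdle_logpmf(y, mu, pi, family="PH", alpha=None):
    """Log pmf of the Poisson (PH) or negative binomial (NBH) hurdle.

    P(0) = pi exactly; positives are (1-pi) times the zero-truncated base
    pmf, i.e. base(y) / (1 - base(0)).
    """
    if family not in HURDLE_FAMILIES:
        raise ValueError(f"family must be one of {HURDLE_FAMILIES}, got {family!r}")
    if family == "NBH" and alpha is None:
        raise ValueError("alpha is required for the NBH family")
    y = _check_y(y)
    mu = _check_mu(mu)
    pi = _check_pi(pi)
    if family == "NBH":
        alpha = _check_alpha(alpha)
        y, mu, pi, alpha = np.broadcast_arrays(y, mu, pi, alpha)
        base = _nb_logpmf(y, mu, alpha)
        log_norm = _log_trunc_normalizer(mu, alpha)
    else:
        y, mu, pi = np.broadcast_arrays(y, mu, pi)
        base = _poisson_logpmf(y, mu)
        log_norm = _log_trunc_normalizer(mu)
    out = np.where(y == 0, _log(pi), _log(1.0 - pi) + base - log_norm)
    return out if out.shape else float(out)


def zip_pmf(y, mu, pi):
    return np.exp(zip_logpmf(y, mu, pi))


def zinb_pmf(y, mu, alpha, pi):
    return np.exp(zinb_logpmf(y, mu, alpha, pi))


def hurdle_pmf(y, mu, pi, family="PH", alpha=None):
    return np.exp(hurdle_logpmf(y, mu, pi, family=family, alpha=alpha))


def family_logpmf(family, y, mu, pi, alpha=None):
    """Dispatch to the family's log pmf."""
    if family == "ZIP":
        return zip_logpmf(y, mu, pi)
    if family == "ZINB":
        return zinb_logpmf(y, mu, alpha, pi)
    return hurdle_logpmf(y, mu, pi, family=family, alpha=alpha)


# ---------------------------------------------------------------------------
# linear predictors and conditional likelihood
# ---------------------------------------------------------------------------


def clipped_expit(xi):
    """Inverse logit clipped away from exact 0 and 1."""
    return np.clip(expit(xi), _PI_EPS, 1.0 - _PI_EPS)


def linear_predictors(record: MotherRecord, params: ParameterVector,
                      re: RandomEffects = RandomEffects()):
    """(mu, pi) for one mother given parameters and her cluster's effects."""
    if record.x.shape[-1] != params.beta.shape[0]:
        raise ValueError(
            f"count design length {record.x.shape[-1]} != beta length {params.beta.shape[0]}"
        )
    if record.z.shape[-1] != params.gamma.shape[0]:
        raise ValueError(
            f"zero design length {record.z.shape[-1]} != gamma length {params.gamma.shape[0]}"
        )
    eta = float(record.x @ params.beta) + re.u
    xi = float(record.z @ params.gamma) + re.w
    return float(np.exp(eta)), float(clipped_expit(xi))


def conditional_loglik(records: Sequence[MotherRecord], params: ParameterVector,
                       re: RandomEffects, spec: ModelSpec) -> float:
    """Cluster log-likelihood given the cluster's random effects.

    Sums log pmf over the mothers of one cluster at their observed counts,
    with (mu, pi) from :func:`linear_predictors`.  A pmf of zero at an
    observed count yields -inf with a warning rather than an exception.
    """
    ids = {r.cluster_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records span multiple clusters: {sorted(map(str, ids))}")
    total = 0.0
    for r in records:
        mu, pi = linear_predictors(r, params, re)
        ll = float(family_logpmf(spec.family, r.y, mu, pi, alpha=params.alpha))
        if not np.isfinite(ll):
            warnings.warn(
                f"pmf is zero at observed count y={r.y} (cluster {r.cluster_id}); "
                "conditional log-likelihood is -inf",
                RuntimeWarning,
            )
            return float("-inf")
        total += ll
    return total
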