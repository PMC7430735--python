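"""Synthetic EDHS-like clustered two-part count data with known truth.

The generator emulates the structure of the 2016 Ethiopian DHS birth-record
analysis dataset: ~645 enumeration areas (clusters), ~22 mothers per
cluster, a per-mother under-five death count with excess zeros and
overdispersion, Gaussian cluster random intercepts in both model parts,
and covariate marginals taken from the published category totals.  Because
the real microdata are restricted-access, every downstream stage of the
package is exercised against this generator, which emits the full truth
manifest alongside the data.

Also packaged here are the published category-wise death counts
(:data:`EDHS2016_CATEGORY_COUNTS`) and the published zero/total split
(:data:`EDHS2016_OUTCOME_SPLIT`), used as exact fixtures by the
descriptive stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .descriptives import ContingencyTable
from .io import build_design
from .models import FAMILIES, NB_FAMILIES

# ---------------------------------------------------------------------------
# published summary counts (2016 EDHS): per category, mothers with at least
# one under-five death and total mothers
# ---------------------------------------------------------------------------

EDHS2016_OUTCOME_SPLIT = {"zero_deaths": 7720, "total_mothers": 14370}

EDHS2016_CATEGORY_COUNTS = {
    "fathers_education": [("No education", 4403, 8250), ("Primary", 1736, 4101),
                          ("Secondary and above", 511, 2019)],
    "child_twin": [("Single", 6225, 13813), ("Multiple", 425, 557)],
    "place_of_delivery": [("Home", 5999, 10884), ("Public sector", 578, 3107),
                          ("Private sector", 73, 379)],
    "mothers_occupation": [("Housewife", 3552, 8169), ("Had working", 3098, 6201)],
    "fathers_occupation": [("Not working", 1300, 2579), ("Had working", 5350, 11791)],
    "mothers_education": [("No education", 5378, 9932), ("Primary", 1027, 3197),
                          ("Secondary and above", 245, 1241)],
    "marital_status": [("Others", 692, 1284), ("Married", 5958, 13086)],
    "drinking_water": [("Piped", 563, 1906), ("Others", 6087, 12464)],
    "toilet_facility": [("Use toilet", 3506, 7911), ("No toilet", 3144, 6459)],
    "breastfeeding": [("No", 3858, 6436), ("Yes", 2792, 7934)],
    "birth_order": [("First", 1213, 3206), ("2-3", 1951, 4705),
                    ("4 and above", 3486, 6459)],
    "residence": [("Urban", 816, 2512), ("Rural", 5834, 11858)],
    "religion": [("Orthodox", 1839, 4208), ("Muslim", 3564, 7348),
                 ("Others", 1247, 2814)],
    "contraceptive_use": [("No", 5471, 10976), ("Yes", 1179, 3394)],
    "vaccination": [("No", 6053, 11881), ("Yes", 597, 2489)],
    "wealth_index": [("Poor", 3896, 7820), ("Medium", 970, 2036),
                     ("Rich", 1784, 4514)],
    "sex_of_child": [("Male", 3642, 7607), ("Female", 3008, 6763)],
    "mothers_age_group": [("Below 20", 145, 974), ("20-29", 1377, 5201),
                          ("30-39", 2935, 5582), ("40+", 2193, 2613)],
    "antenatal_visits": [("No visits", 5654, 9658), ("1-3", 511, 2092),
                         ("4 and above", 485, 2620)],
    "birth_interval": [("0-24 months", 3669, 7129), ("25-36 months", 1642, 3407),
                       (">36 months", 1339, 3834)],
}


def fixture_tables() -> list:
    """Published category-count fixtures as ContingencyTable objects."""
    return [ContingencyTable(var, list(rows))
            for var, rows in EDHS2016_CATEGORY_COUNTS.items()]


# ---------------------------------------------------------------------------
# scenario definition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Covariate:
    """One simulated covariate: categorical with level probabilities, or
    Gaussian continuous with mean/sd."""

    name: str
    kind: str  # "categorical" | "continuous"
    levels: tuple = ()
    probs: tuple = ()
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self):
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical":
            if len(self.levels) != len(self.probs) or len(self.levels) < 2:
                raise ValueError(f"{self.name}: levels and probs must align "
                                 "(>= 2 levels)")
            if abs(sum(self.probs) - 1.0) > 1e-9 or any(p < 0 for p in self.probs):
                raise ValueError(f"{self.name}: probabilities must be "
                                 "nonnegative and sum to 1")
        elif self.sd < 0:
            raise ValueError(f"{self.name}: sd must be nonnegative")


@dataclass(frozen=True)
class Scenario:
    """Generating truth for one synthetic dataset.

    ``beta`` / ``gamma`` are keyed by design column name ("Intercept",
    "var=level" for categoricals, the bare name for continuous); missing
    keys mean a zero coefficient.  ``mothers_per_cluster`` is a fixed int
    or ("poisson", mean) for Poisson-distributed cluster sizes (minimum 1).
    The seed is mandatory: generation is deterministic given the scenario.
    """

    seed: int
    family: str = "NBH"
    n_clusters: int = 645
    mothers_per_cluster: object = 22
    covariates: tuple = ()
    count_covariates: tuple = ()
    zero_covariates: tuple = ()
    beta: dict = field(default_factory=lambda: {"Intercept": 0.0})
    gamma: dict = field(default_factory=lambda: {"Intercept": 0.0})
    alpha: float = 0.55
    sigma2_u: float = 0.526
    sigma2_w: float = 0.691
    cluster_col: str = "cluster"
    outcome_col: str = "y"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in NB_FAMILIES and self.alpha <= 0:
            raise ValueError("NB families need alpha > 0")
        if self.sigma2_u < 0 or self.sigma2_w < 0:
            raise ValueError("variance components must be nonnegative")
        known = {c.name for c in self.covariates}
        for nm in tuple(self.count_covariates) + tuple(self.zero_covariates):
            if nm not in known:
                raise ValueError(f"covariate {nm!r} not defined in the scenario")

    @property
    def categories(self) -> dict:
        return {c.name: list(map(str, c.levels))
                for c in self.covariates if c.kind == "categorical"}


def _coef_vector(coef: dict, names: list) -> np.ndarray:
    unknown = set(coef) - set(names)
    if unknown:
        raise ValueError(f"coefficients for unknown design columns: "
                         f"{sorted(unknown)} (have {names})")
    return np.array([coef.get(n, 0.0) for n in names])


def _draw_cluster_sizes(scenario: Scenario, rng) -> np.ndarray:
    mpc = scenario.mothers_per_cluster
    if isinstance(mpc, (int, np.integer)):
        return np.full(scenario.n_clusters, int(mpc))
    kind, mean = mpc
    if kind != "poisson":
        raise ValueError(f"unknown cluster-size distribution {kind!r}")
    return np.maximum(rng.poisson(mean, size=scenario.n_clusters), 1)


def _truncated_draw(rng, family, mu, alpha):
    """Zero-truncated Poisson/NB draw by inverse transform: U ~ Unif(P0, 1),
    y = ppf(U)."""
    if family == "PH":
        dist = stats.poisson(mu)
    else:
        dist = stats.nbinom(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
    p0 = dist.cdf(0)
    u = p0 + (1.0 - p0) * rng.random(np.shape(mu))
    y = dist.ppf(np.clip(u, None, 1.0 - 1e-16))
    return np.maximum(y.astype(np.int64), 1)


def simulate(scenario: Scenario):
    """Draw one dataset; returns (mother-level DataFrame, truth manifest).

    Cluster intercepts u_j ~ N(0, sigma_u^2) and w_j ~ N(0, sigma_w^2) are
    drawn independently; mu_ij = exp(x'beta + u_j) and pi_ij =
    logit^{-1}(z'gamma + w_j); outcomes follow the family's two-part
    mechanism (hurdle: Bernoulli(pi) zero vs zero-truncated positive draw;
    zero-inflated: Bernoulli(pi) inflation vs untruncated base draw).
    """
    rng = np.random.default_rng(scenario.seed)
    sizes = _draw_cluster_sizes(scenario, rng)
    n = int(sizes.sum())
    cluster = np.repeat(np.arange(scenario.n_clusters), sizes)

    data = {scenario.cluster_col: cluster}
    for cov in scenario.covariates:
        if cov.kind == "categorical":
            draws = rng.choice(len(cov.levels), size=n, p=np.asarray(cov.probs))
            data[cov.name] = np.asarray([str(l) for l in cov.levels])[draws]
        else:
            data[cov.name] = rng.normal(cov.mean, cov.sd, size=n)
    df = pd.DataFrame(data)

    X, count_names, _ = build_design(df, scenario.count_covariates,
                                     scenario.categories)
    Z, zero_names, _ = build_design(df, scenario.zero_covariates,
                                    scenario.categories)
    beta = _coef_vector(scenario.beta, count_names)
    gamma = _coef_vector(scenario.gamma, zero_names)

    u = rng.normal(0.0, math.sqrt(scenario.sigma2_u), size=scenario.n_clusters)
    w = rng.normal(0.0, math.sqrt(scenario.sigma2_w), size=scenario.n_clusters)
    mu = np.exp(X @ beta + u[cluster])
    pi = expit(Z @ gamma + w[cluster])

    is_zero = rng.random(n) < pi
    y = np.zeros(n, dtype=np.int64)
    rest = ~is_zero
    if scenario.family in ("PH", "NBH"):
        if np.any(rest):
            y[rest] = _truncated_draw(rng, scenario.family, mu[rest],
                                      scenario.alpha)
    else:
        if np.any(rest):
            if scenario.family == "ZIP":
                y[rest] = rng.poisson(mu[rest])
            else:
                y[rest] = rng.negative_binomial(
                    1.0 / scenario.alpha,
                    1.0 / (1.0 + scenario.alpha * mu[rest]))
    df[scenario.outcome_col] = y

    truth = {
        "family": scenario.family,
        "seed": scenario.seed,
        "n_clusters": scenario.n_clusters,
        "n_mothers": n,
        "count_names": count_names,
        "zero_names": zero_names,
        "beta": beta.tolist(),
        "gamma": gamma.tolist(),
        "alpha": scenario.alpha if scenario.family in NB_FAMILIES else None,
        "sigma2_u": scenario.sigma2_u,
        "sigma2_w": scenario.sigma2_w,
        "count_covariates": list(scenario.count_covariates),
        "zero_covariates": list(scenario.zero_covariates),
    }
    return df, truth


# ---------------------------------------------------------------------------
# ready-made scenarios
# ---------------------------------------------------------------------------


def recovery_scenario(seed: int = 0, n_clusters: int = 300,
                      mothers_per_cluster: int = 25,
                      family: str = "NBH") -> Scenario:
    """Small parameter-recovery design: one balanced binary covariate in
    both parts, moderate overdispersion, mid-size cluster variances."""
    return Scenario(
        seed=seed,
        family=family,
        n_clusters=n_clusters,
        mothers_per_cluster=mothers_per_cluster,
        covariates=(Covariate("x", "categorical", ("0", "1"), (0.5, 0.5)),),
        count_covariates=("x",),
        zero_covariates=("x",),
        beta={"Intercept": 0.0, "x=1": 0.4},
        gamma={"Intercept": 0.5, "x=1": -0.7},
        alpha=0.6,
        sigma2_u=0.5,
        sigma2_w=0.7,
    )


# covariate marginals from the published category totals (out of 14,370
# mothers); continuous covariates are centered in the generator so that the
# intercepts pin the marginal zero share and mean directly
_EDHS_COVARIATES = (
    Covariate("vaccination", "categorical", ("No", "Yes"), (0.8268, 0.1732)),
    Covariate("birth_interval", "categorical",
              ("0-24 months", "25-36 months", ">36 months"),
              (0.4961, 0.2371, 0.2668)),
    Covariate("antenatal_visits", "categorical",
              ("No visits", "1-3", "4 and above"), (0.6721, 0.1456, 0.1823)),
    Covariate("child_twin", "categorical", ("Single", "Multiple"),
              (0.9612, 0.0388)),
    Covariate("contraceptive_use", "categorical", ("No", "Yes"),
              (0.7638, 0.2362)),
    Covariate("mother_age_c", "continuous", mean=0.0, sd=8.0),
    Covariate("family_size_c", "continuous", mean=0.0, sd=2.2),
)

# ratio-scale generating effects on the two parts, from the published
# adjusted estimates (count part: rate ratios; zero part: odds of a zero
# count)
_EDHS_BETA = {
    "vaccination=Yes": math.log(0.735),
    "birth_interval=25-36 months": math.log(0.836),
    "birth_interval=>36 months": math.log(0.728),
    "antenatal_visits=1-3": math.log(0.841),
    "antenatal_visits=4 and above": math.log(0.814),
    "child_twin=Multiple": math.log(1.355),
    "contraceptive_use=Yes": math.log(0.885),
    "mother_age_c": math.log(1.052),
    "family_size_c": math.log(0.968),
}
_EDHS_GAMMA = {
    "vaccination=Yes": math.log(1.825),
    "birth_interval=25-36 months": math.log(1.766),
    "birth_interval=>36 months": math.log(3.523),
    "antenatal_visits=1-3": math.log(2.013),
    "antenatal_visits=4 and above": math.log(2.390),
    "child_twin=Multiple": math.log(0.256),
    "contraceptive_use=Yes": math.log(1.354),
    "mother_age_c": math.log(0.822),
    "family_size_c": math.log(1.255),
}

# intercepts solved once (bisection on large simulations) so that the
# marginal zero share is ~0.537 and the marginal mean count ~0.9 at the
# default variances
_EDHS_BETA0 = -0.235
_EDHS_GAMMA0 = -0.57


def edhs_scenario(seed: int = 0, n_clusters: int = 645,
                  mothers_per_cluster: int = 22, family: str = "NBH") -> Scenario:
    """Default EDHS-like scenario: published covariate marginals and effect
    sizes, cluster variances 0.526 (count) and 0.691 (zero), scaled to
    ~645 clusters x ~22 mothers."""
    beta = dict(_EDHS_BETA)
    beta["Intercept"] = _EDHS_BETA0
    gamma = dict(_EDHS_GAMMA)
    gamma["Intercept"] = _EDHS_GAMMA0
    names = tuple(c.name for c in _EDHS_COVARIATES)
    return Scenario(
        seed=seed,
        family=family,
        n_clusters=n_clusters,
        mothers_per_cluster=mothers_per_cluster,
        covariates=_EDHS_COVARIATES,
        count_covariates=names,
        zero_covariates=names,
        beta=beta,
        gamma=gamma,
        alpha=0.55,
        sigma2_u=0.526,
        sigma2_w=0.691,
    )
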