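import numpy as np
import pytest

from mlcount.inference import ModelData
from mlcount.io import PipelineConfig, make_model_data
from mlcount.simulate import recovery_scenario, simulate

RECOVERY_CONFIG = PipelineConfig(
    count_covariates=["x"], zero_covariates=["x"], categories={"x": ["0", "1"]}
)


@pytest.fixture(scope="session")
def small_instance():
    """Tiny intercept-only dataset: 3 clusters x 4 mothers."""
    rng = np.random.default_rng(0)
    J, nper = 3, 4
    y = rng.integers(0, 4, size=J * nper)
    cl = np.repeat(np.arange(J), nper)
    ones = np.ones((J * nper, 1))
    return ModelData(y=y, X=ones, Z=ones, cluster=cl, n_clusters=J)


@pytest.fixture(scope="session")
def recovery_data():
    """One mid-size draw from the binary-covariate recovery design."""
    df, truth = simulate(recovery_scenario(seed=0, n_clusters=120,
                                           mothers_per_cluster=20))
    return make_model_data(df, RECOVERY_CONFIG), truth


def mc_marginal_loglik(data, params, family, n_draws, rng):
    """Monte-Carlo oracle for the marginal log-likelihood.

    Brute-force integration over the Gaussian random effects with n_draws
    simple draws per cluster; returns (estimate, standard error).  Kept
    independent of the quadrature implementation.
    """
    from scipy.special import logsumexp

    from mlcount.models import clipped_expit, family_logpmf

    total, var_total = 0.0, 0.0
    for j in range(data.n_clusters):
        idx = data.cluster == j
        yj = data.y[idx]
        etaj = data.X[idx] @ params.beta
        xij = data.Z[idx] @ params.gamma
        u = rng.normal(0.0, np.sqrt(params.sigma2_u), n_draws)
        w = rng.normal(0.0, np.sqrt(params.sigma2_w), n_draws)
        lp = np.zeros(n_draws)
        for yi, e, x in zip(yj, etaj, xij):
            mu = np.exp(e + u)
            pi = clipped_expit(x + w)
            lp += family_logpmf(family, yi, mu, pi, alpha=params.alpha)
        lj = logsumexp(lp) - np.log(n_draws)
        total += lj
        # delta-method SE of log mean on the exp scale
        wts = np.exp(lp - lp.max())
        var_total += np.var(wts) / (np.mean(wts) ** 2 * n_draws)
    return total, np.sqrt(var_total)
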