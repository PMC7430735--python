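"""Unit and property tests for the two-part pmfs and conditional likelihoods."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlcount.models import (
    ModelSpec,
    MotherRecord,
    NumericDegeneracyError,
    ParameterVector,
    RandomEffects,
    conditional_loglik,
    family_logpmf,
    hurdle_pmf,
    linear_predictors,
    zinb_logpmf,
    zinb_pmf,
    zip_pmf,
)

MU_GRID = [0.1, 1.0, 5.0]
ALPHA_GRID = [0.2, 1.0, 3.0]
PI_GRID = [0.0, 0.3, 0.9]


@pytest.mark.parametrize(
    "y, mu, pi, expected",
    [
        (0, 1.0, 0.0, 0.367879),  # plain Poisson P(0)
        (0, 2.0, 0.5, 0.567668),  # 0.5 + 0.5 e^-2
        (3, 2.0, 0.5, 0.090224),  # 0.5 e^-2 8/6
    ],
)
def test_zip_pmf_closed_form(y, mu, pi, expected):
    assert zip_pmf(y, mu, pi) == pytest.approx(expected, abs=1e-6)


@pytest.mark.parametrize(
    "y, mu, alpha, pi, expected",
    [
        (0, 2.0, 1.0, 0.0, 1 / 3),       # (1+2)^-1
        (2, 2.0, 1.0, 0.0, 4 / 27),      # geometric case (1/3)(2/3)^2
    ],
)
def test_zinb_pmf_closed_form(y, mu, alpha, pi, expected):
    assert zinb_pmf(y, mu, alpha, pi) == pytest.approx(expected, abs=1e-9)


def test_zinb_poisson_limit_at_tiny_alpha():
    assert zinb_pmf(0, 1.0, 1e-8, 0.0) == pytest.approx(np.exp(-1), abs=1e-6)


@pytest.mark.parametrize(
    "y, mu, pi, family, alpha, expected",
    [
        (0, 7.3, 0.3, "PH", None, 0.3),  # hurdle zero mass is pi exactly
        (1, 1.0, 0.3, "PH", None, 0.7 * np.exp(-1) / (1 - np.exp(-1))),
        (1, 2.0, 0.5, "NBH", 1.0, 0.5 * ((1 / 3) * (2 / 3)) / (1 - 1 / 3)),
    ],
)
def test_hurdle_pmf_closed_form(y, mu, pi, family, alpha, expected):
    assert hurdle_pmf(y, mu, pi, family=family, alpha=alpha) == pytest.approx(
        expected, abs=1e-6)


@pytest.mark.parametrize("family", ["ZIP", "ZINB", "PH", "NBH"])
@pytest.mark.parametrize("mu", MU_GRID)
@pytest.mark.parametrize("pi", PI_GRID)
def test_pmf_normalizes_over_support(family, mu, pi):
    """Each family's pmf sums to one over y = 0..Y* for large enough Y*."""
    ys = np.arange(0, 400)
    alphas = ALPHA_GRID if family in ("ZINB", "NBH") else [None]
    for alpha in alphas:
        p = np.exp(family_logpmf(family, ys, mu, pi, alpha=alpha))
        assert np.all(p >= 0) and np.all(p <= 1)
        assert p.sum() == pytest.approx(1.0, abs=1e-8)


@pytest.mark.parametrize("mu", MU_GRID)
def test_zero_inflation_collapse(mu):
    """pi = 0 reduces ZIP to Poisson and ZINB to NB exactly."""
    from scipy import stats

    ys = np.arange(0, 30)
    np.testing.assert_allclose(zip_pmf(ys, mu, 0.0), stats.poisson.pmf(ys, mu),
                               atol=1e-12)
    for alpha in ALPHA_GRID:
        nb = stats.nbinom.pmf(ys, 1 / alpha, 1 / (1 + alpha * mu))
        np.testing.assert_allclose(zinb_pmf(ys, mu, alpha, 0.0), nb, atol=1e-12)


@pytest.mark.parametrize("mu", MU_GRID)
@pytest.mark.parametrize("pi", PI_GRID)
def test_nb_to_poisson_limit(mu, pi):
    ys = np.arange(0, 25)
    diff = np.abs(zinb_pmf(ys, mu, 1e-8, pi) - zip_pmf(ys, mu, pi))
    assert diff.max() < 1e-5


@pytest.mark.parametrize("family,base", [("PH", "ZIP"), ("NBH", "ZINB")])
@pytest.mark.parametrize("mu", MU_GRID)
def test_hurdle_equals_base_when_pi_matches_p0(family, base, mu):
    """With the hurdle pi set to the base model's P(0), the hurdle pmf is the
    untruncated base pmf for every y."""
    alpha = 0.7 if family == "NBH" else None
    p0 = float(np.exp(family_logpmf(base, 0, mu, 0.0, alpha=alpha)))
    ys = np.arange(0, 40)
    h = hurdle_pmf(ys, mu, p0, family=family, alpha=alpha)
    b = np.exp(family_logpmf(base, ys, mu, 0.0, alpha=alpha))
    np.testing.assert_allclose(h, b, atol=1e-10)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    mu=st.floats(0.05, 20.0),
    pi=st.floats(0.0, 0.99),
    alpha=st.floats(0.05, 4.0),
    family=st.sampled_from(["ZIP", "ZINB", "PH", "NBH"]),
)
def test_pmf_values_are_probabilities(mu, pi, alpha, family):
    ys = np.arange(0, 200)
    p = np.exp(family_logpmf(family, ys, mu, pi, alpha=alpha))
    assert np.all((p >= 0) & (p <= 1 + 1e-12))
    assert p.sum() <= 1 + 1e-6


def test_pmf_domain_errors():
    with pytest.raises(ValueError):
        zip_pmf(0, -1.0, 0.2)
    with pytest.raises(ValueError):
        zip_pmf(0, 1.0, 1.2)
    with pytest.raises(ValueError):
        zip_pmf(-1, 1.0, 0.2)
    with pytest.raises(ValueError):
        zinb_pmf(1, 1.0, -0.5, 0.2)
    with pytest.raises(ValueError):
        hurdle_pmf(1, 1.0, 0.2, family="NBH")  # alpha missing


def test_truncation_normalizer_extreme_mu():
    # log-scale math keeps the zero-truncation normalizer finite down to
    # subnormal mu: log(1-e^{-mu}) ~ log(mu)
    assert np.isfinite(hurdle_pmf(1, 1e-320, 0.3, family="PH"))
    # a genuinely degenerate normalizer raises instead of silently
    # returning nan
    with pytest.raises(NumericDegeneracyError):
        hurdle_pmf(1, 1.0, 0.3, family="NBH", alpha=np.inf)


def test_linear_predictors_closed_forms():
    rec = MotherRecord("c1", 0, x=[1.0], z=[1.0])
    mu, pi = linear_predictors(rec, ParameterVector([0.0], [0.0]))
    assert mu == pytest.approx(1.0)
    assert pi == pytest.approx(0.5)
    rec2 = MotherRecord("c1", 0, x=[1.0, 1.0], z=[1.0])
    mu2, _ = linear_predictors(rec2, ParameterVector([0.1, 0.3], [0.0]),
                               RandomEffects(u=0.2))
    assert mu2 == pytest.approx(np.exp(0.6), abs=1e-9)


def test_linear_predictors_dimension_mismatch():
    rec = MotherRecord("c1", 0, x=[1.0, 2.0], z=[1.0])
    with pytest.raises(ValueError, match="design length"):
        linear_predictors(rec, ParameterVector([0.0], [0.0]))


class TestConditionalLoglik:
    spec_ph = ModelSpec("PH")
    spec_zinb = ModelSpec("ZINB")

    def test_single_zero_record_is_log_pi(self):
        rec = MotherRecord("a", 0, x=[1.0], z=[1.0])
        # gamma chosen so pi = 0.3
        gamma = [float(np.log(0.3 / 0.7))]
        ll = conditional_loglik([rec], ParameterVector([0.0], gamma),
                                RandomEffects(), self.spec_ph)
        assert ll == pytest.approx(np.log(0.3), abs=1e-9)

    def test_additive_over_iid_records(self):
        recs = [MotherRecord("a", 2, x=[1.0], z=[1.0]) for _ in range(2)]
        p = ParameterVector([0.3], [-0.2])
        one = conditional_loglik(recs[:1], p, RandomEffects(), self.spec_ph)
        two = conditional_loglik(recs, p, RandomEffects(), self.spec_ph)
        assert two == pytest.approx(2 * one, abs=1e-12)

    def test_matches_termwise_summation_oracle(self):
        rng = np.random.default_rng(42)
        p = ParameterVector([0.2, -0.4], [0.1, 0.3], alpha=0.8)
        re = RandomEffects(u=0.15, w=-0.25)
        recs, oracle = [], 0.0
        for _ in range(5):
            x = np.array([1.0, rng.normal()])
            z = np.array([1.0, rng.normal()])
            y = int(rng.integers(0, 5))
            recs.append(MotherRecord("c", y, x=x, z=z))
            mu = np.exp(x @ p.beta + re.u)
            pi = 1 / (1 + np.exp(-(z @ p.gamma + re.w)))
            oracle += float(zinb_logpmf(y, mu, p.alpha, pi))
        ll = conditional_loglik(recs, p, re, self.spec_zinb)
        assert ll == pytest.approx(oracle, abs=1e-9)

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        recs = [MotherRecord("c", int(rng.integers(0, 4)), x=[1.0], z=[1.0])
                for _ in range(6)]
        p = ParameterVector([0.1], [0.2])
        a = conditional_loglik(recs, p, RandomEffects(), self.spec_ph)
        b = conditional_loglik(recs[::-1], p, RandomEffects(), self.spec_ph)
        assert a == b

    def test_mixed_clusters_rejected(self):
        recs = [MotherRecord("a", 0, x=[1.0], z=[1.0]),
                MotherRecord("b", 0, x=[1.0], z=[1.0])]
        with pytest.raises(ValueError, match="multiple clusters"):
            conditional_loglik(recs, ParameterVector([0.0], [0.0]),
                               RandomEffects(), self.spec_ph)

    def test_zero_probability_warns_not_crashes(self):
        # mu overflows to inf, so the truncated-Poisson mass at y=1 is 0;
        # the cluster log-likelihood must come back as -inf with a warning
        rec = MotherRecord("a", 1, x=[1.0], z=[1.0])
        p = ParameterVector([800.0], [0.0])
        with pytest.warns(RuntimeWarning):
            ll = conditional_loglik([rec], p, RandomEffects(), self.spec_ph)
        assert ll == -np.inf


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec("ZIPP")
    with pytest.raises(NotImplementedError):
        ModelSpec("ZIP", random_slopes=("x",))
    assert ModelSpec("ZINB").has_alpha and not ModelSpec("PH").has_alpha
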