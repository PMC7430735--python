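"""Tests for marginal likelihood, fitting and reporting."""

import numpy as np
import pytest

from mlcount.inference import (
    EffectRow,
    MarginalLikelihood,
    ModelData,
    effect_table,
    fit,
    information_criteria,
    marginal_loglik,
    model_comparison,
    numeric_hessian,
    variance_component_table,
)
from mlcount.io import make_model_data
from mlcount.models import ModelSpec, ParameterVector, family_logpmf
from mlcount.quadrature import aghq_2d
from mlcount.simulate import recovery_scenario, simulate

from conftest import RECOVERY_CONFIG, mc_marginal_loglik


class TestMarginalLoglik:
    def test_zero_variance_collapses_to_conditional(self, small_instance):
        d = small_instance
        for family, alpha in (("PH", None), ("NBH", 0.8), ("ZIP", None),
                              ("ZINB", 0.8)):
            p = ParameterVector([0.2], [0.1], alpha=alpha)
            ll = marginal_loglik(d, p, ModelSpec(family), quad_points=15)
            mu = np.exp(0.2)
            pi = 1 / (1 + np.exp(-0.1))
            direct = family_logpmf(family, d.y, mu, pi, alpha=alpha).sum()
            assert ll == pytest.approx(direct, abs=1e-10)

    @pytest.mark.parametrize("family,alpha,s2u,s2w", [
        ("PH", None, 0.5, 1.0),
        ("NBH", 0.7, 0.4, 0.6),
        ("ZIP", None, 0.5, 0.7),
        ("ZINB", 0.9, 0.6, 0.5),
    ])
    def test_matches_monte_carlo_oracle(self, small_instance, family, alpha,
                                        s2u, s2w):
        p = ParameterVector([0.2], [0.1], alpha=alpha, sigma2_u=s2u,
                            sigma2_w=s2w)
        ll = marginal_loglik(small_instance, p, ModelSpec(family), 15)
        rng = np.random.default_rng(99)
        mc, se = mc_marginal_loglik(small_instance, p, family, 200_000, rng)
        assert abs(ll - mc) < 3 * se

    def test_quadrature_self_consistency(self, recovery_data):
        data, truth = recovery_data
        p = ParameterVector(truth["beta"], truth["gamma"],
                            alpha=truth["alpha"], sigma2_u=truth["sigma2_u"],
                            sigma2_w=truth["sigma2_w"])
        spec = ModelSpec("NBH")
        a = marginal_loglik(data, p, spec, 15)
        b = marginal_loglik(data, p, spec, 30)
        assert abs(a - b) < 1e-6

    def test_hurdle_factorization_equals_joint_2d_integral(self,
                                                           small_instance):
        """The hurdle marginal computed as two 1-D integrals equals the full
        2-D integral of the joint conditional likelihood."""
        d = small_instance
        p = ParameterVector([0.2], [-0.1], alpha=0.8, sigma2_u=0.4,
                            sigma2_w=0.6)
        spec = ModelSpec("NBH")
        ll_fact = marginal_loglik(d, p, spec, 21)

        eta0 = d.X @ p.beta
        xi0 = d.Z @ p.gamma

        def joint(u, w):
            u2 = u if u.ndim == 2 else u[:, None]
            w2 = w if w.ndim == 2 else w[:, None]
            mu = np.exp(eta0[:, None] + u2[d.cluster])
            xi = xi0[:, None] + w2[d.cluster]
            pi = 1 / (1 + np.exp(-xi))
            lp = family_logpmf("NBH", d.y[:, None], mu, pi, alpha=p.alpha)
            out = np.zeros((d.n_clusters,) + lp.shape[1:])
            np.add.at(out, d.cluster, lp)
            return out[:, 0] if u.ndim == 1 else out

        ll_joint = aghq_2d(joint, p.sigma2_u, p.sigma2_w, d.n_clusters,
                           21).sum()
        assert ll_fact == pytest.approx(ll_joint, abs=1e-6)

    def test_fast_kernels_match_reference_pmfs(self, small_instance):
        """The inlined likelihood kernels agree with the reference pmfs."""
        d = small_instance
        rng = np.random.default_rng(3)
        u = rng.normal(size=d.n_clusters)
        w = rng.normal(size=d.n_clusters)
        for family, alpha in (("PH", None), ("NBH", 0.8), ("ZIP", None),
                              ("ZINB", 0.8)):
            ml = MarginalLikelihood(d, ModelSpec(family), 5)
            beta = np.array([0.3])
            gamma = np.array([-0.2])
            mu = np.exp(d.X @ beta + u[d.cluster])
            pi = 1 / (1 + np.exp(-(d.Z @ gamma + w[d.cluster])))
            ref = family_logpmf(family, d.y, mu, pi, alpha=alpha)
            expected = np.bincount(d.cluster, weights=ref,
                                   minlength=d.n_clusters)
            if family in ("PH", "NBH"):
                got = (ml._zero_part_fn(gamma)(w)
                       + ml._trunc_count_fn(beta, alpha)(u))
            else:
                got = ml._zi_fn(beta, gamma, alpha)(u, w)
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            MarginalLikelihood(
                ModelData(y=np.array([], dtype=int), X=np.empty((0, 1)),
                          Z=np.empty((0, 1)), cluster=np.array([], dtype=int),
                          n_clusters=0),
                ModelSpec("PH"))


class TestFit:
    def test_nbh_parameter_recovery_within_3se(self, recovery_data):
        data, truth = recovery_data
        fr = fit(data, ModelSpec("NBH"), quad_points=9)
        assert fr.converged
        true_theta = dict(zip(["count:Intercept", "count:x=1"], truth["beta"]))
        true_theta.update(zip(["zero:Intercept", "zero:x=1"], truth["gamma"]))
        true_theta["log_alpha"] = np.log(truth["alpha"])
        true_theta["log_sigma_u"] = 0.5 * np.log(truth["sigma2_u"])
        true_theta["log_sigma_w"] = 0.5 * np.log(truth["sigma2_w"])
        for i, name in enumerate(fr.theta_names):
            z = (fr.theta_hat[i] - true_theta[name]) / fr.se(name)
            assert abs(z) < 3, f"{name}: z={z:.2f}"

    def test_boundary_recovery_when_no_cluster_variance(self):
        # data simulated WITHOUT cluster effects: variance estimates must
        # collapse toward zero
        from dataclasses import replace

        sc = replace(recovery_scenario(seed=5, n_clusters=80,
                                       mothers_per_cluster=15),
                     sigma2_u=0.0, sigma2_w=0.0)
        df, _ = simulate(sc)
        data = make_model_data(df, RECOVERY_CONFIG)
        fr = fit(data, ModelSpec("NBH"), quad_points=9)
        assert fr.params_hat.sigma2_u < 0.05
        assert fr.params_hat.sigma2_w < 0.05

    def test_zero_part_matches_logistic_glm_without_random_effect(self,
                                                                  recovery_data):
        import statsmodels.api as sm

        data, _ = recovery_data
        spec = ModelSpec("PH", random_intercepts=(False, False))
        fr = fit(data, spec, quad_points=1)
        glm = sm.Logit((data.y == 0).astype(float), data.Z).fit(disp=0)
        got = fr.params_hat.gamma
        np.testing.assert_allclose(got, glm.params, atol=1e-4)

    def test_likelihood_trace_monotone(self, recovery_data):
        data, _ = recovery_data
        fr = fit(data, ModelSpec("PH"), quad_points=9)
        # trace holds the two parts' traces back to back; each block must be
        # non-decreasing
        t = np.array(fr.trace)
        drops = np.diff(t) < -1e-6
        # allow the single drop at the seam between the two blocks
        assert drops.sum() <= 1

    def test_zinb_nests_zip(self, small_instance):
        """ZINB attains at least the ZIP likelihood (alpha -> 0 boundary)."""
        d = small_instance
        # larger instance for a stable comparison
        df, _ = simulate(recovery_scenario(seed=3, n_clusters=40,
                                           mothers_per_cluster=12))
        data = make_model_data(df, RECOVERY_CONFIG)
        f_zip = fit(data, ModelSpec("ZIP"), quad_points=7, compute_vcov=False)
        start = ParameterVector(f_zip.params_hat.beta, f_zip.params_hat.gamma,
                                alpha=0.05,
                                sigma2_u=max(f_zip.params_hat.sigma2_u, 1e-4),
                                sigma2_w=max(f_zip.params_hat.sigma2_w, 1e-4))
        f_zinb = fit(data, ModelSpec("ZINB"), quad_points=7, start=start,
                     compute_vcov=False)
        assert f_zinb.loglik >= f_zip.loglik - 1e-4

    def test_fit_requires_two_part_outcome(self):
        data = ModelData(y=np.array([1, 2, 1, 3]), X=np.ones((4, 1)),
                         Z=np.ones((4, 1)), cluster=np.array([0, 0, 1, 1]),
                         n_clusters=2)
        with pytest.raises(ValueError, match="zero"):
            fit(data, ModelSpec("PH"))


class TestReporting:
    @staticmethod
    def _toy_fit(theta, names, vcov, terms_count=(), terms_zero=(),
                 count_names=(), zero_names=(), spec=None):
        from mlcount.inference import FitResult

        spec = spec or ModelSpec("NBH")
        k = len(theta)
        beta = [t for n, t in zip(names, theta) if n.startswith("count:")]
        gamma = [t for n, t in zip(names, theta) if n.startswith("zero:")]
        p = ParameterVector(beta or [0.0], gamma or [0.0], alpha=0.5,
                            sigma2_u=float(np.exp(2 * theta[names.index("log_sigma_u")]))
                            if "log_sigma_u" in names else 0.0,
                            sigma2_w=float(np.exp(2 * theta[names.index("log_sigma_w")]))
                            if "log_sigma_w" in names else 0.0)
        return FitResult(
            spec=spec, params_hat=p, theta_hat=np.asarray(theta, float),
            theta_names=list(names), vcov=np.asarray(vcov, float),
            loglik=-10.0, n_obs=100, n_clusters=10, k=k, converged=True,
            grad_norm=0.0, boundary={}, trace=[], data_signature=(100, 10, 0, 0),
            count_names=list(count_names), zero_names=list(zero_names),
            count_terms=list(terms_count), zero_terms=list(terms_zero),
        )

    def test_wald_interval_centred_ratio(self):
        fr = self._toy_fit([0.0], ["count:Intercept"], [[0.01]],
                           count_names=("Intercept",),
                           spec=ModelSpec("NBH", random_intercepts=(False, False)))
        rows = effect_table(fr)
        r = rows[0]
        assert r.ratio == pytest.approx(1.0)
        assert (r.ci_low, r.ci_high) == (pytest.approx(0.822, abs=1e-3),
                                         pytest.approx(1.217, abs=1e-3))

    def test_wald_interval_published_shape(self):
        # estimate -0.308, SE 0.0648 -> ratio 0.735, CI ~ (0.647, 0.835)
        fr = self._toy_fit([-0.308], ["count:vaccination=Yes"], [[0.0648**2]],
                           count_names=("vaccination=Yes",),
                           spec=ModelSpec("NBH", random_intercepts=(False, False)))
        r = effect_table(fr)[0]
        assert r.ratio == pytest.approx(0.735, abs=1e-3)
        assert r.ci_low == pytest.approx(0.647, abs=1e-3)
        assert r.ci_high == pytest.approx(0.835, abs=1e-3)

    def test_reference_category_rows(self):
        from mlcount.inference import TermInfo

        fr = self._toy_fit(
            [0.1, -0.3], ["count:Intercept", "count:vaccination=Yes"],
            np.diag([0.01, 0.01]),
            terms_count=[TermInfo("vaccination", ["vaccination=Yes"], "No")],
            count_names=("Intercept", "vaccination=Yes"),
            spec=ModelSpec("NBH", random_intercepts=(False, False)))
        rows = [r for r in effect_table(fr) if r.part == "count"]
        ref = [r for r in rows if r.is_reference]
        assert len(ref) == 1
        assert ref[0].ratio == 1.0 and ref[0].ci_low is None

    def test_variance_component_backtransform(self):
        fr = self._toy_fit([0.0, 0.0], ["zero:Intercept", "log_sigma_w"],
                           np.diag([0.01, 0.05**2]),
                           spec=ModelSpec("PH", random_intercepts=(False, True)))
        rows = variance_component_table(fr)
        assert len(rows) == 1
        v = rows[0]
        assert v.part == "zero"
        assert v.estimate == pytest.approx(1.0)
        assert v.ci_low == pytest.approx(np.exp(-2 * 1.96 * 0.05), abs=2e-4)
        assert v.ci_high == pytest.approx(np.exp(2 * 1.96 * 0.05), abs=2e-4)

    def test_effect_table_requires_convergence(self):
        fr = self._toy_fit([0.0], ["count:Intercept"], [[0.01]])
        fr.converged = False
        with pytest.raises(ValueError):
            effect_table(fr)


class TestModelComparison:
    def test_information_criterion_identity(self):
        ic = information_criteria(deviance=29534, k=22, n_obs=14370)
        assert ic["aic"] == 29578
        assert abs(ic["bic"] - 29744) < 1

    def test_penalty_monotonicity(self):
        a = TestReporting._toy_fit([0.0], ["count:Intercept"], [[0.01]])
        b = TestReporting._toy_fit([0.0], ["count:Intercept"], [[0.01]])
        a.k, b.k = 5, 7
        a.loglik = b.loglik = -100.0
        ranked = model_comparison([a, b])
        assert ranked.loc[0, "k"] == 5

    def test_rejects_different_datasets(self):
        a = TestReporting._toy_fit([0.0], ["count:Intercept"], [[0.01]])
        b = TestReporting._toy_fit([0.0], ["count:Intercept"], [[0.01]])
        b.data_signature = (99, 9, 1, 1)
        with pytest.raises(ValueError, match="different datasets"):
            model_comparison([a, b])


def test_numeric_hessian_on_quadratic():
    A = np.array([[2.0, 0.5], [0.5, 1.0]])

    def f(x):
        return -0.5 * x @ A @ x

    H = numeric_hessian(f, np.array([0.3, -0.2]))
    np.testing.assert_allclose(H, -A, atol=1e-5)
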