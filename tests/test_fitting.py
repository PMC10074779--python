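"""Posterior sampling behaviour: reproducibility, prior calibration,
missing-response handling, and the equivalence of the independent-binomial
decomposition with the exact joint multinomial likelihood."""

import numpy as np
import pytest

import multibym as mb
from multibym.model_core import ModelSpec, _SubmodelPosterior, hmc_sample


class TestFitModel:
    def test_reproducible_draws(self, small_scenario):
        spec, table, graph, _ = small_scenario
        kw = dict(chains=2, draws=60, warmup=60, seed=123)
        s1 = mb.fit_model(table, graph, spec.model_spec(), **kw)
        s2 = mb.fit_model(table, graph, spec.model_spec(), **kw)
        for cat in s1.categories:
            for name in ("alpha", "beta", "sigma", "phi", "b"):
                np.testing.assert_array_equal(s1.params[cat][name], s2.params[cat][name])

    def test_posterior_shapes_and_ranges(self, small_fit):
        for cat in small_fit.categories:
            pr = small_fit.params[cat]
            assert pr["alpha"].shape == (2, 300)
            assert pr["beta"].shape == (2, 300, 4)
            assert pr["b"].shape == (2, 300, 36)
            assert np.all(pr["phi"] >= 0) and np.all(pr["phi"] <= 1)
            assert np.all(pr["tau"] > 0)
            np.testing.assert_allclose(pr["tau"], pr["sigma"] ** -2.0)

    def test_missing_districts_get_random_effects(self, small_scenario, small_fit):
        _, table, _, _ = small_scenario
        missing = np.flatnonzero(~table.observed_mask)
        b = small_fit.stacked("obesity", "b")[:, missing]
        assert np.isfinite(b).all()
        assert b.std() > 0  # sampled, not pinned

    def test_prevalence_covers_missing_districts(self, small_fit):
        field = mb.posterior_prevalence(small_fit)
        assert field.mean.shape == (36, 3)
        np.testing.assert_allclose(field.mean.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(field.lower <= field.mean + 1e-12)
        assert np.all(field.mean <= field.upper + 1e-12)

    def test_pointwise_loglik_shape(self, small_scenario, small_fit):
        _, table, _, _ = small_scenario
        n_obs = int(table.observed_mask.sum())
        ll = small_fit.pointwise_loglik()
        assert ll.shape == (600, 2 * n_obs)
        assert np.isfinite(ll).all()

    def test_too_few_districts_rejected(self, small_scenario):
        spec, table, graph, _ = small_scenario
        import pandas as pd

        counts = table.counts.copy()
        counts.iloc[8:] = np.nan  # leave 8 observed
        crippled = mb.DistrictTable(table.district_id, counts, table.covariates)
        with pytest.raises(ValueError, match="at least 10"):
            mb.fit_model(crippled, graph, spec.model_spec(), chains=1, draws=10, seed=0)

    def test_unscaled_graph_rejected(self, small_scenario):
        spec, table, _, _ = small_scenario
        raw = mb.adjacency_from_pairs([(i, i + 1) for i in range(1, 36)], 36)
        with pytest.raises(ValueError, match="scaled"):
            mb.fit_model(table, raw, spec.model_spec(), chains=1, draws=10, seed=0)


class TestPriorOnlySampling:
    def test_prior_calibrations_reproduced(self, small_scenario):
        spec, table, graph, _ = small_scenario
        s = mb.fit_model(table, graph, spec.model_spec(), chains=2, draws=1200,
                         warmup=400, seed=5, prior_only=True, max_leapfrog=24)
        beta = np.concatenate([s.stacked(c, "beta").ravel() for c in s.categories])
        # fixed effects: N(0, precision 0.001) -> sd = sqrt(1000) = 31.62
        assert beta.std() == pytest.approx(np.sqrt(1000.0), rel=0.08)
        sigma = np.concatenate([s.stacked(c, "sigma") for c in s.categories])
        # PC prior tail: P(sigma > 0.5/0.31) = 0.01
        assert (sigma > 0.5 / 0.31).mean() == pytest.approx(0.01, abs=0.006)

    def test_tau_concentrates_when_effects_are_tiny(self):
        # simulate with near-zero random-effect variance: tau posterior mass
        # should sit above the prior median of tau
        spec = mb.ScenarioSpec(m=60, seed=21, n_missing=0,
                               true_tau={"overweight": 1e6, "obesity": 1e6})
        table, graph, _ = mb.simulate_scenario(spec)
        s = mb.fit_model(table, graph, spec.model_spec(), chains=1, draws=300,
                         warmup=300, seed=2)
        lam = spec.model_spec().priors.lambda_tau
        prior_median_tau = (np.log(2.0) / lam) ** -2.0
        for cat in s.categories:
            tau = s.stacked(cat, "tau")
            assert np.median(tau) > prior_median_tau


class _JointMultinomialPosterior:
    """Exact joint multinomial likelihood oracle (small instances).

    Both categories' submodel parameter blocks (in the package's non-centred
    parameterisation) are stacked and tied together through the multinomial
    likelihood: grad wrt eta_k is y_k - M p_k with p from the softmax, unlike
    the conditional-binomial factorisation where trials are y_k + y_3.
    """

    def __init__(self, table, graph, spec):
        X = spec.design_matrix(table.covariates)
        obs = table.observed_mask
        self.obs = obs
        self.y = {c: np.where(obs, table.counts[c].to_numpy(float), 0.0)
                  for c in ("overweight", "obesity")}
        self.M = np.where(obs, np.nan_to_num(table.M), 0.0)
        self.parts = {}
        for c in ("overweight", "obesity"):
            n_c = self.y[c] + table.counts["neither"].to_numpy(float)
            self.parts[c] = _SubmodelPosterior(
                self.y[c], np.where(obs, n_c, 0.0), X, graph, spec.priors,
                prior_only=True, standardize=True)
        self.dim = sum(p.dim for p in self.parts.values())

    def eta(self, part, x):
        alpha_s, beta_s, ls, zeta, latent = part.unpack(x)
        b = part.random_effect(ls, zeta, latent)[0]
        return np.concatenate([[alpha_s], beta_s]) @ part.D.T + b

    def __call__(self, x):
        d1 = self.parts["overweight"].dim
        xs = {"overweight": x[:d1], "obesity": x[d1:]}
        lp = 0.0
        grad = np.zeros_like(x)
        etas, priors_g = {}, {}
        for c, part in self.parts.items():
            lp_c, g_c = part(xs[c])  # prior terms only (prior_only instances)
            if not np.isfinite(lp_c):
                return -np.inf, grad
            lp += lp_c
            priors_g[c] = g_c
            etas[c] = self.eta(part, xs[c])
        e1, e2 = etas["overweight"][self.obs], etas["obesity"][self.obs]
        shift = np.maximum.reduce([e1, e2, np.zeros_like(e1)])
        lse = shift + np.log(np.exp(e1 - shift) + np.exp(e2 - shift) + np.exp(-shift))
        y1, y2 = self.y["overweight"][self.obs], self.y["obesity"][self.obs]
        lp += np.sum(y1 * e1 + y2 * e2 - self.M[self.obs] * lse)
        p1 = np.exp(e1 - lse)
        p2 = np.exp(e2 - lse)
        g_eta = {"overweight": y1 - self.M[self.obs] * p1,
                 "obesity": y2 - self.M[self.obs] * p2}
        off = 0
        for c, part in self.parts.items():
            g = np.zeros(self.parts[c].dim)
            ge = np.zeros(part.m)
            ge[self.obs] = g_eta[c]
            alpha_s, beta_s, ls, zeta, latent = part.unpack(xs[c])
            b, sigma, phi, dphi = part.random_effect(ls, zeta, latent)
            v, z = latent[: part.m], latent[part.m :]
            u = part.W @ z
            g[: 1 + part.p] = part.D.T @ ge
            g[1 + part.p] = np.dot(ge, b)
            db_dphi = sigma * 0.5 * (-v / np.sqrt(1 - phi) + u / np.sqrt(phi))
            g[2 + part.p] = np.dot(ge, db_dphi) * dphi
            g[3 + part.p : 3 + part.p + part.m] = sigma * np.sqrt(1 - phi) * ge
            g[3 + part.p + part.m :] = sigma * np.sqrt(phi) * (part.W.T @ ge)
            grad[off : off + part.dim] = priors_g[c] + g
            off += part.dim
        return lp, grad


class TestJointMultinomialEquivalence:
    def test_oracle_gradient_is_consistent(self):
        spec = mb.ScenarioSpec(m=16, seed=8, n_missing=1)
        table, graph, _ = mb.simulate_scenario(spec)
        joint = _JointMultinomialPosterior(table, graph, spec.model_spec())
        rng = np.random.default_rng(0)
        x = 0.05 * rng.standard_normal(joint.dim)
        lp, g = joint(x)
        for k in rng.choice(joint.dim, 12, replace=False):
            h = 1e-6
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            num = (joint(xp)[0] - joint(xm)[0]) / (2 * h)
            assert num == pytest.approx(g[k], rel=2e-3, abs=2e-3)

    def test_binomial_decomposition_matches_joint_multinomial(self):
        # fixed effects agree within 0.5 posterior sd between the package's
        # conditional-binomial route and the exact multinomial oracle
        spec = mb.ScenarioSpec(m=36, seed=31, n_missing=0)
        table, graph, _ = mb.simulate_scenario(spec)
        mspec = spec.model_spec()
        fit = mb.fit_model(table, graph, mspec, chains=2, draws=500, warmup=500, seed=3)

        joint = _JointMultinomialPosterior(table, graph, mspec)
        rng = np.random.default_rng(12)
        x0 = np.concatenate([p.initial_point(rng) for p in joint.parts.values()])
        draws, _ = hmc_sample(joint, x0, 800, 800, rng, max_leapfrog=48)
        d1 = joint.parts["overweight"].dim
        for c, sl in (("overweight", slice(0, d1)), ("obesity", slice(d1, None))):
            part = joint.parts[c]
            th_s = draws[:, sl][:, : 1 + part.p]
            th_nat = th_s @ part.A.T
            beta_joint = th_nat[:, 1:]
            beta_binom = fit.stacked(c, "beta")
            sd = beta_binom.std(axis=0)
            diff = np.abs(beta_binom.mean(axis=0) - beta_joint.mean(axis=0))
            assert np.all(diff < 0.5 * sd), (c, diff / sd)
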