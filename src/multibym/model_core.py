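"""Multinomial baseline-logit model with BYM2 district effects.

Each district *i* reports counts ``(y_i1, y_i2, y_i3)`` of overweight,
obese, and unaffected children out of ``M_i`` measured, modelled as
``Y_i ~ Multinomial(M_i, p_i)``. With the unaffected category as baseline,
the model is equivalent to two binomial logistic submodels, one per
non-baseline category k:

    logit q_ik = alpha_k + x_i' beta_k + b_ik,   q_ik = y_ik / (y_ik + y_i3)

where ``b_k`` is a BYM2 random effect over the district graph,

    b_k = (1/sqrt(tau_k)) ( sqrt(1-phi_k) v + sqrt(phi_k) u* ),

``v ~ N(0, I)`` unstructured and ``u* ~ N(0, (kappa Q)^-)`` the scaled ICAR
component. The per-district category probabilities follow from the softmax
of the two linear predictors against the baseline (eta_3 = 0).

Posterior inference is by Hamiltonian Monte Carlo with analytic gradients:
non-centred parameterisation of ``(v, z)`` (``u* = W z`` in the constrained
eigenbasis), ``sigma = 1/sqrt(tau)`` sampled on the log scale, ``phi`` on
the logit scale, dual-averaging step-size adaptation and diagonal mass
adaptation during warmup. Covariates are standardised internally for
sampler geometry and coefficients mapped back to their natural per-unit
scale before anything is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .priors import PCPriorSpec, pc_prior_phi
from .spatial_graph import DistrictGraph

__all__ = [
    "CATEGORIES",
    "DistrictTable",
    "ModelSpec",
    "PosteriorSamples",
    "PrevalenceField",
    "linear_predictor",
    "softmax_probs",
    "fit_model",
    "summarize_fixed_effects",
    "summarize_hyperparameters",
    "odds_change",
    "turning_point",
    "posterior_prevalence",
    "exceedance_probability",
    "hmc_sample",
]

CATEGORIES = ("overweight", "obesity", "neither")
#: national prevalence baselines used as default exceedance thresholds
DEFAULT_THRESHOLDS = {"overweight": 0.20, "obesity": 0.14}


# ---------------------------------------------------------------------------
# data containers


@dataclass
class DistrictTable:
    """Per-district category counts and covariates.

    ``counts`` has columns ``overweight``, ``obesity``, ``neither`` (NaN for
    the districts whose response is missing); ``covariates`` must be complete
    for every district that enters the likelihood or prediction.
    """

    district_id: list
    counts: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self):
        self.counts = self.counts.reset_index(drop=True)
        self.covariates = self.covariates.reset_index(drop=True)
        m = len(self.district_id)
        if len(self.counts) != m or len(self.covariates) != m:
            raise ValueError("counts/covariates length mismatch with district_id")
        obs = self.observed_mask
        c = self.counts.loc[obs, list(CATEGORIES)]
        if (c.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def observed_mask(self) -> np.ndarray:
        return ~self.counts[list(CATEGORIES)].isna().any(axis=1).to_numpy()

    @property
    def M(self) -> np.ndarray:
        """Total measured children per district (NaN where missing)."""
        return self.counts[list(CATEGORIES)].sum(axis=1, min_count=3).to_numpy()

    @property
    def n_districts(self) -> int:
        return len(self.district_id)


@dataclass(frozen=True)
class ModelSpec:
    """Model structure: covariates, quadratic expansions, priors."""

    covariate_names: tuple = ("Deprivation", "Population<14", "Schooling")
    quadratic_terms: tuple = ("Schooling",)
    baseline_category: str = "neither"
    priors: PCPriorSpec = field(default_factory=PCPriorSpec)

    def __post_init__(self):
        if not set(self.quadratic_terms) <= set(self.covariate_names):
            raise ValueError("quadratic_terms must be a subset of covariate_names")
        if self.baseline_category != "neither":
            raise ValueError("baseline category is fixed to 'neither'")

    @property
    def expanded_names(self) -> list:
        out = list(self.covariate_names)
        out += [f"{c}^2" for c in self.quadratic_terms]
        return out

    def design_matrix(self, covariates: pd.DataFrame) -> np.ndarray:
        """Expand covariates into the design matrix (quadratic columns
        appended after the linear block)."""
        missing = [c for c in self.covariate_names if c not in covariates.columns]
        if missing:
            raise ValueError(f"missing covariate columns: {missing}")
        X = covariates[list(self.covariate_names)].to_numpy(dtype=float)
        if self.quadratic_terms:
            Xq = covariates[list(self.quadratic_terms)].to_numpy(dtype=float) ** 2
            X = np.hstack([X, Xq])
        if np.isnan(X).any():
            raise ValueError("covariates must be complete for modeled districts")
        return X


# ---------------------------------------------------------------------------
# elementary model functions


def linear_predictor(alpha, beta, x, b, quadratic_idx=()):
    """eta = alpha + x' beta + b, expanding quadratic terms of ``x`` first.

    ``quadratic_idx`` lists the positions in ``x`` whose squares are appended
    (in order) before the dot product; ``beta`` must match the expanded
    length.
    """
    x = np.asarray(x, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if quadratic_idx:
        x = np.concatenate([x, x[list(quadratic_idx)] ** 2])
    if x.shape[-1] != beta.shape[-1]:
        raise ValueError(
            f"dimension mismatch: expanded x has {x.shape[-1]} entries, beta has {beta.shape[-1]}"
        )
    return alpha + x @ beta + b


def softmax_probs(eta1, eta2):
    """Category probabilities from the two non-baseline linear predictors.

    Baseline has eta_3 = 0; computed with a max-shift so arbitrarily large
    or small predictors neither overflow nor collapse to NaN.
    """
    eta1 = np.asarray(eta1, dtype=float)
    eta2 = np.asarray(eta2, dtype=float)
    if np.isnan(eta1).any() or np.isnan(eta2).any():
        raise ValueError("NaN linear predictor")
    eta = np.stack([eta1, eta2, np.zeros(np.broadcast(eta1, eta2).shape)], axis=-1)
    eta = eta - eta.max(axis=-1, keepdims=True)
    w = np.exp(eta)
    p = w / w.sum(axis=-1, keepdims=True)
    return p[..., 0], p[..., 1], p[..., 2]


def odds_change(or_per_unit: float, delta: float) -> float:
    """Percent change in the odds for a ``delta``-unit covariate shift:
    ``(OR^delta - 1) * 100``."""
    if or_per_unit <= 0:
        raise ValueError("odds ratio must be positive")
    return (or_per_unit**delta - 1.0) * 100.0


def turning_point(or_linear: float, or_quadratic: float) -> float:
    """Covariate value at the extremum of a quadratic log-odds relationship.

    Given per-unit odds ratios for the linear and quadratic terms, returns
    ``-beta1 / (2 beta2)`` with ``beta = ln(OR)``.
    """
    if or_linear <= 0 or or_quadratic <= 0:
        raise ValueError("odds ratios must be positive")
    b2 = np.log(or_quadratic)
    if b2 == 0.0:
        raise ValueError("quadratic odds ratio of 1 gives no curvature")
    return float(-np.log(or_linear) / (2.0 * b2))


# ---------------------------------------------------------------------------
# generic HMC with dual averaging and diagonal mass adaptation


def _slice_update_1d(logp_and_grad, x, coord, lp, rng, width=1.0, max_steps=8):
    """One stepping-out/shrinkage slice-sampling update of ``x[coord]``.

    Returns ``(x, lp, grad)`` at the new point (Neal 2003). Used to
    decorrelate weakly identified scalar coordinates (the BYM2 mixing
    parameter in particular) from the latent field between HMC steps.
    """
    y = lp + np.log(rng.random())
    x0c = x[coord]
    lo = x0c - width * rng.random()
    hi = lo + width
    trial = x.copy()
    for _ in range(max_steps):
        trial[coord] = lo
        if logp_and_grad(trial)[0] <= y:
            break
        lo -= width
    for _ in range(max_steps):
        trial[coord] = hi
        if logp_and_grad(trial)[0] <= y:
            break
        hi += width
    while True:
        prop = lo + (hi - lo) * rng.random()
        trial[coord] = prop
        lp_new, grad_new = logp_and_grad(trial)
        if lp_new > y:
            return trial, lp_new, grad_new
        if prop < x0c:
            lo = prop
        else:
            hi = prop
        if hi - lo < 1e-12:
            return x, *logp_and_grad(x)


def hmc_sample(
    logp_and_grad,
    x0,
    n_warmup,
    n_draws,
    rng,
    max_leapfrog: int = 32,
    target_accept: float = 0.8,
    init_step: float = 0.1,
    slice_coords=(),
):
    """Adaptive Hamiltonian Monte Carlo for a differentiable log-density.

    ``logp_and_grad(x) -> (float, ndarray)``. Step size is tuned by
    Nesterov dual averaging toward ``target_accept``; a diagonal mass matrix
    is estimated from expanding warmup windows. The number of leapfrog steps
    is jittered uniformly in ``[max_leapfrog/2, max_leapfrog]`` to avoid
    resonances. Coordinates in ``slice_coords`` additionally get a 1-D slice
    sampling update after every HMC step.

    Returns ``(draws, info)`` with ``draws`` of shape ``(n_draws, dim)``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    lp, grad = logp_and_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log-density")

    inv_mass = np.ones(dim)
    # dual averaging state (Hoffman & Gelman 2014 defaults)
    mu = np.log(10.0 * init_step)
    log_eps = np.log(init_step)
    log_eps_bar, h_bar, t_da = 0.0, 0.0, 0
    gamma_da, t0, kappa_da = 0.05, 10.0, 0.75

    w1 = max(1, int(0.15 * n_warmup))  # step-size only
    # two expanding mass-estimation windows, each followed by a DA restart
    w2 = max(w1 + 2, int(0.5 * n_warmup))
    w3 = max(w2 + 2, int(0.9 * n_warmup))
    window = []

    draws = np.empty((n_draws, dim))
    n_divergent = 0
    accept_sum = 0.0

    total = n_warmup + n_draws
    for it in range(total):
        eps = np.exp(log_eps if it < n_warmup else log_eps_bar)
        L = int(rng.integers(max(1, max_leapfrog // 2), max_leapfrog + 1))
        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        x_new, grad_new = x.copy(), grad.copy()
        h0 = -lp + 0.5 * np.dot(p * inv_mass, p)
        p_half = p + 0.5 * eps * grad_new
        diverged = False
        for _ in range(L):
            x_new = x_new + eps * inv_mass * p_half
            lp_new, grad_new = logp_and_grad(x_new)
            if not np.isfinite(lp_new):
                diverged = True
                break
            p_half = p_half + eps * grad_new
        if not diverged:
            p_new = p_half - 0.5 * eps * grad_new  # undo the extra half kick
            with np.errstate(over="ignore", invalid="ignore"):
                h1 = -lp_new + 0.5 * np.dot(p_new * inv_mass, p_new)
            if not np.isfinite(h1):
                h1 = np.inf
            dh = h0 - h1
            accept_prob = min(1.0, np.exp(min(dh, 0.0)))
            if dh < -1000.0:
                diverged = True
        if diverged:
            accept_prob = 0.0
            if it >= n_warmup:
                n_divergent += 1
        if not diverged and rng.random() < accept_prob:
            x, lp, grad = x_new, lp_new, grad_new

        for coord in slice_coords:
            x, lp, grad = _slice_update_1d(logp_and_grad, x, coord, lp, rng)

        if it < n_warmup:
            # dual averaging update (own counter, restarted at the mass update)
            t_da += 1
            h_bar = (1 - 1 / (t_da + t0)) * h_bar + (target_accept - accept_prob) / (t_da + t0)
            log_eps = mu - np.sqrt(t_da) / gamma_da * h_bar
            eta_da = t_da**-kappa_da
            log_eps_bar = eta_da * log_eps + (1 - eta_da) * log_eps_bar
            if it >= w1:
                window.append(x.copy())
            if it + 1 in (w2, w3) and len(window) >= 10:
                var = np.var(np.asarray(window), axis=0)
                inv_mass = np.clip(var, 1e-6, 1e6)
                window = []
                # restart step-size adaptation around the current value
                mu = np.log(10.0) + log_eps
                h_bar, t_da, log_eps_bar = 0.0, 0, log_eps
        else:
            accept_sum += accept_prob
            draws[it - n_warmup] = x

    info = {
        "accept_rate": accept_sum / max(n_draws, 1),
        "step_size": float(np.exp(log_eps_bar)),
        "divergences": n_divergent,
        "inv_mass": inv_mass,
    }
    return draws, info


# ---------------------------------------------------------------------------
# one binomial BYM2 submodel: log posterior and gradient


class _SubmodelPosterior:
    """Log posterior (and gradient) of one binomial-logit BYM2 submodel in
    an unconstrained parameterisation.

    With data (the default, *centred* parameterisation) the random effect is
    sampled in the orthonormal eigenbasis of the scaled structured
    covariance: ``x = [alpha_s, beta_s (p), log sigma, zeta, w (m)]`` with
    ``b = E w`` and ``w_i ~ N(0, sigma^2 (1 - phi + phi gamma_i))``. The
    district counts here are large, so ``b`` is strongly data-identified and
    the hyperparameters mix well conditionally on it. In prior-only runs the
    *non-centred* form ``x = [..., v (m), z (r)]`` with
    ``b = sigma (sqrt(1-phi) v + sqrt(phi) W z)`` is used instead: without a
    likelihood it is an independent product of standard normals.

    ``phi`` is always sampled through the inverse CDF of its prior applied
    to a standard normal score ``zeta`` (the PC prior piles mass near
    ``phi = 1``, which is hostile geometry on the logit scale).

    Fixed effects are sampled on the standardised-covariate scale and the
    N(0, beta_precision^-1) prior is applied to the *natural-scale*
    coefficients through the affine back-transform.
    """

    def __init__(self, y, n, X, graph: DistrictGraph, priors: PCPriorSpec,
                 prior_only=False, standardize=True):
        self.y = np.asarray(y, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.m = X.shape[0]
        self.p = X.shape[1]
        self.obs = self.n > 0
        self.prior_only = prior_only

        # sampler basis for the fixed effects: thin QR of [1, X] decorrelates
        # the columns (raw quadratic expansions are nearly collinear), with
        # the affine map A returning coefficients to the natural scale
        D_nat = np.column_stack([np.ones(self.m), X])
        if standardize:
            Q, R = np.linalg.qr(D_nat)
            self.D = Q * np.sqrt(self.m)  # unit-scale columns; D[:,0] constant
            self.A = np.linalg.inv(R / np.sqrt(self.m))
        else:
            self.D = D_nat
            self.A = np.eye(self.p + 1)
        self.AtA = self.A.T @ self.A
        self.kappa_beta = priors.beta_precision

        self.lam_tau = priors.lambda_tau
        self.centered = not prior_only
        self.W, _ = graph.structured_basis()  # non-centred basis (m x r)
        self.r = self.W.shape[1]
        E, gamma = graph.centered_basis()
        # centred coordinates only where the structured covariance is
        # informative (gamma > 0); the null/island directions have prior
        # scale sigma*sqrt(1-phi), a funnel at phi -> 1, and stay non-centred
        pos = gamma > 0
        self.E_pos, self.gamma_pos = E[:, pos], gamma[pos]
        self.E_null = E[:, ~pos]
        self.k1, self.k0 = self.E_pos.shape[1], self.E_null.shape[1]
        # phi is sampled through its inverse-CDF map from a standard normal
        # (light-tailed geometry; the PC prior's mass piles up near phi=1)
        if priors.phi_prior == "pc":
            self.phi_prior = pc_prior_phi(graph, priors.phi_U, priors.phi_alpha)
            self.phi_transform = self.phi_prior.normal_transform()
        else:
            from scipy.stats import norm

            self.phi_prior = None  # uniform fallback
            self.phi_transform = lambda zeta: (
                np.clip(norm.cdf(zeta), 1e-12, 1 - 1e-12), norm.pdf(zeta))
        n_latent = self.m if self.centered else self.m + self.r
        self.dim = 1 + self.p + 2 + n_latent
        # binomial coefficient constants (for pointwise log-likelihood)
        self.log_binom = gammaln(self.n + 1) - gammaln(self.y + 1) - gammaln(self.n - self.y + 1)

    # slices
    def unpack(self, x):
        p = self.p
        return x[0], x[1 : 1 + p], x[1 + p], x[2 + p], x[3 + p :]

    def natural_coefs(self, alpha_s, beta_s):
        th = self.A @ np.concatenate([[alpha_s], np.atleast_1d(beta_s)])
        return th[0], th[1:]

    def random_effect(self, log_sigma, zeta, latent):
        sigma = np.exp(log_sigma)
        phi, dphi = self.phi_transform(zeta)
        if self.centered:
            w, vt = latent[: self.k1], latent[self.k1 :]
            b = self.E_pos @ w + sigma * np.sqrt(1 - phi) * (self.E_null @ vt)
        else:
            v, z = latent[: self.m], latent[self.m :]
            b = sigma * (np.sqrt(1 - phi) * v + np.sqrt(phi) * (self.W @ z))
        return b, sigma, phi, dphi

    def __call__(self, x):
        alpha_s, beta_s, ls, zeta, latent = self.unpack(x)
        if not np.isfinite(x).all() or not (-300.0 < ls < 13.0):  # sigma < ~4e5
            return -np.inf, np.zeros_like(x)
        b, sigma, phi, dphi = self.random_effect(ls, zeta, latent)
        th_s = np.concatenate([[alpha_s], beta_s])
        eta = self.D @ th_s + b

        grad = np.zeros_like(x)
        lp = 0.0

        g_eta = np.zeros(self.m)
        if not self.prior_only:
            # binomial likelihood over observed districts
            e = eta[self.obs]
            yo, no = self.y[self.obs], self.n[self.obs]
            lp += np.sum(yo * e - no * np.logaddexp(0.0, e))
            g_eta[self.obs] = yo - no * expit(e)

        # fixed-effect prior on natural-scale coefficients
        th_nat = self.A @ th_s
        lp += -0.5 * self.kappa_beta * np.dot(th_nat, th_nat)
        g_th = -self.kappa_beta * (self.AtA @ th_s)
        grad[: 1 + self.p] = self.D.T @ g_eta + g_th

        # sigma ~ Exp(lam_tau) on the sd scale, sampled as log sigma
        lp += np.log(self.lam_tau) - self.lam_tau * sigma + ls
        g_ls = 1.0 - self.lam_tau * sigma
        # zeta carries the phi prior exactly as N(0,1)
        lp += -0.5 * zeta * zeta
        g_zeta = -zeta

        if self.centered:
            w, vt = latent[: self.k1], latent[self.k1 :]
            lam_v = 1.0 - phi + phi * self.gamma_pos  # prior variances / sigma^2
            s2 = sigma * sigma
            q = w * w / (s2 * lam_v)
            lp += -0.5 * np.sum(q) - 0.5 * np.sum(np.log(lam_v)) - self.k1 * ls
            lp += -0.5 * np.dot(vt, vt)
            grad[3 + self.p : 3 + self.p + self.k1] = self.E_pos.T @ g_eta - w / (s2 * lam_v)
            g_null = self.E_null.T @ g_eta
            sn = sigma * np.sqrt(1 - phi)
            grad[3 + self.p + self.k1 :] = sn * g_null - vt
            b_null = sn * (self.E_null @ vt)
            g_ls += np.sum(q) - self.k1 + np.dot(g_eta, b_null)
            g_zeta += 0.5 * np.sum((self.gamma_pos - 1.0) * (q - 1.0) / lam_v) * dphi
            g_zeta += -0.5 / (1.0 - phi) * np.dot(g_eta, b_null) * dphi
        else:
            v, z = latent[: self.m], latent[self.m :]
            u = self.W @ z
            lp += -0.5 * (np.dot(v, v) + np.dot(z, z))
            sv = sigma * np.sqrt(1 - phi)
            su = sigma * np.sqrt(phi)
            grad[3 + self.p : 3 + self.p + self.m] = sv * g_eta - v
            grad[3 + self.p + self.m :] = su * (self.W.T @ g_eta) - z
            g_ls += np.dot(g_eta, b)
            db_dphi = sigma * 0.5 * (-v / np.sqrt(1 - phi) + u / np.sqrt(phi))
            g_zeta += np.dot(g_eta, db_dphi) * dphi

        grad[1 + self.p] = g_ls
        grad[2 + self.p] = g_zeta
        return lp, grad

    def initial_point(self, rng):
        x = np.zeros(self.dim)
        if self.obs.any() and not self.prior_only:
            rate = (self.y[self.obs].sum() + 0.5) / (self.n[self.obs].sum() + 1.0)
            x[0] = np.log(rate / (1 - rate)) / self.D[0, 0]  # D[:,0] is constant
        x[1 + self.p] = np.log(0.2)  # sigma
        x[2 + self.p] = 0.0  # phi at its prior median
        jitter = 0.1 * rng.standard_normal(self.dim)
        if self.centered:
            jitter[3 + self.p :] *= 0.2  # w has prior scale sigma, start tight
        x += jitter
        return x

    def reconstruct_b(self, raw):
        """Random-effect draws (..., m) from raw draws (..., dim)."""
        p = self.p
        if self.centered:
            w = raw[..., 3 + p : 3 + p + self.k1]
            vt = raw[..., 3 + p + self.k1 :]
            sigma = np.exp(raw[..., 1 + p])
            phi = self.phi_transform(raw[..., 2 + p])[0]
            b = np.einsum("mk,...k->...m", self.E_pos, w)
            if self.k0:
                b = b + (sigma * np.sqrt(1 - phi))[..., None] * np.einsum(
                    "mk,...k->...m", self.E_null, vt)
            return b
        sigma = np.exp(raw[..., 1 + p])
        phi = self.phi_transform(raw[..., 2 + p])[0]
        v = raw[..., 3 + p : 3 + p + self.m]
        z = raw[..., 3 + p + self.m :]
        u = np.einsum("mr,...r->...m", self.W, z)
        return sigma[..., None] * (np.sqrt(1 - phi)[..., None] * v
                                   + np.sqrt(phi)[..., None] * u)

    def pointwise_loglik(self, draws):
        """Binomial log-likelihood per draw (rows) and observed district
        (columns), including the binomial coefficient."""
        idx = np.flatnonzero(self.obs)
        th_s = draws[:, : 1 + self.p]
        b = self.reconstruct_b(draws)
        eta = (th_s @ self.D.T + b)[:, idx]
        return (self.y[idx] * eta - self.n[idx] * np.logaddexp(0.0, eta)
                + self.log_binom[idx])


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorSamples:
    """Merged posterior draws of both non-baseline submodels.

    Per category, ``alpha``/``sigma``/``tau``/``phi`` have shape
    ``(chains, draws)``; ``beta`` is ``(chains, draws, p)`` on the natural
    covariate scale; ``b`` is ``(chains, draws, m)``.
    """

    categories: tuple
    covariate_names: list
    params: dict  # category -> dict of arrays
    X: np.ndarray
    district_id: list
    observed_mask: np.ndarray
    metadata: dict
    _posteriors: dict | None = None  # category -> _SubmodelPosterior
    _raw_draws: dict | None = None  # category -> (chains, draws, dim)

    @property
    def n_chains(self):
        return self.params[self.categories[0]]["alpha"].shape[0]

    @property
    def n_draws(self):
        return self.params[self.categories[0]]["alpha"].shape[1]

    def stacked(self, category, name):
        """Draws pooled across chains."""
        a = self.params[category][name]
        return a.reshape(-1, *a.shape[2:])

    @property
    def converged(self) -> bool:
        return bool(self.metadata.get("converged", False))

    def pointwise_loglik(self, category=None):
        """Pointwise log-likelihood matrix (draws x observed districts),
        columns concatenated over both submodels when ``category`` is None."""
        if self._posteriors is None:
            raise ValueError("log-likelihood unavailable (samples loaded without model)")
        cats = [category] if category is not None else [c for c in self.categories]
        blocks = []
        for c in cats:
            post = self._posteriors[c]
            raw = self._raw_draws[c].reshape(-1, self._raw_draws[c].shape[-1])
            blocks.append(post.pointwise_loglik(raw))
        return np.hstack(blocks)


def _diagnose(param_dict, n_chains):
    """split-R-hat and bulk ESS per scalar parameter via arviz."""
    import arviz as az

    rhat, ess = {}, {}
    for name, arr in param_dict.items():
        if arr.ndim == 2:
            data = {name: arr}
        else:
            data = {f"{name}[{j}]": arr[..., j] for j in range(arr.shape[-1])}
        for k, a in data.items():
            ds = az.convert_to_dataset(a[..., None] if a.ndim == 1 else a)
            rhat[k] = float(az.rhat(ds).x.values)
            ess[k] = float(az.ess(ds).x.values)
    return rhat, ess


def fit_model(
    table: DistrictTable,
    graph: DistrictGraph,
    spec: ModelSpec | None = None,
    chains: int = 2,
    draws: int = 1000,
    warmup: int | None = None,
    seed: int = 0,
    prior_only: bool = False,
    max_leapfrog: int = 32,
) -> PosteriorSamples:
    """Fit the two independent binomial BYM2 submodels by HMC.

    Districts with a missing response stay in the graph and receive their
    random effect from the prior conditional; they contribute no likelihood.
    Reproducible given ``(seed, chains, draws)``. Convergence is gated at
    split-R-hat <= 1.05 and ESS >= 100 on every reported scalar; failure is
    recorded in ``metadata`` (and surfaces as a nonzero exit in the CLI).
    """
    spec = spec or ModelSpec()
    if graph.scaling_factor is None:
        raise ValueError("graph must be scaled (scale_icar) before fitting")
    warmup = draws if warmup is None else warmup
    obs = table.observed_mask
    if obs.sum() < 10 and not prior_only:
        raise ValueError(f"only {int(obs.sum())} modeled districts; need at least 10")
    X = spec.design_matrix(table.covariates)
    counts = table.counts

    root = np.random.SeedSequence(seed)
    cat_seeds = root.spawn(2)
    params, posts, raws = {}, {}, {}
    meta = {
        "chains": chains, "draws": draws, "warmup": warmup, "seed": seed,
        "accept_rate": {}, "divergences": {}, "rhat": {}, "ess": {},
        "covariates": spec.expanded_names, "prior_only": prior_only,
    }
    for cat, cseed in zip(("overweight", "obesity"), cat_seeds):
        y = np.where(obs, counts[cat].to_numpy(dtype=float), 0.0)
        n = np.where(obs, counts[cat].to_numpy(dtype=float)
                     + counts["neither"].to_numpy(dtype=float), 0.0)
        post = _SubmodelPosterior(y, n, X, graph, spec.priors, prior_only=prior_only,
                                  standardize=not prior_only)
        chain_draws, acc, div = [], [], 0
        for ch, chseed in enumerate(cseed.spawn(chains)):
            rng = np.random.default_rng(chseed)
            x0 = post.initial_point(rng)
            # 1-D slice updates of (log sigma, zeta) between HMC steps act as
            # near-Gibbs hyperparameter moves in the centred parameterisation
            d, info = hmc_sample(post, x0, warmup, draws, rng, max_leapfrog=max_leapfrog,
                                 slice_coords=(1 + post.p, 2 + post.p) if post.centered else ())
            chain_draws.append(d)
            acc.append(info["accept_rate"])
            div += info["divergences"]
        raw = np.asarray(chain_draws)  # (chains, draws, dim)
        p = post.p
        alpha_s = raw[..., 0]
        beta_s = raw[..., 1 : 1 + p]
        th = np.einsum("ij,cdj->cdi", post.A,
                       np.concatenate([alpha_s[..., None], beta_s], axis=-1))
        sigma = np.exp(raw[..., 1 + p])
        phi = post.phi_transform(raw[..., 2 + p])[0]
        b = post.reconstruct_b(raw)
        params[cat] = {
            "alpha": th[..., 0], "beta": th[..., 1:], "sigma": sigma,
            "tau": sigma**-2.0, "phi": phi, "b": b,
        }
        posts[cat], raws[cat] = post, raw
        meta["accept_rate"][cat] = float(np.mean(acc))
        meta["divergences"][cat] = int(div)
        scalars = {"alpha": th[..., 0], "sigma": sigma, "phi": phi, "beta": th[..., 1:]}
        rhat, ess = _diagnose(scalars, chains)
        meta["rhat"][cat] = rhat
        meta["ess"][cat] = ess

    all_rhat = [v for c in meta["rhat"].values() for v in c.values()]
    all_ess = [v for c in meta["ess"].values() for v in c.values()]
    converged = (chains < 2 or max(all_rhat) <= 1.05) and min(all_ess) >= 100
    meta["converged"] = bool(converged)
    if not converged:
        warnings.warn(
            f"convergence gate failed: max R-hat {max(all_rhat):.3f}, "
            f"min ESS {min(all_ess):.0f}", stacklevel=2)

    return PosteriorSamples(
        categories=("overweight", "obesity"),
        covariate_names=spec.expanded_names,
        params=params, X=X, district_id=list(table.district_id),
        observed_mask=obs, metadata=meta, _posteriors=posts, _raw_draws=raws,
    )


# ---------------------------------------------------------------------------
# posterior products


def summarize_fixed_effects(samples: PosteriorSamples) -> pd.DataFrame:
    """Odds-ratio table: draw-wise exp of intercepts and coefficients,
    summarised as mean, sd and the 2.5%/97.5% quantiles, per category."""
    rows = []
    for cat in samples.categories:
        alpha = samples.stacked(cat, "alpha")
        beta = samples.stacked(cat, "beta")
        names = ["Intercept"] + list(samples.covariate_names)
        draws = np.column_stack([alpha, beta])
        ors = np.exp(draws)
        for j, name in enumerate(names):
            d = ors[:, j]
            rows.append({
                "category": cat, "variable": name,
                "mean": d.mean(), "sd": d.std(ddof=1),
                "q2.5": np.quantile(d, 0.025), "q97.5": np.quantile(d, 0.975),
            })
    return pd.DataFrame(rows)


def summarize_hyperparameters(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior summaries of tau and phi per category."""
    rows = []
    for cat in samples.categories:
        for name in ("tau", "phi"):
            d = samples.stacked(cat, name)
            rows.append({
                "category": cat, "hyperparameter": name,
                "mean": d.mean(), "sd": d.std(ddof=1),
                "q2.5": np.quantile(d, 0.025), "q97.5": np.quantile(d, 0.975),
            })
    return pd.DataFrame(rows)


@dataclass
class PrevalenceField:
    """Per-district posterior prevalence: means, 95% credible bounds, and
    the retained joint probability draws used for exceedance probabilities."""

    district_id: list
    categories: tuple  # ("overweight", "obesity", "neither")
    mean: np.ndarray  # (m, 3)
    lower: np.ndarray
    upper: np.ndarray
    draws: np.ndarray  # (S, m, 3)

    def exceedance(self, thresholds: dict | None = None) -> pd.DataFrame:
        thresholds = thresholds or DEFAULT_THRESHOLDS
        out = {"district_id": self.district_id}
        for cat, thr in thresholds.items():
            k = self.categories.index(cat)
            out[f"P({cat}>{thr:g})"] = exceedance_probability(self.draws[:, :, k], thr)
        return pd.DataFrame(out)

    def to_frame(self) -> pd.DataFrame:
        out = {"district_id": self.district_id}
        for k, cat in enumerate(self.categories):
            out[f"{cat}_mean"] = self.mean[:, k]
            out[f"{cat}_q2.5"] = self.lower[:, k]
            out[f"{cat}_q97.5"] = self.upper[:, k]
        return pd.DataFrame(out)


def posterior_prevalence(samples: PosteriorSamples, table: DistrictTable | None = None) -> PrevalenceField:
    """Joint per-district category probabilities from the two submodels.

    For each posterior draw the two linear predictors are reconstructed and
    passed through the softmax (baseline eta_3 = 0); draws of the two
    independently sampled submodels are paired by index.
    """
    X = samples.X
    etas = {}
    for cat in samples.categories:
        alpha = samples.stacked(cat, "alpha")[:, None]
        beta = samples.stacked(cat, "beta")
        b = samples.stacked(cat, "b")
        etas[cat] = alpha + beta @ X.T + b
    p1, p2, p3 = softmax_probs(etas["overweight"], etas["obesity"])
    draws = np.stack([p1, p2, p3], axis=-1)  # (S, m, 3)
    return PrevalenceField(
        district_id=list(samples.district_id),
        categories=("overweight", "obesity", "neither"),
        mean=draws.mean(axis=0),
        lower=np.quantile(draws, 0.025, axis=0),
        upper=np.quantile(draws, 0.975, axis=0),
        draws=draws,
    )


def exceedance_probability(draws, threshold, axis=0):
    """Fraction of posterior draws strictly above ``threshold``.

    ``draws`` is (S, m) (or any array reduced over ``axis``);
    ``threshold`` must lie in (0, 1) for prevalence use, 0 allowed as the
    degenerate lower bound.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must lie in [0,1)")
    return np.mean(np.asarray(draws) > threshold, axis=axis)
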