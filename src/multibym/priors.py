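"""Penalized-complexity (PC) priors for the BYM2 hyperparameters.

The BYM2 random effect ``b = (1/sqrt(tau)) (sqrt(1-phi) v + sqrt(phi) u*)``
has two hyperparameters: the overall precision ``tau`` and the mixing
proportion ``phi`` (share of the marginal variance that is spatially
structured). Both carry PC priors, which penalise distance from a simpler
base model at a constant exponential rate:

* ``tau`` — the prior is placed on the standard deviation ``sigma = 1/sqrt(tau)``
  (base model: ``sigma = 0``, no random effect). On this scale the PC prior is
  exactly exponential, ``sigma ~ Exp(lambda)``, calibrated through the tail
  statement ``P(sigma > U) = alpha``, i.e. ``lambda = -ln(alpha)/U``.

* ``phi`` — the base model is ``phi = 0`` (purely unstructured). The distance
  is ``d(phi) = sqrt(2 KLD(phi))``, where KLD is the Kullback-Leibler
  divergence of the BYM2 covariance ``(1-phi) I + phi (kappa Q)^-`` from the
  base ``I``. With ``gamma_i`` the eigenvalues of the scaled structured
  covariance (zeros for the sum-to-zero null directions included),

      KLD(phi) = 1/2 sum_i [ phi (gamma_i - 1) - ln(1 + phi (gamma_i - 1)) ].

  The null directions make ``d(phi) -> inf`` as ``phi -> 1``, so the
  exponential-on-distance prior is proper on (0, 1) with CDF
  ``1 - exp(-lambda d(phi))`` and the calibration ``P(phi < U) = alpha``
  solves in closed form: ``lambda = -ln(1 - alpha) / d(U)``.

Default calibrations: ``(U, alpha) = (0.5/0.31, 0.01)`` for ``tau`` and
``(0.5, 2/3)`` for ``phi``; fixed effects get independent
``N(0, precision 0.001)`` priors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCPriorSpec", "pc_rate_tau", "pc_prior_phi", "PhiPCPrior"]

#: default tau calibration, the single number U = 0.5/0.31 (INLA convention)
DEFAULT_TAU_U = 0.5 / 0.31
DEFAULT_TAU_ALPHA = 0.01
DEFAULT_PHI_U = 0.5
DEFAULT_PHI_ALPHA = 2.0 / 3.0
DEFAULT_BETA_PRECISION = 0.001


@dataclass(frozen=True)
class PCPriorSpec:
    """Hyperparameter prior calibrations for one BYM2 submodel."""

    tau_U: float = DEFAULT_TAU_U
    tau_alpha: float = DEFAULT_TAU_ALPHA
    phi_U: float = DEFAULT_PHI_U
    phi_alpha: float = DEFAULT_PHI_ALPHA
    beta_mean: float = 0.0
    beta_precision: float = DEFAULT_BETA_PRECISION
    phi_prior: str = "pc"  # "pc" or "uniform" (sensitivity fallback)

    def __post_init__(self):
        if not (0.0 < self.tau_alpha < 1.0):
            raise ValueError("tau_alpha must be in (0,1)")
        if not (0.0 < self.phi_alpha < 1.0):
            raise ValueError("phi_alpha must be in (0,1)")
        if self.tau_U <= 0:
            raise ValueError("tau_U must be positive")
        if not (0.0 < self.phi_U < 1.0):
            raise ValueError("phi_U must be in (0,1)")
        if self.beta_precision <= 0:
            raise ValueError("beta_precision must be positive")
        if self.phi_prior not in ("pc", "uniform"):
            raise ValueError("phi_prior must be 'pc' or 'uniform'")

    @property
    def lambda_tau(self) -> float:
        return pc_rate_tau(self.tau_U, self.tau_alpha)

    @property
    def beta_sd(self) -> float:
        return 1.0 / np.sqrt(self.beta_precision)


def pc_rate_tau(U: float, alpha: float) -> float:
    """Rate of the exponential PC prior on ``sigma = 1/sqrt(tau)``.

    Calibrated so ``P(sigma > U) = alpha`` holds exactly:
    ``lambda = -ln(alpha)/U``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0,1)")
    if U <= 0:
        raise ValueError("U must be positive")
    return -np.log(alpha) / U


class PhiPCPrior:
    """PC prior for the BYM2 mixing parameter ``phi`` on a given graph.

    Callable as a normalized log-density on (0, 1); also exposes the distance
    ``d(phi)``, its derivative, the CDF, and the gradient of the log-density
    (needed by gradient-based samplers).
    """

    def __init__(self, gamma: np.ndarray, U: float, alpha: float):
        gamma = np.asarray(gamma, dtype=float)
        if np.any(gamma < -1e-12):
            raise ValueError("invalid (negative) covariance eigenvalues")
        # the divergence is computed on the support of the constrained
        # structured covariance: the sum-to-zero null directions (gamma = 0)
        # carry no structured variability and are excluded, so the distance
        # to the base model stays finite at phi = 1
        gamma = gamma[gamma > 1e-12]
        if gamma.size == 0:
            raise ValueError("no structured eigenvalues available")
        self.c = gamma - 1.0  # 1 + phi*c are the BYM2 covariance eigenvalues
        self.U = float(U)
        self.alpha = float(alpha)
        dU = float(self.distance(self.U))
        self.d_max = float(self.distance(1.0))
        if dU <= 0 or self.d_max <= dU:
            raise ValueError("degenerate distance at U; cannot calibrate")
        self.rate = self._calibrate_rate(dU)

    def _truncated_cdf(self, d, rate):
        """CDF of the exponential-on-distance prior truncated to [0, d_max]."""
        if abs(rate) < 1e-12:
            return d / self.d_max
        return np.expm1(-rate * d) / np.expm1(-rate * self.d_max)

    def _calibrate_rate(self, dU):
        """Solve ``P(phi < U) = alpha`` for the penalisation rate.

        The truncated-exponential CDF is monotone in the rate; the bracket is
        widened geometrically until it straddles the root.
        """
        from scipy.optimize import brentq

        f = lambda lam: self._truncated_cdf(dU, lam) - self.alpha
        lo, hi = -1.0, 1.0
        for _ in range(60):
            if f(lo) * f(hi) <= 0:
                return brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
            lo *= 2.0
            hi *= 2.0
        raise ValueError(
            f"PC prior calibration failed to bracket a rate in [{lo}, {hi}] "
            f"for U={self.U}, alpha={self.alpha}")

    # -- distance machinery -------------------------------------------------

    def _kld(self, phi):
        phi = np.asarray(phi, dtype=float)
        t = np.multiply.outer(phi, self.c)
        return 0.5 * np.sum(t - np.log1p(t), axis=-1)

    def _kld_grad(self, phi):
        t = np.multiply.outer(np.asarray(phi, float), self.c)
        return 0.5 * np.sum(self.c * t / (1.0 + t), axis=-1)

    def _kld_hess(self, phi):
        t = np.multiply.outer(np.asarray(phi, float), self.c)
        return 0.5 * np.sum(self.c**2 / (1.0 + t) ** 2, axis=-1)

    def distance(self, phi):
        """``d(phi) = sqrt(2 KLD(phi))``; 0 at the base model ``phi = 0``."""
        return np.sqrt(2.0 * self._kld(phi))

    def _d_and_deriv(self, phi):
        K = self._kld(phi)
        Kp = self._kld_grad(phi)
        d = np.sqrt(2.0 * K)
        # limit phi -> 0: d ~ phi * sqrt(sum c^2 / 2), d' -> sqrt(sum c^2 / 2)
        small = d < 1e-12
        slope0 = np.sqrt(0.5 * np.sum(self.c**2))
        dp = np.where(small, slope0, Kp / np.where(small, 1.0, d))
        return d, dp

    def cdf(self, phi):
        """Prior CDF: truncated exponential on the distance scale,
        ``P(Phi < phi) = expm1(-rate d(phi)) / expm1(-rate d_max)``."""
        return self._truncated_cdf(self.distance(phi), self.rate)

    def ppf(self, q):
        """Inverse CDF: the phi with ``P(Phi < phi) = q`` (vectorized).

        Solves for the target distance in closed form, then inverts the
        strictly increasing ``d(phi)`` on a dense monotone grid.
        """
        q = np.clip(np.asarray(q, dtype=float), 0.0, 1.0)
        if abs(self.rate) < 1e-12:
            d_target = q * self.d_max
        else:
            d_target = -np.log1p(q * np.expm1(-self.rate * self.d_max)) / self.rate
        lo = np.geomspace(1e-14, 0.5, 4000)
        hi = 1.0 - np.geomspace(1e-14, 0.5, 4000)[::-1][1:]
        grid = np.concatenate([lo, hi, [1.0]])
        dg = self.distance(grid)
        return np.interp(d_target, dg, grid)

    # -- density ------------------------------------------------------------

    def logpdf(self, phi):
        phi = np.asarray(phi, dtype=float)
        if np.any((phi <= 0) | (phi >= 1)):
            raise ValueError("phi must lie strictly in (0,1)")
        d, dp = self._d_and_deriv(phi)
        # log of rate / (1 - exp(-rate d_max)); positive for either rate sign
        lognorm = np.log(abs(self.rate)) - np.log(abs(-np.expm1(-self.rate * self.d_max)))
        return lognorm - self.rate * d + np.log(dp)

    def __call__(self, phi):
        return self.logpdf(phi)

    def logpdf_grad(self, phi):
        """d/dphi of the log-density (scalar phi)."""
        phi = float(phi)
        d, dp = self._d_and_deriv(phi)
        Kpp = self._kld_hess(phi)
        if d < 1e-12:
            dpp = 0.0  # d is locally linear at the base model
        else:
            # d = sqrt(2K) => d' = K'/d, d'' = K''/d - (K')^2/d^3
            dpp = Kpp / d - self._kld_grad(phi) ** 2 / d**3
        return -self.rate * dp + dpp / dp


    def normal_transform(self, n_grid: int = 2001, zmax: float = 6.0):
        """Monotone map ``T`` with ``T(zeta) = ppf(Phi_N(zeta))`` and its
        derivative, as fast interpolants on ``[-zmax, zmax]``.

        Under ``zeta ~ N(0,1)``, ``T(zeta)`` has exactly this PC prior
        (up to interpolation error); used to give samplers light-tailed
        geometry in place of the heavy upper tail of phi itself.
        """
        from scipy.interpolate import PchipInterpolator
        from scipy.stats import norm

        zg = np.linspace(-zmax, zmax, n_grid)
        phig = self.ppf(norm.cdf(zg))
        phig = np.clip(phig, 1e-12, 1.0 - 1e-12)
        phig = np.maximum.accumulate(phig)  # guard strict monotonicity
        T = PchipInterpolator(zg, phig, extrapolate=False)
        Tp = T.derivative()
        lo, hi = float(phig[0]), float(phig[-1])

        def transform(zeta):
            z = np.clip(zeta, -zmax, zmax)
            phi = T(z)
            dphi = Tp(z)
            if np.ndim(zeta) == 0:
                phi = float(np.clip(phi, lo, hi))
                dphi = float(max(dphi, 0.0)) if np.abs(zeta) < zmax else 0.0
            return phi, dphi

        return transform


def pc_prior_phi(graph, U: float = DEFAULT_PHI_U, alpha: float = DEFAULT_PHI_ALPHA) -> PhiPCPrior:
    """Build the calibrated PC prior for ``phi`` on a scaled district graph.

    Uses the eigenvalues of the scaled structured covariance ``(kappa Q)^-``
    (computed once per graph and cached on it by ``scale_icar``).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0,1)")
    if not (0.0 < U < 1.0):
        raise ValueError("U must be in (0,1)")
    gamma = graph.covariance_eigenvalues()
    return PhiPCPrior(gamma, U, alpha)
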