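"""Model-comparison criteria and spatial autocorrelation diagnostics.

WAIC and the CPO score operate on a pointwise log-likelihood matrix
(posterior draws in rows, observation units in columns; here one unit is a
district's binomial observation in one submodel, concatenated over both
submodels for a combined model score).

The Empirical Bayes Index (EBI) is the Assuncao-Reis modification of
Moran's I for rates with heterogeneous denominators: raw rates are
standardised by an empirical-Bayes estimate of their sampling variance
before the Moran statistic is formed, so small-population districts do not
dominate the index. Inference is by random permutation of the standardised
rates over districts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .spatial_graph import DistrictGraph

__all__ = ["waic", "cpo_score", "ebi_moran", "EBIResult", "model_comparison_table"]


def _validate_loglik(loglik):
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 2:
        raise ValueError("loglik must be 2-D (draws x observations)")
    if loglik.shape[0] < 2:
        raise ValueError("need at least 2 posterior draws")
    return loglik


def waic(loglik):
    """Widely Applicable Information Criterion.

    ``lppd = sum_j ln mean_s exp(loglik[s, j])`` (log-sum-exp),
    ``p_waic = sum_j var_s loglik[s, j]`` (ddof=1),
    ``waic = -2 (lppd - p_waic)``.

    Returns ``(waic, lppd, p_waic)``.
    """
    ll = _validate_loglik(loglik)
    S = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(S)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic), lppd, p_waic


def cpo_score(loglik):
    """Conditional Predictive Ordinates via the harmonic-mean identity.

    ``CPO_j = [mean_s exp(-loglik[s, j])]^-1``; the scalar score is
    ``-sum_j ln CPO_j`` (smaller is better). Columns whose harmonic mean is
    numerically unreliable (non-finite) are flagged.

    Returns ``(cpo, score, unreliable_mask)``.
    """
    ll = _validate_loglik(loglik)
    S = ll.shape[0]
    log_inv_cpo = logsumexp(-ll, axis=0) - np.log(S)  # = -ln CPO_j
    cpo = np.exp(-log_inv_cpo)
    unreliable = ~np.isfinite(log_inv_cpo)
    score = float(np.sum(log_inv_cpo[~unreliable]))
    return cpo, score, unreliable


def model_comparison_table(fits: dict) -> pd.DataFrame:
    """WAIC/CPO comparison across fitted models.

    ``fits`` maps a model label to either a pointwise log-likelihood matrix
    or an object with a ``pointwise_loglik()`` method. The table is sorted
    by WAIC with ties broken by the number of covariates when available
    (most parsimonious first).
    """
    rows = []
    for label, fit in fits.items():
        ll = fit if isinstance(fit, np.ndarray) else fit.pointwise_loglik()
        w, _, p = waic(ll)
        _, score, _ = cpo_score(ll)
        n_cov = len(getattr(fit, "covariate_names", [])) or np.nan
        rows.append({"model": label, "WAIC": w, "p_waic": p, "CPO": score,
                     "n_covariates": n_cov})
    df = pd.DataFrame(rows)
    return df.sort_values(["WAIC", "n_covariates"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Empirical Bayes Index


@dataclass(frozen=True)
class EBIResult:
    index: float
    p_value: float
    n_permutations: int
    seed: int
    alternative: str


def _row_standardized_weights(graph: DistrictGraph):
    m = graph.n_districts
    W = np.zeros((m, m))
    for i, nbs in enumerate(graph.neighbor_lists):
        if nbs:
            W[i, nbs] = 1.0 / len(nbs)
    return W


def _moran(z, W):
    zc = z - z.mean()
    denom = np.dot(zc, zc)
    if denom == 0:
        return 0.0
    s0 = W.sum()
    return float(len(z) / s0 * (zc @ W @ zc) / denom)


def ebi_moran(
    counts,
    populations,
    graph: DistrictGraph,
    n_permutations: int = 999,
    seed: int = 0,
    alternative: str = "auto",
    variance: str = "poisson",
) -> EBIResult:
    """Empirical Bayes Index (Assuncao-Reis) with permutation inference.

    Rates ``r_i = O_i / n_i`` are standardised to
    ``z_i = (r_i - b) / sqrt(v_i)`` with ``b`` the global rate,
    ``v_i = a + b/n_i`` (``a`` the between-district variance component,
    ``s^2 - b / (sum n / m)``; wherever ``v_i <= 0`` it is replaced by
    ``b/n_i``). ``variance="binomial"`` uses ``b(1-b)/n_i`` in place of
    ``b/n_i``. The index is Moran's I on ``z`` with row-standardised binary
    weights; the p-value is one-sided, by default on the side of the
    observed sign (``alternative="auto"``), with ``(1 + #extreme)/(1 + P)``.
    """
    O = np.asarray(counts, dtype=float)
    n = np.asarray(populations, dtype=float)
    if O.shape != n.shape or O.ndim != 1 or len(O) != graph.n_districts:
        raise ValueError("counts/populations must be 1-D and match the graph size")
    if np.any(n <= 0):
        raise ValueError("populations must be positive")
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    if alternative not in ("auto", "greater", "less"):
        raise ValueError("alternative must be 'auto', 'greater' or 'less'")

    m = len(O)
    r = O / n
    b = O.sum() / n.sum()
    s2 = np.sum(n * (r - b) ** 2) / n.sum()
    base = b * (1 - b) if variance == "binomial" else b
    a = s2 - base / (n.sum() / m)
    v = a + base / n
    v = np.where(v <= 0, base / n, v)
    z = (r - b) / np.sqrt(v)

    W = _row_standardized_weights(graph)
    observed = _moran(z, W)

    if np.allclose(r, r[0]):
        return EBIResult(0.0, 1.0, n_permutations, seed, alternative)

    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n_permutations, m)), axis=1)
    perm_stats = np.array([_moran(z[idx], W) for idx in perm_idx])
    side = alternative
    if side == "auto":
        side = "greater" if observed >= 0 else "less"
    if side == "greater":
        extreme = int(np.sum(perm_stats >= observed))
    else:
        extreme = int(np.sum(perm_stats <= observed))
    p = (1.0 + extreme) / (1.0 + n_permutations)
    return EBIResult(observed, p, n_permutations, seed, alternative)
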