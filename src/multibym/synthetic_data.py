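"""Synthetic district systems with the statistical structure the model assumes.

The real study data (a national anthropometric census joined to population
census covariates over 472 districts) is restricted, so this module
generates district systems that reproduce its published summary statistics:

* district totals ``M_i`` from a moment-matched lognormal
  (mean 740.7, sd 788.1 children, minimum 4 — strongly right-skewed);
* seven socioeconomic covariates from a Gaussian copula with normal
  marginals at the published means/sds and pairwise correlations
  (the printed correlation matrix is repaired to the nearest positive
  definite matrix when rounding has made it indefinite);
* category counts from the multinomial baseline-logit model itself, with
  BYM2 random effects at the published hyperparameter levels and fixed
  effects at the logs of the published posterior-mean odds ratios, so
  synthetic effect sizes and prevalences (about 20% overweight, 14% obese)
  match the study's regime;
* a configurable number of districts (default 3) with the response blanked,
  mimicking the study's missing-response districts.

Geometry is either a near-square lattice with queen contiguity (which also
yields polygons for GeoJSON export) or a Delaunay triangulation of uniform
random points (connected by construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .model_core import CATEGORIES, DistrictTable, ModelSpec, softmax_probs
from .spatial_graph import (
    DistrictGraph,
    adjacency_from_pairs,
    build_adjacency,
    sample_structured,
    scale_icar,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioSpec",
    "make_geometry",
    "sample_covariates",
    "simulate_counts",
    "simulate_scenario",
    "COVARIATE_STATS",
    "COVARIATE_CORR",
    "TRUE_PARAMS",
]

#: published covariate means and sds (percent points, years, persons)
COVARIATE_STATS = {
    "Unemployment": (3.07, 1.23),
    "Urban Population": (52.52, 37.74),
    "Deprivation": (29.29, 13.90),
    "Population<14": (25.16, 4.27),
    "Single Mother Homes": (20.21, 5.48),
    "Occupants": (3.47, 0.27),
    "Schooling": (8.09, 1.55),
}

_COVARIATE_ORDER = list(COVARIATE_STATS)

#: published pairwise covariate correlations (lower triangle, same order)
COVARIATE_CORR = np.array([
    #  Unemp  Urban  Depr  Pop14  SingleM  Occup  School
    [1.00, 0.16, -0.03, 0.10, 0.26, -0.01, 0.02],
    [0.16, 1.00, -0.69, -0.48, 0.69, -0.09, 0.75],
    [-0.03, -0.69, 1.00, 0.74, -0.63, 0.33, -0.84],
    [0.10, -0.48, 0.74, 1.00, -0.55, 0.59, -0.77],
    [0.26, 0.69, -0.63, -0.55, 1.00, -0.31, 0.74],
    [-0.01, -0.09, 0.33, 0.59, -0.31, 1.00, -0.41],
    [0.02, 0.75, -0.84, -0.77, 0.74, -0.41, 1.00],
])

_PERCENT_COVARIATES = {
    "Unemployment", "Urban Population", "Deprivation", "Population<14",
    "Single Mother Homes",
}

#: published posterior means: fixed effects on the odds-ratio scale and
#: BYM2 hyperparameters, per non-baseline category
TRUE_PARAMS = {
    "overweight": {
        "alpha": float(np.log(0.204)),
        "beta": {"Deprivation": float(np.log(0.998)),
                 "Population<14": float(np.log(0.995)),
                 "Schooling": float(np.log(1.130)),
                 "Schooling^2": float(np.log(0.994))},
        "tau": 68.538, "phi": 0.844,
    },
    "obesity": {
        "alpha": float(np.log(0.200)),
        "beta": {"Deprivation": float(np.log(0.992)),
                 "Population<14": float(np.log(0.985)),
                 "Schooling": float(np.log(1.189)),
                 "Schooling^2": float(np.log(0.989))},
        "tau": 26.533, "phi": 0.944,
    },
}

CHILDREN_MEAN = 740.7
CHILDREN_SD = 788.1
CHILDREN_MIN = 4


@dataclass
class ScenarioSpec:
    """Full description of one synthetic study scenario."""

    m: int = 472
    children_mean: float = CHILDREN_MEAN
    children_sd: float = CHILDREN_SD
    covariate_stats: dict = field(default_factory=lambda: dict(COVARIATE_STATS))
    covariate_corr: np.ndarray = field(default_factory=lambda: COVARIATE_CORR.copy())
    true_alpha: dict = field(
        default_factory=lambda: {c: TRUE_PARAMS[c]["alpha"] for c in ("overweight", "obesity")})
    true_beta: dict = field(
        default_factory=lambda: {c: dict(TRUE_PARAMS[c]["beta"]) for c in ("overweight", "obesity")})
    true_tau: dict = field(
        default_factory=lambda: {c: TRUE_PARAMS[c]["tau"] for c in ("overweight", "obesity")})
    true_phi: dict = field(
        default_factory=lambda: {c: TRUE_PARAMS[c]["phi"] for c in ("overweight", "obesity")})
    geometry: str = "grid"
    n_missing: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.m < 10:
            raise ValueError("need at least 10 districts")
        for c, t in self.true_tau.items():
            if t <= 0:
                raise ValueError(f"true_tau[{c}] must be positive")
        for c, p in self.true_phi.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"true_phi[{c}] must lie in [0,1]")
        C = np.asarray(self.covariate_corr, dtype=float)
        if C.shape != (len(self.covariate_stats),) * 2 or not np.allclose(C, C.T):
            raise ValueError("covariate_corr must be symmetric and match covariate_stats")

    def model_spec(self) -> ModelSpec:
        """The ModelSpec matching the generator's true fixed effects."""
        names = [n for n in self.true_beta["overweight"] if not n.endswith("^2")]
        quads = [n[:-2] for n in self.true_beta["overweight"] if n.endswith("^2")]
        return ModelSpec(covariate_names=tuple(names), quadratic_terms=tuple(quads))


def make_geometry(m: int, kind: str = "grid", seed: int = 0):
    """Build a connected district system of ``m`` units.

    Returns ``(graph, geometries)``; ``geometries`` is a list of shapely
    polygons for ``kind="grid"`` and ``None`` for ``kind="delaunay"``.
    The graph is returned scaled (BYM2 scaling factor computed).
    """
    if m < 10:
        raise ValueError("need at least 10 districts")
    if kind == "grid":
        nrow = int(np.floor(np.sqrt(m)))
        ncol = int(np.ceil(m / nrow))
        geoms = []
        for i in range(m):
            r, c = divmod(i, ncol)
            geoms.append(box(c, -r, c + 1, -r + 1))
        graph = build_adjacency(geoms, rule="queen")
        return scale_icar(graph), geoms
    if kind == "delaunay":
        from scipy.spatial import Delaunay

        rng = np.random.default_rng(seed)
        pts = rng.random((m, 2))
        tri = Delaunay(pts)
        pairs = set()
        for simplex in tri.simplices:
            for a in range(3):
                i, j = sorted((simplex[a], simplex[(a + 1) % 3]))
                pairs.add((i + 1, j + 1))
        graph = adjacency_from_pairs(sorted(pairs), m)
        return scale_icar(graph), None
    raise ValueError(f"unknown geometry kind {kind!r}")


def sample_covariates(spec: ScenarioSpec, rng=None) -> pd.DataFrame:
    """Draw the covariate table from a Gaussian copula.

    Marginals are normal at the specified means/sds; the correlation matrix
    is repaired to the nearest positive definite matrix when needed.
    Percentage covariates are clipped to [0, 100]; Schooling and Occupants
    are clipped at 0 (clipping is logged, and a repair that moves any
    correlation entry by more than 0.1 raises a warning).
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    names = list(spec.covariate_stats)
    C = np.asarray(spec.covariate_corr, dtype=float)
    if np.linalg.eigvalsh(C).min() <= 1e-10:
        from statsmodels.stats.correlation_tools import corr_nearest

        R = corr_nearest(C, threshold=1e-8)
        shift = np.abs(R - C).max()
        logger.info("correlation matrix repaired; max entry shift %.4g", shift)
        if shift > 0.1:
            import warnings

            warnings.warn(f"correlation repair moved an entry by {shift:.3f} (> 0.1)",
                          stacklevel=2)
        C = R
    L = np.linalg.cholesky(C)
    Z = rng.standard_normal((spec.m, len(names))) @ L.T
    data = {}
    n_clipped = 0
    for j, name in enumerate(names):
        mu, sd = spec.covariate_stats[name]
        x = mu + sd * Z[:, j]
        lo, hi = (0.0, 100.0) if name in _PERCENT_COVARIATES else (0.0, np.inf)
        clipped = np.clip(x, lo, hi)
        n_clipped += int(np.sum(clipped != x))
        data[name] = clipped
    if n_clipped:
        logger.info("clipped %d covariate values to their valid range", n_clipped)
    return pd.DataFrame(data)


def simulate_counts(spec: ScenarioSpec, graph: DistrictGraph,
                    covariates: pd.DataFrame, rng=None) -> DistrictTable:
    """Simulate district totals and category counts from the model.

    Random effects are drawn per category from the BYM2 decomposition at the
    scenario's (tau, phi); totals ``M_i`` come from a lognormal matched by
    moments to (children_mean, children_sd), rounded and floored at 4;
    counts are multinomial at the softmax probabilities. The response of
    ``n_missing`` randomly chosen districts is blanked.
    """
    if graph.scaling_factor is None:
        raise ValueError("graph must be scaled before simulating")
    rng = np.random.default_rng(spec.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    m = graph.n_districts
    if len(covariates) != m:
        raise ValueError("covariates length must match the graph")

    mspec = spec.model_spec()
    X = mspec.design_matrix(covariates)
    etas = {}
    for cat in ("overweight", "obesity"):
        sigma = 1.0 / np.sqrt(spec.true_tau[cat])
        phi = spec.true_phi[cat]
        v = rng.standard_normal(m)
        u = sample_structured(graph, rng)
        b = sigma * (np.sqrt(1.0 - phi) * v + np.sqrt(phi) * u)
        beta = np.array([spec.true_beta[cat][name] for name in mspec.expanded_names])
        etas[cat] = spec.true_alpha[cat] + X @ beta + b

    p1, p2, p3 = softmax_probs(etas["overweight"], etas["obesity"])
    P = np.stack([p1, p2, p3], axis=1)

    cv = spec.children_sd / spec.children_mean
    s2 = np.log1p(cv**2)
    mu = np.log(spec.children_mean) - 0.5 * s2
    M = np.exp(mu + np.sqrt(s2) * rng.standard_normal(m))
    M = np.maximum(np.rint(M).astype(int), CHILDREN_MIN)

    counts = np.array([rng.multinomial(M[i], P[i]) for i in range(m)], dtype=float)
    if spec.n_missing > 0:
        blank = rng.choice(m, size=min(spec.n_missing, m), replace=False)
        counts[blank] = np.nan

    ids = [f"D{i + 1:04d}" for i in range(m)]
    return DistrictTable(
        district_id=ids,
        counts=pd.DataFrame(counts, columns=list(CATEGORIES)),
        covariates=covariates.copy(),
    )


def simulate_scenario(spec: ScenarioSpec):
    """Full pipeline: geometry, covariates, counts.

    Returns ``(table, graph, geometries)``; all randomness is derived from
    ``spec.seed`` so the scenario is fully reproducible.
    """
    root = np.random.SeedSequence(spec.seed)
    s_geom, s_cov, s_counts = root.spawn(3)
    graph, geoms = make_geometry(spec.m, spec.geometry,
                                 seed=int(s_geom.generate_state(1)[0] % 2**31))
    covariates = sample_covariates(spec, rng=np.random.default_rng(s_cov))
    table = simulate_counts(spec, graph, covariates, rng=np.random.default_rng(s_counts))
    return table, graph, geoms
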