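# Methods

## Model

Counts of three mutually exclusive conditions per district are multinomial,
`Y_i ~ Multinomial(M_i, p_i)`. A baseline-category logit links the two
non-baseline categories to covariates and a spatial random effect. The model
is fitted as two *independent binomial* submodels: for category k the
successes are `y_ik` out of `n_ik = y_ik + y_i3` trials with
`logit q_ik = alpha_k + x_i' beta_k + b_ik`. This conditional-binomial
factorisation is not algebraically identical to the joint multinomial
likelihood, but the two agree closely whenever counts are informative; the
test suite verifies agreement of fixed-effect posteriors within 0.5 posterior
standard deviations against an exact joint-multinomial sampler on small
instances. Keeping the submodels independent also gives each condition its
own `(tau, phi)`, which the data support (the two conditions show different
spatial fractions).

Covariates enter on their natural scales (percentage points, years) so each
odds ratio is per unit; schooling additionally enters squared (inverted-U
hypothesis). Joint per-district probabilities for all three categories are
recovered draw-by-draw through the softmax with the baseline's linear
predictor fixed at 0, pairing the two submodels' draws by index.

## Spatial structure

The ICAR precision `Q` is the contiguity-graph Laplacian. Contiguity from
polygons is queen by default (any shared boundary point; rook available),
the common disease-mapping choice. `Q` has one null direction per connected
component; the structured effect is identified by a per-component sum-to-zero
constraint, under which the generalized inverse equals the Moore–Penrose
pseudo-inverse, computed per component by dense eigendecomposition (fine for
the few hundred to ~1000 areas this package targets). Following the BYM2
convention the precision is rescaled by
`kappa = exp(mean_i log [Q^-]_ii)` over non-island districts so the
structured effect has unit typical (geometric-mean) marginal variance —
making `phi` interpretable as a variance fraction and the PC prior
transferable across graphs. Islands (degree-0 districts) are excluded from
the structured effect and from `kappa`; they keep the unstructured component.

## Priors

* `sigma = 1/sqrt(tau)`: exponential PC prior with rate `-ln(alpha)/U`,
  defaults `U = 0.5/0.31 ≈ 1.613`, `alpha = 0.01` (the `U` is read as the
  single ratio, the convention of the INLA school). This says a random-effect
  standard deviation above 1.61 on the log-odds scale has 1% prior
  probability.
* `phi`: PC prior against the base model `phi = 0` (purely unstructured).
  The distance is `d(phi) = sqrt(2 KLD(phi))` with the Kullback–Leibler
  divergence of `(1-phi) I + phi (kappa Q)^-` from `I` computed from the
  eigenvalues of the scaled structured covariance **on its support**: the
  sum-to-zero null directions are excluded. Including them would make
  `d(phi) -> infinity` at `phi -> 1` and — measured numerically on a
  100-district lattice at the default calibration — would place roughly 9% of
  the prior mass within 1e-13 of `phi = 1`, a boundary pile-up with no
  statistical meaning that also wrecks posterior exploration. On the support,
  `d(1)` is finite and the prior is a truncated exponential in distance; the
  rate solving `P(phi < U) = alpha` (defaults `U = 0.5`, `alpha = 2/3`) has
  no closed form and is found by Brent root finding with a geometrically
  widened bracket. A uniform prior on `phi` is available
  (`PCPriorSpec(phi_prior="uniform")`) for sensitivity analysis.
* Fixed effects: `N(0, precision 0.001)` (sd ≈ 31.6) on the natural
  coefficient scale.

## Posterior computation

Sampling is Hamiltonian Monte Carlo with analytic gradients; no external
probabilistic-programming framework is used. Choices that matter:

* **Fixed effects in a QR basis.** `[1, X]` is QR-orthogonalised (columns
  rescaled to unit typical size) and coefficients are sampled there, then
  mapped back through the affine transform before any reporting; the raw
  quadratic expansion (e.g. schooling and schooling²) is otherwise nearly
  collinear. The Gaussian prior is applied to the *natural-scale*
  coefficients through the same transform, so the posterior is unchanged.
* **`phi` through its prior inverse CDF.** `phi = F^{-1}(Phi_N(zeta))` with
  `zeta` standard normal, so the sampler sees light-tailed geometry; the map
  and its derivative are precomputed as monotone (PCHIP) interpolants on
  `zeta in [-6, 6]`.
* **Hybrid centring of the random effect.** In the eigenbasis of the scaled
  structured covariance, coordinates with positive eigenvalue are sampled
  *centred* (`b = E w`, `w_i ~ N(0, sigma^2 (1-phi+phi gamma_i))`): with
  hundreds of children per district, `b` is strongly data-identified and the
  hyperparameters then mix through their near-conditionals. The null and
  island directions, whose prior scale `sigma sqrt(1-phi)` collapses as
  `phi -> 1`, stay non-centred. Prior-only runs use the fully non-centred
  form, which is an independent product of standard normals.
* **Adaptation.** Dual-averaging step size (target acceptance 0.8), diagonal
  mass matrix from two expanding warmup windows (each followed by a
  dual-averaging restart), leapfrog count jittered uniformly in
  `[L/2, L]` with `L = 32` by default. One-dimensional slice-sampling
  updates of `log sigma` and `zeta` are interleaved after each HMC step as
  near-Gibbs hyperparameter moves.
* **Convergence gate.** Split R-hat ≤ 1.05 and bulk ESS ≥ 100 (arviz) on
  every reported scalar; failure is a warning in the run metadata and a
  nonzero CLI exit. Non-finite Hamiltonians reject the proposal and count as
  divergences.
* **Missing responses.** Districts with a blanked response stay in the graph
  and contribute no likelihood; their random effects come from the prior
  conditional given the neighbours, and their prevalence is predicted.
  Fewer than 10 modelled districts is an error.

Reported summaries: odds ratios are `exp` of each draw then summarised
(mean, sd, 2.5%/97.5% quantiles); `tau` is reported as `sigma^-2`;
exceedance probabilities are strict-inequality draw fractions, defaults 0.20
(overweight) and 0.14 (obesity).

## Diagnostics

WAIC is `-2 (lppd - p_waic)` with `lppd` from log-sum-exp over draws and
`p_waic` the sum of pointwise draw variances (ddof 1); CPO uses the
harmonic-mean identity per observation, aggregated as `-sum log CPO`
(smaller is better — on this convention the CPO score lands near half the
WAIC, matching how the two criteria are usually tabulated side by side).
The observation unit is one district's binomial observation in one submodel,
concatenated over submodels for a combined score. The per-observation CPO
vector is also returned so other aggregations remain possible.

The Empirical Bayes Index standardises rates by `z_i = (r_i - b)/sqrt(v_i)`
with `v_i = a + b/n_i` (Poisson-motivated Assunção–Reis variance; the
binomial variant `b(1-b)/n_i` is available), replacing non-positive `v_i` by
`b/n_i`, then computes Moran's I with row-standardised binary weights.
Inference is by random permutation (default 999); the default p-value is
one-sided on the side of the observed index. Note the sign-adaptive default
rejects at about twice the nominal level under a true null (it is implicitly
two-sided); for a calibrated one-sided test pass `alternative="greater"`
(or `"less"`), which is what the calibration test uses.

## Synthetic districts

The generator emulates the study conditions so the pipeline is testable
without the restricted census:

* geometry: near-square lattice with queen contiguity (default; also yields
  polygons for GeoJSON export) or Delaunay triangulation of uniform points
  (irregular, connected);
* district child totals: lognormal matched by moments to mean 740.7 and
  sd 788.1, rounded and floored at 4 — the published size distribution is
  strongly right-skewed;
* covariates: Gaussian copula with normal marginals at the published means
  and sds and the published pairwise correlation matrix (already positive
  definite; a nearest-correlation repair is applied if a user-supplied
  matrix is not), percentages clipped to [0, 100];
* counts: simulated from the model itself with fixed effects at the logs of
  the published posterior-mean odds ratios and hyperparameters at the
  published posterior means (`tau` 68.5 / 26.5, `phi` 0.844 / 0.944), which
  reproduces overall prevalences near the published 19.7% / 13.9%;
* three districts' responses are blanked by default, mirroring the study's
  missingness.

What this does *not* emulate: the real district map and its component
structure, non-Gaussian covariate marginals, any model misspecification
(overdispersion beyond the random effect, ecological aggregation effects).
Passing recovery and coverage tests therefore demonstrates correctness of
the inference machinery under the model's own assumptions, not robustness on
real census data.

## Problem sizes and defaults

Recovery tests run at 150 districts (single replicate, 2 chains × 1000
draws after as many warmup iterations) and 50 districts (20-replicate
coverage study, 1 chain × 400 draws), sizes at which the posterior is
informative for all parameters while a full study runs in minutes on one
core. The 472-district default of `ScenarioSpec` matches the study scale and
fits in a few minutes per submodel at 2 × 1000 draws.

## Known limitations

* The two submodels are fitted independently; any cross-condition
  correlation in the random effects is ignored (as in the source analysis).
* Dense eigendecomposition of `Q` is cubic in the number of districts;
  beyond a few thousand areas a sparse formulation would be needed.
* The HMC sampler uses a fixed jittered trajectory length, not dynamic
  termination; severely misspecified models may need a larger
  `max_leapfrog`.
* Binary contiguity weights only (no distance-band or k-nearest-neighbour
  schemes).
* No INLA-style deterministic approximation is provided; all inference is
  by sampling.
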