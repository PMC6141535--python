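# Methods

## Model

`sdfa` implements a joint dynamic species distribution model for
haul-level trawl-survey catches — a spatial dynamic factor analysis with
delta-gamma observations. Catch weight C of species c in haul i (knot s,
year t, survey v) is zero with probability 1 − p and gamma-distributed
given a positive catch:

    Pr(C = 0)         = 1 − p
    Pr(C = c | c > 0) = p · λ^k c^(k−1) e^(−λc) / Γ(k)

with per-species shape k. The two stages have separate linear
predictors,

    logit p(s,c,t) = β_p(c,t) + Σ_f L_ω,p(c,f) ω_p(s,f)
                   + Σ_f L_ε,p(c,f) ε_p(s,f,t) + δ_p(v) Q_p(c,v)
    log   r(s,c,t) = β_r(c,t) + Σ_f L_ω,r(c,f) ω_r(s,f)
                   + Σ_f L_ε,r(c,f) ε_r(s,f,t) + δ_r(v) Q_r(c,v)
                   [+ log a_i]

where r is the *mean* of the positive distribution (λ = k/r; the mean
parameterisation is the standard delta-model convention and the package's
choice — the rate form above does not by itself tie λ to a predictor),
β are species-by-year intercepts, L are factor loadings, ω are
time-invariant ("average") spatial factor fields, ε are year-varying
spatiotemporal factor fields, δ·Q are survey/gear catchability fixed
effects (first survey fixed at 0 as the reference level), and a_i is
swept area.

Factor fields are unit-variance Gaussian Markov random fields over a
set of knots, iid across factors, with anisotropic Matérn correlation

    R(d) = 2^(1−ν)/Γ(ν) (κd)^ν K_ν(κd),   d = sqrt(δ' H δ),
    H = [[e^h1, h2], [h2, (1+h2²) e^(−h1)]],  det H = 1.

The species-level field for a component therefore has matrix-normal law
vec(E) ~ MVN(0, R ⊗ L L'): the loadings carry all scale and the implied
among-species covariance is L L'. Hauls map to their nearest knot
(fields are piecewise constant), and coordinates are planar kilometres
(an equirectangular projection at the domain's central latitude is
adequate at the ~100 km correlation scales involved).

### Assumptions

- Encounters and positive catches are conditionally independent across
  hauls and species given the latent fields.
- Spatiotemporal fields are independent across years (no temporal
  autocorrelation in ε beyond what ω provides).
- Catchability is multiplicative on each link scale and constant over
  time within a survey.
- ν is fixed at 1.0 (the SPDE-family default); it is notoriously hard
  to estimate and no value is stated for the system this emulates.
- Swept area enters the density predictor as an offset by default
  (catch = density × area swept); encounter probability is treated as
  area-independent. Whether area should instead be a covariate is
  genuinely open, so `offset_policy` also supports `"covariate"`
  (estimated elasticity) and `"none"`.

## Estimation

All fixed effects θ (intercepts, loadings, catchability, gamma shapes,
κ_p, κ_r, h1, h2) are estimated by maximising the Laplace-approximated
marginal likelihood,

    −log L(θ) = f(θ, u*) + ½ log det H(θ, u*) − (n_u/2) log 2π,

where f is the joint NLL (observations plus field priors), u* the inner
mode over all latent fields and H = ∇²_u f.

**Inner problem.** Both observation stages are log-concave in their
predictors (∂²ℓ/∂η² = −p(1−p) for the Bernoulli stage and −kC/r for the
gamma stage), so the inner problem is convex and plain Newton iteration
converges in a handful of steps. The inner Hessian has an arrowhead
structure — the ω block couples to every year's ε block through the
data, but years never couple to each other — so each Newton solve is T
per-year Cholesky factorisations plus one Schur complement on the ω
block. Convergence is declared at inner gradient ∞-norm < 1e-8, or at a
Newton decrement below 1e-14·(1+|f|) (the numerical floor).

**Outer problem.** L-BFGS-B with the *exact* gradient of the Laplace
objective:

    dL/dθ = ∂f/∂θ + ½ tr(G ∂H/∂θ) − ½ w' ∂²f/∂u∂θ,
    w = G J'(d3 ∘ ℓ),  ℓ_i = J_i G J_i',  G = H^(−1),

where J = ∂η/∂u and d3 is the third derivative of the per-observation
NLL (p(1−p)(1−2p) for the Bernoulli stage, −kC/r for the gamma stage, 0
for the Gaussian check family). The per-observation leverages ℓ_i need
only the (ω, ε_t) diagonal blocks of G at each (knot, year), which come
from the same arrowhead factorisation (a selected inverse); no dense
n_u × n_u inverse is formed against the data. Derivatives of R with
respect to (log κ, h1, h2) are central finite differences of the (small)
knot correlation matrix itself; everything else is exact. The full outer
gradient is verified against finite differences of the objective in the
test suite (agreement ~1e−6, the FD noise floor). Outer convergence:
projected gradient < 1e-3 (`gtol`) with a very tight `ftol` (1e-12) so
termination is gradient-driven.

**Identifiability.** Loadings are estimated as unconstrained
lower-triangular matrices; after convergence each factor column is
sign-flipped so the diagonal is non-negative. Because the likelihood is
exactly invariant to column sign flips, this is equivalent to imposing
the non-negative-diagonal constraint during estimation without putting a
kink at the optimum.

**Starting values.** Intercepts from empirical per-(species, year)
encounter rates (clipped to [0.02, 0.98] before the logit) and mean
positive densities; loadings 0.1 × standard normal (seeded); k = 1;
κ such that correlation falls to 10% at half the domain diameter; h = 0.

**Standard errors** come from a central finite-difference Hessian of
the exact outer gradient, inverted by Cholesky. Near symmetry points
(loadings ≈ 0) the outer Hessian can be indefinite; the covariance then
uses a magnitude-eigenvalue pseudo-inverse (1/|λ|, floored) and the fit
is flagged `hessian_pd=False`. This keeps the uncertainty in
weakly-identified directions large but finite, which is exactly what the
downstream correlation masks need.

**AIC/BIC.** AIC = 2·n_fixed + 2·NLL, BIC = ln(n_obs)·n_fixed + 2·NLL
with n_obs the number of haul × species rows.

**Exactness check.** With an identity link and Gaussian errors the
marginal likelihood integrates in closed form; the Laplace value matches
the dense multivariate-normal computation to ~1e-13 on a 5-knot,
2-species, 3-year instance. This is the single most important estimation
oracle, exercised in both the tests and the acceptance script.

## Dimension-reduction outputs

- **PCA rotation**: via the SVD L = U S W', the reported loadings are
  L W (ordered by decreasing singular value) and factor coefficients are
  counter-rotated by W', leaving L L' and every predicted surface
  unchanged; each rotated column is flipped so its largest-magnitude
  loading is positive. Eigen-rotation was chosen over varimax because
  factors are reported in explained-variance order; variance explained
  by the first k factors is the corresponding eigenvalue ratio of L L'.
  Fractions are computed from L L' of each loading matrix separately
  (not from realized field variance) — an open choice, documented here.
- **Species correlations**: corr(i,j) = (LL')_ij / √((LL')_ii (LL')_jj);
  zero-variance species are flagged undefined rather than silently 0.
  SEs by Monte-Carlo propagation: 500 draws of the loading block from
  its asymptotic normal, correlation recomputed per draw, SE = draw
  standard deviation; entries whose estimate ± 1.96·SE spans zero are
  masked non-significant. Monte-Carlo propagation was preferred to the
  delta method: simpler, testably correct, and it matches ±1.96·SE
  reporting directly.
- **Assemblages**: average-linkage hierarchical clustering on the
  distance 1 − corr, cut at n_groups (default 3); linkage is
  configurable; undefined entries are imputed 0 with a warning; labels
  are renumbered by first appearance in species order so ties break
  deterministically.
- **Spatial vs. spatiotemporal regression**: for each species pair, the
  across-knot correlation of the realized spatial fields (ω L') is the
  predictor and each year's across-knot correlation of the realized
  spatiotemporal field (ε_t L') the response, pooled over years; OLS
  slope, Pearson r with a Fisher-z CI, and R² are reported. Realized
  fields (not model-implied correlations) are used because the
  model-implied spatiotemporal correlation is year-invariant by
  construction — only the realized fields vary from year to year.
- **Covariate correlation**: Pearson r of a factor-coefficient map with
  a knot covariate, Fisher-z 95% CI; constant inputs are flagged
  undefined.

## Prediction products

Expected density is the delta-gamma mean p·r (not the median — closed
form and standard for index construction), at reference catchability
(δ = 0) and unit area, so maps and indices are gear-free. Difference
maps standardise each species' surface across knots (z-score by
default; min-max available) and subtract; they are exactly antisymmetric.
Catch compositions apply a gear's δ·Q to both predictors at one knot and
renormalise expected catches across species. The abundance index is
Σ_s area_s · density(s, t) per year, with SEs by the same Monte-Carlo
propagation (fields held at their modes — the reported SEs cover
fixed-effect uncertainty only, a documented limitation).

## Synthetic data

The generator emulates a Celtic-Sea-like mixed demersal survey and is
the package's study condition, not a tuning dial:

| quantity | default | why |
|---|---|---|
| extent | 717 × 445 km | 48–52°N × 12–2°W at ~50°N in planar km |
| knots | 250 (application-scale), 12–30 (desk-scale tests) | grid cells partition the extent exactly |
| β_p | N(0, 0.5²) | encounter rates centred near 0.5 |
| β_r | N(log 100, 0.5²) | positive densities of order 100 kg/km² |
| δ | N(0, 0.4²), survey 0 ≡ 0 | gears differing by tens of percent |
| k | 1.0 | strongly right-skewed positive catches |
| κ_p, κ_r | 0.0331, 0.0230 /km | 10% correlation at ≈97 and ≈140 km (ν = 1) |
| h1, h2 | 0.3, 0.1 | mild geometric anisotropy |
| swept area | lognormal(log 0.05, 0.25²) km² | typical trawl tow |
| loadings | dominant 1.0 / off-block 0.2, ±20% jitter | planted assemblage structure |

Assemblage structure is planted through block loadings: each factor has
a dominant species block. Whole columns get random signs — which leaves
L L', hence every correlation and every recovery target, unchanged —
and per-entry random signs apply only to the small off-block entries, so
within-assemblage correlations stay high (≳0.9) and between-assemblage
correlations near zero by construction. Per-species random signs on the
dominant entries would destroy exactly the structure the generator
exists to plant, which is why the randomisation is column-wise.

What the generator does **not** emulate: gear physics, tow tracks or
vessel movement; temporally autocorrelated ε; overdispersion beyond the
gamma; species interactions beyond shared factors; non-stationary or
covariate-driven fields. Passing recovery tests therefore show that the
estimator inverts its own generative model at realistic sizes — not that
the model is adequate for any particular real survey.

## Problem sizes and numerical choices

Desk-scale defaults keep the full test suite and the acceptance script
comfortably inside a few minutes on one CPU:

- recovery experiment: 4 species (2 assemblages), 2 factors per
  component, 30 knots, 10 years, 3 000 hauls, 2 surveys (~20 s to fit);
- null calibration: 20 replicates of 3 species, 1 factor per component,
  12 knots, 3 years, 270 hauls, with standard errors (~2 s each);
- smoke pipeline: 20 knots, 2 species, 5 years, 1 factor (~10 s).

The 250-knot, 18-species, 9-factor configuration is accepted by every
code path (the dense per-year blocks are then 2 250×2 250) but is not
exercised by tests.

PD jitter 1e-8 is added to correlation matrix diagonals before
factorisation; rank deficiency of V = L L' from n_factors < n_species is
expected and handled the same way in `matrix_normal_logpdf`. Coincident
knots produce off-diagonal correlation 1 and fail loudly if the jitter
cannot rescue positive definiteness (the error names the smallest
eigenvalue). Hauls outside the knot hull map to the nearest knot with a
warning (rejected in strict mode). All-zero hauls are retained — zeros
are informative in a hurdle model. Size-class boundary: length ≥ cutoff
counts as adult. The length-weight relation is the standard allometric
power law W = a·L^b fitted by log-log regression.

## Known limitations

- No temporal smoothing or autocorrelation on intercepts or ε fields.
- Index SEs ignore latent-field uncertainty (fixed-effect propagation
  only).
- ν is not estimable; anisotropy is shared between encounter and
  density components (two κ's, one H), matching the two reported ranges
  without doubling the spatial parameter count.
- The outer objective is multimodal in small samples: weakly-loaded
  species can converge with flipped correlation signs when data are
  thin (binary stage, few years). Multi-start stability is tested at
  desk scale; real applications should refit from several seeds.
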