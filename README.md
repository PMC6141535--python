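# sdfa — spatial dynamic factor analysis for mixed-fishery survey data

Mixed fisheries catch many species in the same tow, so managing them
well requires knowing *which species are caught together, where, and
how consistently from year to year*. `sdfa` answers that with a joint
dynamic species distribution model for haul-level trawl-survey catches:
a **spatial dynamic factor analysis** in which every species' encounter
probability and positive catch density load onto a small number of
shared latent spatial fields.

The model, for species c at knot s, year t, sampled by survey v:

    logit p(s,c,t) = β_p(c,t) + Σ_f L_ω,p(c,f)·ω_p(s,f)
                   + Σ_f L_ε,p(c,f)·ε_p(s,f,t) + δ_p(v)·Q_p(c,v)
    log   r(s,c,t) = β_r(c,t) + Σ_f L_ω,r(c,f)·ω_r(s,f)
                   + Σ_f L_ε,r(c,f)·ε_r(s,f,t) + δ_r(v)·Q_r(c,v) + log a

    Pr(C = 0)       = 1 − p                       (delta-gamma
    Pr(C = c | c>0) = p · Gamma(c; k, λ = k/r)     observation model)

ω are time-invariant spatial factors and ε year-varying spatiotemporal
factors — Gaussian Markov random fields over knots with anisotropic
Matérn correlation, so that vec(E) ~ MVN(0, R ⊗ LL′). δ·Q are
survey/gear catchability effects and `a` is swept area. Estimation is
maximum marginal likelihood via the Laplace approximation: a convex
inner Newton solve over all latent fields (exploiting the per-year
block structure of the inner Hessian) inside an outer quasi-Newton over
the fixed effects, driven by the exact analytic gradient of the Laplace
objective.

On top of the fit, the package produces the dimension-reduction outputs
used to reason about mixed fisheries: PCA-rotated factor maps with
variance explained, among-species correlation matrices with Monte-Carlo
confidence masks, hierarchical clustering into species assemblages,
standardised density difference maps, gear-specific expected catch
compositions, and area-weighted yearly abundance indices.

Written for quantitative fisheries scientists and spatial
statisticians. Because real survey extracts are not redistributable, a
first-class synthetic-data module generates knot grids, latent fields
and haul-level catch tables with exactly the model's structure, so every
stage is testable against a known ground truth. See
[docs/methods.md](docs/methods.md) for the full model description,
assumptions and numerical choices.

## Worked example

Simulate a 4-species survey (two planted assemblages, two factors per
component, 30 knots, 10 years, 3 000 hauls from 2 gears), fit the
model, and summarise:

```python
import numpy as np
from sdfa import (ModelConfig, SurveyDesign, cluster_assemblages,
                  make_knot_grid, pca_rotate, prepare_data, simulate_survey,
                  simulate_truth, species_correlations, variance_explained)
from sdfa.model import fit

grid = make_knot_grid(30, (0.0, 400.0, 0.0, 300.0))
config = ModelConfig(n_species=4, n_years=10, n_knots=30, n_surveys=2,
                     n_factors_omega_p=2, n_factors_eps_p=2,
                     n_factors_omega_r=2, n_factors_eps_r=2, seed=0)
truth = simulate_truth(config, grid, seed=11, n_assemblages=2)
table = simulate_survey(truth, SurveyDesign(hauls_per_year={0: 150, 1: 150}),
                        seed=12)
data = prepare_data(table, grid, config)
result = fit(data, seed=0)
print("converged:", result.converged, " NLL: %.1f" % result.nll,
      " AIC: %.1f" % result.aic)
rf = pca_rotate(result.params.L_omega_p, result.fields.omega_p)
print("variance explained (first spatial encounter factor): %.3f"
      % variance_explained(rf, 1))
cs = species_correlations(result.params.L_omega_r)
print(np.round(cs.corr, 2))
print("assemblages:", cluster_assemblages(cs, n_groups=2))
```

prints (about 20 seconds on one CPU):

```
converged: True  NLL: 23906.1  AIC: 48048.2
variance explained (first spatial encounter factor): 0.569
[[1.   0.95 0.12 0.14]
 [0.95 1.   0.43 0.45]
 [0.12 0.43 1.   1.  ]
 [0.14 0.45 1.   1.  ]]
assemblages: [0 0 1 1]
```

The first two species and the last two form the two simulated
assemblages: within-assemblage spatial correlations are high (0.95,
1.00), between-assemblage correlations low, and average-linkage
clustering on 1 − corr recovers the planted grouping exactly. The first
rotated factor carries 57% of the between-species variance in encounter
probability.

A scikit-learn style front end wraps the same machinery:

```python
from sdfa import SpatialDynamicFactorAnalysis
est = SpatialDynamicFactorAnalysis(n_factors_spatial=2,
                                   n_factors_spatiotemporal=2,
                                   n_knots=30, seed=0).fit(table)
est.aic_, est.converged_      # fitted attributes
est.predict(table)            # expected catch per haul x species row
```

and a CLI runs the pipeline from config files:

```bash
sdfa run --config config.json --out-dir out/     # simulate→fit→summarise→predict
sdfa simulate | fit | summarize | predict | compose   # individual stages
```

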