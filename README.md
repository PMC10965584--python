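# skyglow

Multi-scale Bayesian analysis of artificial light at night (ALAN) and the
relative abundance of crepuscular birds.

## The problem

Nightjars (Caprimulgidae) are crepuscular aerial insectivores that nest on
the ground. Artificial light could help them (insects aggregate under lamps)
or hurt them (illuminated nests are easier for predators to find), and the
answer plausibly depends on *where* the light is measured: a streetlight 200 m
away is a different exposure than diffuse skyglow over the whole home range.
Roadside point-count surveys give relative-abundance counts; satellite
radiance composites and land-cover inventories give landscape context.

This package implements the full analysis chain for that kind of study:

1. **Synthetic data** (`skyglow.synthdata`) — raster landscapes with point
   light sources plus Gaussian skyglow, urban cover spatially coupled to the
   lights at a controlled correlation, roadside routes of 6–10 stations
   ~1.6 km apart, negative-binomial counts whose covariates act at known
   buffer scales, and per-minute Bernoulli detection histories.
2. **Covariates** (`skyglow.covariates`) — buffer means of each landscape
   layer at 400 / 1600 / 6400 m around every station, radiance-composite and
   land-cover compositing rules, the prior-count covariate, and column
   standardization with invertible scaling metadata.
3. **MCMC engine** (`skyglow.mcmc`) — Poisson / negative-binomial /
   zero-inflated-Poisson likelihoods with a log link, an adaptive
   Metropolis-within-Gibbs sampler, DIC, split-chain R-hat, and
   maximum-likelihood GLM + all-subsets AIC helpers for the preliminary
   geographic screen.
4. **BLISS** (`skyglow.bliss`) — Bayesian latent indicator scale selection:
   a categorical latent variable per covariate chooses which buffer radius
   enters the linear predictor, sampled jointly with the coefficients, so the
   posterior frequency of each radius measures its explanatory support.
5. **Abundance** (`skyglow.abundance`) — the final fixed-scale NB fit and the
   derived quantities: posterior prediction curves over an ALAN gradient,
   percent changes with credible intervals, the interaction sign-switch
   threshold `u* = -beta_ALAN / beta_int`, posterior coefficient
   correlations, and the post-hoc refits (station removal, dual-scale entry).
6. **Detection** (`skyglow.detection`) — the binomial minutes-detected GLM,
   the whole-survey detection probability `1 - (1 - p_min)^6`, the <90%
   detection filter with abundance refit, and the simulate-refit
   parameter-recovery harness.

## The model

Counts are negative binomial with a log link,

```
y_i ~ NB(mu_i, k),            Var[y_i] = mu_i + mu_i^2 / k
log mu_i = b0 + sum_j b_j x_ij(s_j) + b_int x_A(s_A) x_U(s_U) + g' z_i
```

where `x_ij(s_j)` is covariate `j` measured in the buffer of radius `s_j`
(its *scale of effect*), the ALAN × urban interaction carries its own pair of
parent scales, and `z_i` collects temporal, geographic and prior-count
covariates. The latent `s_j` are sampled over {400, 1600, 6400} m with a
uniform prior; coefficients get Normal(0, 2.5²) priors on the standardized
scale and the dispersion a Gamma(0.1, 0.1) prior. Final inference uses 3
chains × 12,000 iterations with 3,000 burn-in — 27,000 retained draws,
unthinned.

## Worked example

```python
import numpy as np
from skyglow import (ChainConfig, BlissSpec, run_bliss, scale_selection_table,
                     select_scale, fit_final, percent_change)
from skyglow.synthdata import SimulationConfig, TrueParameters, simulate_study

cfg = SimulationConfig(seed=7, n_routes=20, target_alan_urban_corr=0.6)
truth = TrueParameters(coefficients={"alan": (-0.5, 1600), "urban": (0.3, 6400)},
                       interaction=(-0.2, 1600, 1600),
                       detection_slopes={"alan_400": -0.3})
bundle = simulate_study(cfg, truth)         # 596 surveys at ~150 stations

chains = ChainConfig(chains=3, iterations=2000, burn_in=500, seed=1)
spec = BlissSpec(covariates=("alan", "urban"),
                 fixed_terms=bundle.design.fixed_covs,
                 interaction=("alan", "urban"))
post = run_bliss(spec, bundle.design, bundle.design.y, chains)
print(scale_selection_table(post).round(2))
print(select_scale(post, "scale[alan]"), select_scale(post, "scale[urban]"))

fit = fit_final(bundle.design, {"alan": 1600, "urban": 6400}, chains,
                interaction=("alan", "urban"), interaction_scales=(1600, 1600))
print(percent_change(fit, 0.0, 1.0, urban_level=0.05))
```

prints

```
                         400   1600  6400
covariate
scale[alan]              0.00  1.00  0.00
scale[urban]             0.01  0.36  0.64
scale[alan:urban|alan]   0.54  0.42  0.04
scale[alan:urban|urban]  0.21  0.78  0.01
1600 6400
-64.0% (-73.2%, -52.9%)
```

The BLISS posterior concentrates on the generating scales — 100% of draws
select 1600 m for the ALAN main effect and 64% select 6400 m for urban —
while the weaker interaction's parent scales stay diffuse. The final line is
the expected-count change as radiance rises from 0 to 1 nW cm⁻² sr⁻¹ at 5%
urban cover: a 64% decline with a 95% credible interval of (−73%, −53%),
consistent with the generating coefficient (−0.5 per standard deviation of
intermediate-scale ALAN, ≈ 2 SD per radiance unit on this landscape). Exact
numbers depend on the seed.

A thin CLI wraps the same functions:

```
skyglow simulate --out runs/demo --seed 3
skyglow select-scales --design runs/demo/design.csv --out runs/demo/scales.json
skyglow fit --design runs/demo/design.csv --scales '{"alan":1600,"urban":6400}' \
        --out runs/demo/fit
skyglow detect --design runs/demo/design.csv --surveys runs/demo/surveys.csv \
        --out runs/demo/detect.json
```

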